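"""Synthetic pooled-screen generator and the clone-sampling uncertainty experiment.

The generator reproduces the statistical structure the inference assumes:

* a skewed plasmid library (log-normal guide proportions, sigma chosen so the
  90th/10th centile guide-count ratio falls in the 3-5 range reported for
  pooled cloning);
* an engraftment bottleneck (the clone count per guide is Poisson with rate
  proportional to library prevalence times a per-guide rate factor eps*);
* heavy-tailed clone sizes (default: a two-component zero-truncated
  negative-binomial mixture whose large component is overdispersed enough
  that clone sizes span 3-4 orders of magnitude, as transplant tumours do)
  scaled per guide by a size factor phi*;
* optional paired amplicon FASTQ with the vector anchors, the degenerate UMI
  in reverse orientation, and substitution errors in UMI bases.

Ground truth (per-guide true fitness eps* times the winsorized mean of the
scaled size distribution) is emitted alongside, so truth-recovery of the full
extract -> merge -> fit chain can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .clone_extraction import (
    FORWARD_ANCHOR,
    REVERSE_ANCHOR,
    CloneRecord,
    CloneTable,
)
from .fitness_model import ScreenDataset, winsorized_mean_of_pmf
from .library_design import LibraryDesign, make_fixture, reverse_complement

__all__ = [
    "SimulationConfig",
    "SimulatedScreen",
    "simulate_screen",
    "sampling_uncertainty_curve",
    "winsorize_sample",
]


def winsorize_sample(values, upper_fraction: float = 0.02) -> np.ndarray:
    """Replace values above the empirical (1 - fraction) quantile (linear
    interpolation) by that quantile; length and order preserved."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if not 0.0 <= upper_fraction < 1.0:
        raise ValueError("upper_fraction must be in [0, 1)")
    if upper_fraction == 0.0:
        return values.copy()
    q = float(np.quantile(values, 1.0 - upper_fraction))
    return np.minimum(values, q)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults emulate a signaling-library transplant: 192 guides, log-normal
    library skew sigma=0.55 (90/10 count ratio ~ 4), 500 clones per guide,
    mix-NB clone sizes with component means (5, 60), dispersions (1.0, 0.25)
    and small-component weight 0.3.
    """

    library: "LibraryDesign | str" = "signaling"
    seed: int = 0
    library_sigma: float = 0.55
    total_initial_reads: int = 1_000_000
    clones_per_guide: float = 500.0
    eps_star: Optional[dict[str, float]] = None  # per-guide clone-rate factor
    phi_star: Optional[dict[str, float]] = None  # per-guide size factor
    family: str = "mix_nb"
    family_params: dict = field(
        default_factory=lambda: {"mu1": 5.0, "mu2": 60.0, "r1": 1.0, "r2": 0.25, "w": 0.3}
    )
    umi_error_rate: float = 0.0
    winsor_upper_fraction: float = 0.02  # used for the true-fitness table
    # Fixed plasmid counts (guide_id -> reads); replicate transplants share one
    # plasmid pool, so pass the first replicate's counts to the others.
    initial_counts: Optional[dict[str, int]] = None

    def resolve_library(self) -> LibraryDesign:
        if isinstance(self.library, LibraryDesign):
            return self.library
        return make_fixture(self.library)


@dataclass
class SimulatedScreen:
    dataset: ScreenDataset
    clone_table: CloneTable
    truth: pd.DataFrame  # guide_id, eps_star, phi_star, true_fitness
    initial_counts: dict[str, int]
    fastq_fwd: Optional[Path] = None
    fastq_rev: Optional[Path] = None


def _scaled_params(cfg: SimulationConfig, phi: float) -> dict:
    p = dict(cfg.family_params)
    if cfg.family == "mix_nb":
        p["mu1"] *= phi
        p["mu2"] *= phi
    elif cfg.family == "nb":
        p["mu"] *= phi
    elif cfg.family == "poisson":
        p["mu"] *= phi
    else:
        raise ValueError(f"simulator supports poisson/nb/mix_nb, not {cfg.family!r}")
    return p


def _sample_zt_sizes(cfg: SimulationConfig, phi: float, n: int, rng) -> np.ndarray:
    p = _scaled_params(cfg, phi)
    if cfg.family == "poisson":
        draw = lambda m: rng.poisson(p["mu"], m)  # noqa: E731
    elif cfg.family == "nb":
        draw = lambda m: rng.negative_binomial(p["r"], p["r"] / (p["r"] + p["mu"]), m)  # noqa: E731
    else:
        def draw(m):
            pick1 = rng.random(m) < p["w"]
            mu = np.where(pick1, p["mu1"], p["mu2"])
            r = np.where(pick1, p["r1"], p["r2"])
            return rng.negative_binomial(r, r / (r + mu))
    # Zero truncation of the mixture: zero redraws re-pick the component too.
    x = draw(n)
    for _ in range(200):
        n_zero = int((x == 0).sum())
        if not n_zero:
            break
        x[x == 0] = draw(n_zero)
    x[x == 0] = 1
    return x.astype(np.int64)


def simulate_screen(
    config: SimulationConfig,
    make_fastq: bool = False,
    fastq_prefix: "str | Path | None" = None,
    sample_id: str = "sim",
) -> SimulatedScreen:
    """Draw one synthetic screen; fully reproducible under ``config.seed``."""
    lib = config.resolve_library()
    rng = np.random.default_rng(config.seed)
    gids = lib.guide_ids
    T = len(gids)

    # Skewed plasmid library: log-normal proportions -> multinomial reads.
    props = np.exp(rng.normal(0.0, config.library_sigma, T))
    props /= props.sum()
    I = rng.multinomial(config.total_initial_reads, props)
    I = np.maximum(I, 1)
    if config.initial_counts is not None:
        I = np.array([config.initial_counts[g] for g in gids], dtype=np.int64)
    initial = {g: int(c) for g, c in zip(gids, I)}
    pi = I / I.sum()

    eps = np.array([(config.eps_star or {}).get(g, 1.0) for g in gids])
    phi = np.array([(config.phi_star or {}).get(g, 1.0) for g in gids])

    # Engraftment bottleneck: clone counts per guide.
    K = rng.poisson(config.clones_per_guide * T * pi * eps)

    clone_sizes: dict[str, list[int]] = {}
    records: list[CloneRecord] = []
    template = lib.umi_template
    for t, gid in enumerate(gids):
        if K[t] == 0:
            clone_sizes[gid] = []
            continue
        sizes = _sample_zt_sizes(config, phi[t], int(K[t]), rng)
        clone_sizes[gid] = sorted(int(s) for s in sizes)
        umis = set()
        while len(umis) < K[t]:
            umis.add(template.realize(rng))
        for umi, size in zip(sorted(umis), sizes):
            records.append(CloneRecord(gid, umi, int(size)))

    table = CloneTable(sample_id=sample_id, records=records)
    dataset = ScreenDataset(
        sample_id=sample_id, clone_sizes=clone_sizes, initial_counts=initial, library=lib
    )

    truth = pd.DataFrame(
        {
            "guide_id": gids,
            "eps_star": eps,
            "phi_star": phi,
            "true_fitness": [
                e
                * winsorized_mean_of_pmf(
                    config.family, _scaled_params(config, p), config.winsor_upper_fraction
                )
                for e, p in zip(eps, phi)
            ],
            "n_clones": [len(clone_sizes[g]) for g in gids],
            "initial_reads": [initial[g] for g in gids],
        }
    )

    out = SimulatedScreen(
        dataset=dataset, clone_table=table, truth=truth, initial_counts=initial
    )
    if make_fastq:
        if fastq_prefix is None:
            raise ValueError("fastq_prefix required with make_fastq")
        out.fastq_fwd, out.fastq_rev = _write_fastq(
            table, lib, Path(fastq_prefix), config.umi_error_rate, rng
        )
    return out


# FASTQ layout: fixed pads around the invariant anchors; the sgRNA sits at
# offsets 24-43 downstream of the forward anchor and the reverse-complemented
# UMI inside the 50-nt window after the reverse anchor.  Constant phred 37.
_FWD_PAD = "ACGTACGTAC"
_FWD_SPACER = "GTTTAAGAGCTAAGCTGGAAAGT"  # 23 nt between anchor and guide window
_FWD_TAIL = "TTTTTTTTTT"
_REV_PAD = "TTGCAG"
_REV_SPACER = "CGAAT"  # 5 nt into the 50-nt UMI search window
_REV_TAIL = "GGATCCGGTT"
_MUT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _write_fastq(
    table: CloneTable,
    library: LibraryDesign,
    prefix: Path,
    umi_error_rate: float,
    rng: np.random.Generator,
) -> tuple[Path, Path]:
    p1 = prefix.with_suffix(".R1.fastq")
    p2 = prefix.with_suffix(".R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        read_no = 0
        for rec in table.records:
            guide_seq = library[rec.guide_id].sequence
            fwd = _FWD_PAD + FORWARD_ANCHOR + _FWD_SPACER + guide_seq + _FWD_TAIL
            umi_rc = reverse_complement(rec.umi)
            for _ in range(rec.count):
                read_no += 1
                umi_out = umi_rc
                if umi_error_rate > 0:
                    hits = np.flatnonzero(rng.random(len(umi_out)) < umi_error_rate)
                    if hits.size:
                        chars = list(umi_out)
                        for i in hits:
                            chars[i] = _MUT[chars[i]][rng.integers(3)]
                        umi_out = "".join(chars)
                rev = _REV_PAD + REVERSE_ANCHOR + _REV_SPACER + umi_out + _REV_TAIL
                f1.write(f"@sim_{read_no}/1\n{fwd}\n+\n{'F' * len(fwd)}\n")
                f2.write(f"@sim_{read_no}/2\n{rev}\n+\n{'F' * len(rev)}\n")
    return p1, p2


def sampling_uncertainty_curve(
    clone_sizes,
    n_grid,
    reps: int = 200,
    winsorize: bool = False,
    upper_fraction: float = 0.02,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Uncertainty in the sampled population mean clone size vs sample size.

    For each n in ``n_grid``: draw ``reps`` without-replacement samples of n
    clones, compute the (winsorized) mean of each, and report the central 90%
    interval across repetitions.  Heavy-tailed populations give wide intervals
    at small n; winsorization narrows them by tempering outlying clones.
    """
    population = np.asarray(clone_sizes, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        if n > population.size:
            raise ValueError(f"sample size {n} exceeds population {population.size}")
        means = np.empty(reps)
        for i in range(reps):
            sample = rng.choice(population, size=n, replace=False)
            if winsorize:
                sample = winsorize_sample(sample, upper_fraction)
            means[i] = sample.mean()
        lo, hi = np.percentile(means, [5, 95])
        rows.append((int(n), float(lo), float(hi), float(hi - lo)))
    return pd.DataFrame(rows, columns=["n", "lo90", "hi90", "width"])
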