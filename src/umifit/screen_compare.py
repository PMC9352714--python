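"""Post-inference analysis: normalization to the neutral level, neutrality
calls with FDR control, pairwise dataset comparison with four outlier
criteria, Hasse-diagram resolution of the fitness partial order, rank
correlations, and in-silico clone subsampling.

Fitness is made comparable across datasets by setting the 70th centile of the
gene-targeting guides' posterior medians to a neutral level of 1.  A guide is
called non-neutral when its posterior tail probability around 1, doubled and
BH-adjusted across targeting guides, falls under the FDR threshold.  Between
two datasets a gene is an outlier when at least two of its guides satisfy all
of: (c1) non-zero fitness differential at 95%, (c2) a median differential
outside the variability of the neutral control guides, and (c3) a non-zero
rank differential at 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .fitness_model import FitnessPosterior, ScreenDataset
from .library_design import LibraryDesign

__all__ = [
    "NormalizedFitness",
    "ScreenComparison",
    "PosetGraph",
    "normalize_fitness",
    "call_nonneutral",
    "compare_datasets",
    "hasse_poset",
    "subsample_clones",
    "combine_replicates",
    "spearman_guides",
]


@dataclass
class NormalizedFitness:
    """Posterior fitness draws rescaled so the 70th centile of targeting-guide
    medians equals 1."""

    guide_ids: list[str]
    draws: np.ndarray  # (n_draws, T)
    scalar: float
    guide_class: np.ndarray  # (T,) object array of class labels

    @property
    def medians(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    @property
    def targeting_mask(self) -> np.ndarray:
        return self.guide_class == "targeting"

    def summary(self) -> pd.DataFrame:
        qs = np.percentile(self.draws, [50, 2.5, 97.5, 5, 95], axis=0)
        return pd.DataFrame(
            {
                "guide_id": self.guide_ids,
                "median": qs[0],
                "lo95": qs[1],
                "hi95": qs[2],
                "lo90": qs[3],
                "hi90": qs[4],
                "guide_class": self.guide_class,
            }
        )


def _as_draws(posterior: Union[FitnessPosterior, np.ndarray]) -> np.ndarray:
    if isinstance(posterior, FitnessPosterior):
        return posterior.fitness_flat
    return np.atleast_2d(np.asarray(posterior, dtype=float))


def normalize_fitness(
    posterior: Union[FitnessPosterior, np.ndarray],
    library: LibraryDesign,
    guide_ids: Optional[Sequence[str]] = None,
) -> NormalizedFitness:
    """Divide all draws by the 70th centile (linear interpolation) of the
    targeting-guide posterior medians.  Idempotent.  Raw draw matrices of
    shape (n_draws, T) are accepted with an explicit ``guide_ids``."""
    draws = _as_draws(posterior)
    if guide_ids is None:
        if not isinstance(posterior, FitnessPosterior):
            raise ValueError("guide_ids required when passing a raw draw matrix")
        guide_ids = posterior.guide_ids
    guide_ids = list(guide_ids)
    if draws.shape[1] != len(guide_ids):
        raise ValueError("draws and guide_ids disagree on guide count")
    classes = np.array([library[g].guide_class for g in guide_ids], dtype=object)
    medians = np.median(draws, axis=0)
    targeting = classes == "targeting"
    if targeting.sum() < 3:
        raise ValueError("need at least 3 targeting guides to normalize")
    scalar = float(np.percentile(medians[targeting], 70))
    if scalar <= 0:
        raise ValueError("normalization scalar is non-positive (all-zero medians?)")
    return NormalizedFitness(
        guide_ids=guide_ids, draws=draws / scalar, scalar=scalar, guide_class=classes
    )


def call_nonneutral(normalized: NormalizedFitness, alpha: float = 0.05) -> pd.DataFrame:
    """Neutrality calls at FDR ``alpha`` (Benjamini-Hochberg over targeting guides).

    Posterior p-value p_t = 2*min(Pr(f_t <= 1), Pr(f_t >= 1)), floored at
    1/#draws; controls are reported unadjusted (p_adj = NaN, never called).
    Direction is low/high by the side of the median.
    """
    from statsmodels.stats.multitest import multipletests

    draws = normalized.draws
    n = draws.shape[0]
    p_lo = (draws <= 1.0).mean(axis=0)
    p_hi = (draws >= 1.0).mean(axis=0)
    p = np.clip(2.0 * np.minimum(p_lo, p_hi), 1.0 / n, 1.0)
    medians = normalized.medians
    direction = np.where(medians < 1.0, "low", "high")
    targeting = normalized.targeting_mask
    p_adj = np.full(len(p), np.nan)
    called = np.zeros(len(p), dtype=bool)
    if targeting.any():
        rej, adj, _, _ = multipletests(p[targeting], alpha=alpha, method="fdr_bh")
        p_adj[targeting] = adj
        called[targeting] = rej
    return pd.DataFrame(
        {
            "guide_id": normalized.guide_ids,
            "median": medians,
            "p": p,
            "p_adj": p_adj,
            "nonneutral": called,
            "direction": direction,
            "guide_class": normalized.guide_class,
        }
    )


@dataclass
class ScreenComparison:
    """Per-guide differentials (B - A) and outlier criteria between two screens."""

    guide_ids: list[str]
    table: pd.DataFrame  # per-guide medians, criteria flags
    gene_outliers: list[str]
    spearman_rho: float
    degraded: bool = False  # c2 unavailable (too few control guides)


def _rank_within(draws: np.ndarray) -> np.ndarray:
    order = np.argsort(draws, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(draws.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, draws.shape[1] + 1)[None, :]
    return ranks.astype(float)


def compare_datasets(
    postA: NormalizedFitness, postB: NormalizedFitness, library: LibraryDesign
) -> ScreenComparison:
    """Outlier analysis between two normalized posteriors over the same library.

    Draws are paired by index (chains are independent, so the pairing order is
    just the draw order); c1 = 95% interval of the fitness differential
    excludes 0; c2 = median differential outside the central 95% range of
    control-guide median differentials; c3 = 95% interval of the rank
    differential excludes 0.  A gene is an outlier when >= 2 of its guides
    pass c1 & c2 & c3.  Also reports the Spearman rho of median fitness.
    """
    if postA.guide_ids != postB.guide_ids:
        raise ValueError("posteriors cover different guide sets")
    guide_ids = postA.guide_ids
    n = min(postA.draws.shape[0], postB.draws.shape[0])
    A, B = postA.draws[:n], postB.draws[:n]
    diff = B - A
    lo, hi = np.percentile(diff, [2.5, 97.5], axis=0)
    c1 = (lo > 0) | (hi < 0)

    rank_diff = _rank_within(B) - _rank_within(A)
    rlo, rhi = np.percentile(rank_diff, [2.5, 97.5], axis=0)
    c3 = (rlo > 0) | (rhi < 0)

    med_diff = np.median(diff, axis=0)
    controls = ~postA.targeting_mask
    degraded = int(controls.sum()) < 5
    if degraded:
        c2 = np.zeros(len(guide_ids), dtype=bool)
    else:
        clo, chi = np.percentile(med_diff[controls], [2.5, 97.5])
        c2 = (med_diff < clo) | (med_diff > chi)

    passing = c1 & c2 & c3 & postA.targeting_mask
    genes = np.array(
        [library[g].gene if library[g].gene is not None else "" for g in guide_ids],
        dtype=object,
    )
    gene_outliers = sorted(
        {
            gene
            for gene in set(genes[passing]) - {""}
            if int((passing & (genes == gene)).sum()) >= 2
        }
    )
    rho = spearman_guides(postA, postB)
    table = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "gene": genes,
            "median_A": np.median(A, axis=0),
            "median_B": np.median(B, axis=0),
            "diff_median": med_diff,
            "diff_lo95": lo,
            "diff_hi95": hi,
            "rank_diff_median": np.median(rank_diff, axis=0),
            "c1_fitness_diff": c1,
            "c2_beyond_controls": c2,
            "c3_rank_diff": c3,
            "outlier_guide": passing,
        }
    )
    return ScreenComparison(
        guide_ids=guide_ids,
        table=table,
        gene_outliers=gene_outliers,
        spearman_rho=rho,
        degraded=degraded,
    )


@dataclass
class PosetGraph:
    """Transitively reduced order of guides with non-overlapping 95% intervals."""

    graph: nx.DiGraph  # edge a -> b means fitness(a) < fitness(b), Hasse-reduced
    resolved_pairs: int  # ordered pairs in the full (unreduced) interval order

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges())

    def to_dot(self) -> str:
        lines = ["digraph poset {"]
        for a, b in self.edges():
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def hasse_poset(summaries: pd.DataFrame) -> PosetGraph:
    """Hasse diagram of the strict interval order hi95(a) < lo95(b).

    ``summaries`` needs columns guide_id, lo95, hi95.  The full relation count
    (resolved pairs) is returned alongside the transitive reduction; the
    relation is irreflexive and transitive, hence acyclic.
    """
    ids = list(summaries["guide_id"])
    lo = summaries["lo95"].to_numpy(dtype=float)
    hi = summaries["hi95"].to_numpy(dtype=float)
    rel = hi[:, None] < lo[None, :]  # a < b
    np.fill_diagonal(rel, False)
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    a_idx, b_idx = np.nonzero(rel)
    g.add_edges_from((ids[a], ids[b]) for a, b in zip(a_idx, b_idx))
    reduced = nx.transitive_reduction(g)
    return PosetGraph(graph=reduced, resolved_pairs=int(rel.sum()))


def subsample_clones(
    dataset: ScreenDataset,
    fraction: Optional[float] = None,
    n: Optional[int] = None,
    seed: Optional[int] = None,
) -> ScreenDataset:
    """Uniform without-replacement subsample of clones (not reads); initial
    counts are untouched.  Exactly round(fraction * N) or ``n`` clones kept."""
    if (fraction is None) == (n is None):
        raise ValueError("give exactly one of fraction or n")
    pool = [
        (gid, size) for gid, sizes in dataset.clone_sizes.items() for size in sizes
    ]
    N = len(pool)
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n = int(round(fraction * N))
    if n > N:
        raise ValueError(f"requested {n} clones from {N}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(N, size=n, replace=False)
    new_sizes: dict[str, list[int]] = {gid: [] for gid in dataset.clone_sizes}
    for i in sorted(idx):
        gid, size = pool[i]
        new_sizes[gid].append(size)
    return ScreenDataset(
        sample_id=f"{dataset.sample_id}_sub",
        clone_sizes=new_sizes,
        initial_counts=dataset.initial_counts,
        library=dataset.library,
    )


def combine_replicates(datasets: Sequence[ScreenDataset]) -> ScreenDataset:
    """Concatenate clone lists of biological replicates sharing one library."""
    if not datasets:
        raise ValueError("no datasets")
    lib = datasets[0].library
    if any(d.library.name != lib.name for d in datasets):
        raise ValueError("datasets use different libraries")
    sizes: dict[str, list[int]] = {}
    for ds in datasets:
        for gid, v in ds.clone_sizes.items():
            sizes.setdefault(gid, []).extend(v)
    return ScreenDataset(
        sample_id="+".join(d.sample_id for d in datasets),
        clone_sizes=sizes,
        initial_counts=datasets[0].initial_counts,
        library=lib,
    )


def spearman_guides(
    postA: Union[NormalizedFitness, FitnessPosterior, np.ndarray],
    postB: Union[NormalizedFitness, FitnessPosterior, np.ndarray],
) -> float:
    """Spearman rank correlation of median fitness vectors (average ranks on ties)."""

    def med(p):
        if isinstance(p, NormalizedFitness):
            return p.medians
        if isinstance(p, FitnessPosterior):
            return np.median(p.fitness_flat, axis=0)
        return np.asarray(p, dtype=float)

    a, b = med(postA), med(postB)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need matched vectors of >= 3 guides")
    return float(stats.spearmanr(a, b).statistic)
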