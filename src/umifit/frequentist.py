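"""Delta-method ratio estimator of guide fitness, as a frequentist reference.

The estimator is the winsorized total clonal output over the plasmid initial
count, S_t / I_t (clone sizes winsorized at the per-guide empirical 98th
centile before summation), optionally divided by the dataset normalizer Z
(70th centile of the targeting-guide ratios).  The variance follows from a
first-order delta expansion of S_t / I_t with Var(S_t) estimated as the
winsorized sample variance times the clone count and I_t treated as a Poisson
count; the 95% CI is symmetric on the log scale to respect positivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitness_model import ScreenDataset
from .simulate import winsorize_sample

__all__ = ["FrequentistEstimate", "delta_method_fitness"]


@dataclass(frozen=True)
class FrequentistEstimate:
    guide_id: str
    estimate: float
    lo95: float
    hi95: float
    n_clones: int
    flagged: bool = False


def delta_method_fitness(
    dataset: ScreenDataset,
    winsor_upper_fraction: float = 0.02,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-guide fitness estimates with delta-method 95% CIs.

    Guides with zero initial counts are dropped; guides with zero clones get
    estimate 0 with a one-sided (flagged) interval.  Columns mirror the
    Bayesian summary: guide_id, estimate, lo95, hi95, n_clones, flagged.
    """
    rows = []
    for gid in dataset.library.guide_ids:
        I = dataset.initial_counts.get(gid, 0)
        if I <= 0:
            continue
        sizes = np.asarray(dataset.clone_sizes.get(gid, []), dtype=float)
        K = sizes.size
        if K == 0:
            rows.append((gid, 0.0, 0.0, np.nan, 0, np.nan, True))
            continue
        wins = winsorize_sample(sizes, winsor_upper_fraction)
        S = float(wins.sum())
        var_S = float(np.var(wins, ddof=1)) * K if K > 1 else float(wins[0] ** 2)
        ratio = S / I
        # delta expansion of S/I: Var ~ Var(S)/I^2 + S^2 Var(I)/I^4, Var(I) = I
        var_ratio = var_S / I**2 + S**2 / I**3
        rows.append((gid, ratio, np.sqrt(var_ratio), K, ratio, False))
    if not rows:
        raise ValueError("no guides with positive initial counts")

    out = []
    targeting = {g.guide_id for g in dataset.library.guides if g.is_targeting}
    zvals = [r[4] for r in rows if r[0] in targeting and len(r) == 6 and not r[5]]
    Z = float(np.percentile(zvals, 70)) if (normalize and len(zvals) >= 3) else 1.0
    for row in rows:
        if len(row) == 7:  # zero-clone guide
            gid = row[0]
            out.append(FrequentistEstimate(gid, 0.0, 0.0, np.nan, 0, flagged=True))
            continue
        gid, ratio, se, K, _, _ = row
        est = ratio / Z
        se_n = se / Z
        if est > 0:
            se_log = se_n / est
            lo = est * np.exp(-1.96 * se_log)
            hi = est * np.exp(1.96 * se_log)
        else:
            lo, hi = 0.0, np.nan
        out.append(FrequentistEstimate(gid, est, lo, hi, int(K)))
    return pd.DataFrame(
        [(e.guide_id, e.estimate, e.lo95, e.hi95, e.n_clones, e.flagged) for e in out],
        columns=["guide_id", "estimate", "lo95", "hi95", "n_clones", "flagged"],
    )
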