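"""Hierarchical Bayesian inference of per-guide winsorized-mean fitness.

Model
-----
For guide t with plasmid (initial) read count I_t, library proportions are
plug-in pi_t = I_t / sum(I).  In tumour replicate j the observed number of
clones K^j_t follows

    K^j_t ~ Poisson(c_j * pi_t * eps_t)

with a per-sample engraftment scale c_j and a per-guide engraftment factor
eps_t.  Clone sizes are iid draws from a zero-truncated count family whose
location is scaled by a per-guide factor phi_t (for the default two-component
negative-binomial mixture: component means phi_t*mu_{j,1}, phi_t*mu_{j,2},
dispersions r_{j,1}, r_{j,2}, and a sample-shared weight w_j; the
``mix_bnb_local`` variant carries a separate weight per guide).  Priors:
log phi_t ~ N(0, tau_phi), log eps_t ~ N(0, tau_eps) with half-Normal
hyperpriors on the tau's; sample-level nuisances get weak log-Normal priors;
mixture weights are Beta(1, 1).

The fitness of guide t at each posterior draw is

    f_t = eps_t * W_t

where W_t is the winsorized mean (top ``winsor_upper_fraction`` of the fitted
clone-size distribution revalued to its upper quantile, default top 2% to the
98th centile) of the guide's fitted distribution at that draw.  Grouped fits
share phi_t, eps_t and the tau's across replicate datasets, with per-dataset
c_j and family parameters; W_t is then the clone-total-weighted average of the
per-dataset winsorized means.

Sampling is adaptive Metropolis-within-Gibbs on log-transformed parameters:
vectorized elementwise updates for the guide-level factors (conditionally
independent given sample-level parameters), joint blocks per sample, and two
scale-decorrelation moves that shift mass between phi and the component means
(resp. eps and c) along the likelihood-invariant direction.  Convergence is
summarized by split-chain R-hat on the fitness draws.

Goodness of fit is a posterior-predictive check: the per-guide ``mean clone
size`` draws are means of replicate datasets simulated from the fitted guide
distribution (K^j_t clones per draw), so their credible interval accounts for
the sampling noise of the observed mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .library_design import LibraryDesign

__all__ = [
    "ScreenDataset",
    "ModelSpec",
    "FitnessPosterior",
    "count_pmf",
    "winsorized_mean_of_pmf",
    "fit_fitness_model",
    "gof_coverage",
    "log_marginal_likelihood",
    "stepping_stone_evidence",
    "split_rhat",
    "COUNT_FAMILIES",
]

logger = logging.getLogger(__name__)

COUNT_FAMILIES = ("poisson", "nb", "bnb", "ys", "mix_nb", "mix_bnb", "mix_bnb_local")


# ---------------------------------------------------------------------------
# Screen data container
# ---------------------------------------------------------------------------


@dataclass
class ScreenDataset:
    """Final clone sizes per guide plus plasmid initial counts, bound to a library."""

    sample_id: str
    clone_sizes: dict[str, list[int]]
    initial_counts: dict[str, int]
    library: LibraryDesign

    def __post_init__(self) -> None:
        for gid in self.clone_sizes:
            if gid not in self.library:
                raise ValueError(f"guide {gid!r} not in library {self.library.name!r}")
            if any(s < 1 for s in self.clone_sizes[gid]):
                raise ValueError(f"guide {gid!r}: clone sizes must be >= 1")
        for gid in self.initial_counts:
            if gid not in self.library:
                raise ValueError(f"guide {gid!r} not in library {self.library.name!r}")

    @classmethod
    def from_clone_table(cls, table, initial_counts: dict[str, int], library: LibraryDesign,
                         sample_id: Optional[str] = None) -> "ScreenDataset":
        sizes = {gid: [] for gid in library.guide_ids}
        for r in table.records:
            sizes.setdefault(r.guide_id, []).append(r.count)
        sizes = {g: sorted(v) for g, v in sizes.items()}
        return cls(sample_id or table.sample_id, sizes, dict(initial_counts), library)

    def n_clones(self, guide_id: str) -> int:
        return len(self.clone_sizes.get(guide_id, []))

    def total_clones(self) -> int:
        return sum(len(v) for v in self.clone_sizes.values())


def read_initial_counts(path: "str | Path") -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str})
    if "guide_id" not in df.columns or "reads" not in df.columns:
        raise ValueError(f"{path}: initial counts need columns guide_id, reads")
    return {str(g): int(r) for g, r in zip(df["guide_id"], df["reads"])}


def write_initial_counts(counts: dict[str, int], path: "str | Path") -> None:
    pd.DataFrame(
        {"guide_id": list(counts), "reads": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count-likelihood menu (zero-truncated pmfs on k >= 1)
# ---------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _zt(base_logpmf0: float, logpmf_k: np.ndarray) -> np.ndarray:
    # divide by 1 - pmf(0); base_logpmf0 is log pmf(0)
    return logpmf_k - np.log(-np.expm1(base_logpmf0))


def _bnb_logpmf(k, n, a, b):
    """Beta-negative-binomial log-pmf for real n > 0.

    f(k) = Gamma(n+k)/(k! Gamma(n)) * B(a+n, b+k) / B(a, b).  scipy's
    betanbinom restricts n to integers, which the guide-scaled hierarchy
    cannot honour, so the pmf is evaluated directly.
    """
    from scipy.special import betaln

    k = np.asarray(k, dtype=float)
    return (
        gammaln(n + k)
        - gammaln(k + 1.0)
        - gammaln(n)
        + betaln(a + n, b + k)
        - betaln(a, b)
    )


def count_pmf(family: str, params: dict, k) -> np.ndarray:
    """Zero-truncated pmf value(s) at integer k >= 1 for the likelihood menu.

    Families with mass at zero (poisson, nb, bnb and their mixtures) are
    renormalized by 1 - pmf(0); the Yule-Simon pmf rho*B(k, rho+1) is already
    supported on k >= 1.  Mixtures are w*f1 + (1-w)*f2 of the zero-truncated
    components' shared base measure (truncation applied to the mixture).
    """
    k = np.asarray(k)
    _require(np.all(k >= 1), "support is k >= 1 (observed clones)")
    if family == "poisson":
        lam = params["mu"]
        _require(lam > 0, "poisson mean must be > 0")
        return np.exp(_zt(-lam, stats.poisson.logpmf(k, lam)))
    if family == "nb":
        mu, r = params["mu"], params["r"]
        _require(mu > 0 and r > 0, "nb mean and dispersion must be > 0")
        p = r / (r + mu)
        return np.exp(_zt(r * math.log(p), stats.nbinom.logpmf(k, r, p)))
    if family == "bnb":
        n, a, b = params["n"], params["a"], params["b"]
        _require(n > 0 and a > 0 and b > 0, "bnb parameters must be > 0")
        lp0 = float(_bnb_logpmf(0, n, a, b))
        return np.exp(_zt(lp0, _bnb_logpmf(k, n, a, b)))
    if family == "ys":
        rho = params["rho"]
        _require(rho > 0, "yule-simon rho must be > 0")
        return np.exp(stats.yulesimon.logpmf(k, rho))
    if family in ("mix_nb", "mix_bnb", "mix_bnb_local"):
        w = params["w"]
        _require(0.0 <= w <= 1.0, "mixture weight must be in [0, 1]")
        base = "nb" if family == "mix_nb" else "bnb"
        if base == "nb":
            p1 = {"mu": params["mu1"], "r": params["r1"]}
            p2 = {"mu": params["mu2"], "r": params["r2"]}
            g0 = w * (p1["r"] / (p1["r"] + p1["mu"])) ** p1["r"] + (1 - w) * (
                p2["r"] / (p2["r"] + p2["mu"])
            ) ** p2["r"]
            _require(p1["mu"] > 0 and p2["mu"] > 0 and p1["r"] > 0 and p2["r"] > 0,
                     "nb mixture means/dispersions must be > 0")
            gk = w * stats.nbinom.pmf(k, p1["r"], p1["r"] / (p1["r"] + p1["mu"])) + (
                1 - w
            ) * stats.nbinom.pmf(k, p2["r"], p2["r"] / (p2["r"] + p2["mu"]))
        else:
            for key in ("n1", "a1", "b1", "n2", "a2", "b2"):
                _require(params[key] > 0, f"bnb mixture parameter {key} must be > 0")
            g0 = w * np.exp(_bnb_logpmf(0, params["n1"], params["a1"], params["b1"])) + (
                1 - w
            ) * np.exp(_bnb_logpmf(0, params["n2"], params["a2"], params["b2"]))
            gk = w * np.exp(_bnb_logpmf(k, params["n1"], params["a1"], params["b1"])) + (
                1 - w
            ) * np.exp(_bnb_logpmf(k, params["n2"], params["a2"], params["b2"]))
        return gk / (1.0 - g0)
    raise ValueError(f"unknown count family {family!r}")


_INFINITE_MEAN = {
    "ys": lambda p: p["rho"] <= 1,
    "bnb": lambda p: p["a"] <= 1,
    "mix_bnb": lambda p: p["a1"] <= 1 or p["a2"] <= 1,
    "mix_bnb_local": lambda p: p["a1"] <= 1 or p["a2"] <= 1,
}


def winsorized_mean_of_pmf(
    family: "str | Callable[[np.ndarray], np.ndarray]",
    params: Optional[dict] = None,
    upper_fraction: float = 0.02,
) -> float:
    """Winsorized mean of a zero-truncated count distribution.

    With q the smallest k such that CDF(k) >= 1 - upper_fraction, returns
    sum_{k<=q} k*pmf(k) + q*P(K > q).  ``family`` may be a menu name (with
    ``params``) or a callable pmf over integer arrays (support k >= 1).
    ``upper_fraction = 0`` requests the plain mean and raises for
    infinite-mean families.
    """
    _require(0.0 <= upper_fraction < 0.5, "upper_fraction must be in [0, 0.5)")
    if isinstance(family, str):
        if upper_fraction == 0.0 and family in _INFINITE_MEAN and _INFINITE_MEAN[family](params):
            raise ValueError(f"{family} with these parameters has infinite mean; winsorize")
        pmf = lambda kk: count_pmf(family, params, kk)  # noqa: E731
    else:
        pmf = family
    target = 1.0 - upper_fraction
    tail_eps = 1e-12 if upper_fraction == 0.0 else 0.0
    cum = 0.0
    partial = 0.0
    block, lo = 1024, 1
    while lo < (1 << 24):  # hard support cap guards against extreme tails
        k = np.arange(lo, lo + block)
        p = np.asarray(pmf(k), dtype=float)
        csum = cum + np.cumsum(p)
        if upper_fraction > 0.0:
            hit = np.flatnonzero(csum >= target)
            if len(hit):
                i = int(hit[0])
                q = int(k[i])
                partial += float((k[: i + 1] * p[: i + 1]).sum())
                cdf_q = float(csum[i])
                return partial + q * (1.0 - cdf_q)
        partial += float((k * p).sum())
        cum = float(csum[-1])
        if upper_fraction == 0.0 and 1.0 - cum < tail_eps:
            return partial
        lo += block
        block = min(block * 2, 1 << 20)
    if upper_fraction == 0.0:
        return partial  # tail numerically negligible
    raise RuntimeError(
        "winsorization quantile beyond the 2^24 support cap; "
        "the distribution's tail is too heavy for direct summation"
    )


def _nbmix_winsorized_mean(mu1, mu2, r1, r2, w, frac: float):
    """Vectorized winsorized mean of a zero-truncated NB mixture.

    Uses the partial-expectation identity sum_{k<=q} k f(k; r, p)
    = mu * F(q-1; r+1, p) and integer bisection on the mixture CDF.
    Arrays broadcast; pass w=1 for a single NB, r1 -> inf approximations are
    not needed (Poisson has its own analog).
    """
    mu1, mu2, r1, r2, w = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (mu1, mu2, r1, r2, w))
    )
    p1 = r1 / (r1 + mu1)
    p2 = r2 / (r2 + mu2)
    g0 = w * p1**r1 + (1.0 - w) * p2**r2
    mean = w * mu1 + (1.0 - w) * mu2
    if frac == 0.0:
        return mean / (1.0 - g0)

    def G(k):
        return w * stats.nbinom.cdf(k, r1, p1) + (1.0 - w) * stats.nbinom.cdf(k, r2, p2)

    target = 1.0 - frac * (1.0 - g0)  # untruncated-CDF form of ZT-CDF >= 1-frac
    hi = np.maximum(2.0 * mean, 8.0)
    for _ in range(64):
        bad = G(hi) < target
        if not bad.any():
            break
        hi = np.where(bad, hi * 2.0, hi)
    lo = np.zeros_like(hi)
    for _ in range(52):
        mid = np.floor((lo + hi) / 2.0)
        ok = G(mid) >= target
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid)
        if np.all(hi - lo <= 1.0):
            break
    q = np.maximum(hi, 1.0)
    partial = w * mu1 * stats.nbinom.cdf(q - 1.0, r1 + 1.0, p1) + (
        1.0 - w
    ) * mu2 * stats.nbinom.cdf(q - 1.0, r2 + 1.0, p2)
    return (partial + q * (1.0 - G(q))) / (1.0 - g0)


def _poisson_winsorized_mean(lam, frac: float):
    lam = np.asarray(lam, dtype=float)
    g0 = np.exp(-lam)
    if frac == 0.0:
        return lam / (1.0 - g0)
    target = 1.0 - frac * (1.0 - g0)
    hi = np.maximum(2.0 * lam, 8.0)
    for _ in range(64):
        bad = stats.poisson.cdf(hi, lam) < target
        if not bad.any():
            break
        hi = np.where(bad, hi * 2.0, hi)
    lo = np.zeros_like(hi)
    for _ in range(52):
        mid = np.floor((lo + hi) / 2.0)
        ok = stats.poisson.cdf(mid, lam) >= target
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid)
        if np.all(hi - lo <= 1.0):
            break
    q = np.maximum(hi, 1.0)
    partial = lam * stats.poisson.cdf(q - 1.0, lam)
    return (partial + q * (1.0 - stats.poisson.cdf(q, lam))) / (1.0 - g0)


# ---------------------------------------------------------------------------
# Family adapters for the hierarchical sampler
# ---------------------------------------------------------------------------


def _log1mexp(x):
    # log(1 - exp(x)) for x < 0, stable
    return np.log(-np.expm1(np.minimum(x, -1e-12)))


class _NbMixFamily:
    """Zero-truncated NB mixture; w=None means single NB."""

    def __init__(self, n_components: int, local_w: bool = False):
        self.n_components = n_components
        self.local_w = local_w
        # theta layout: [lmu_1..lmu_C, lr_1..lr_C, (logit w if C==2 and not local)]
        self.n_params = 2 * n_components + (1 if (n_components == 2 and not local_w) else 0)
        self.scale_shift = np.zeros(self.n_params)
        self.scale_shift[:n_components] = 1.0  # component means scale with phi

    def init_theta(self, sizes: np.ndarray, rng) -> np.ndarray:
        m = max(float(sizes.mean()), 1.5) if sizes.size else 5.0
        if self.n_components == 1:
            th = np.array([math.log(m), 0.0])
        else:
            th = np.array([math.log(max(0.4 * m, 1.0)), math.log(2.0 * m), 0.0, 0.0])
            if not self.local_w:
                th = np.append(th, 0.0)
        return th + rng.normal(0.0, 0.1, size=th.shape)

    def log_prior(self, theta: np.ndarray) -> float:
        lp = float(-0.5 * (theta[: 2 * self.n_components] ** 2).sum() / 25.0)
        if self.n_components == 2 and not self.local_w:
            x = theta[-1]
            lp += float(x - 2.0 * np.log1p(np.exp(x)))  # Beta(1,1) via logit Jacobian
        return lp

    def _components(self, theta, lphi_pts):
        C = self.n_components
        mus = [np.exp(theta[i] + lphi_pts) for i in range(C)]
        rs = [math.exp(theta[C + i]) for i in range(C)]
        return mus, rs

    def logpmf_points(self, k, theta, lphi_pts, logitw_pts=None):
        mus, rs = self._components(theta, lphi_pts)
        comp_lp = []
        comp_l0 = []
        for mu, r in zip(mus, rs):
            lp_r = r * np.log(r / (r + mu))
            comp_l0.append(lp_r)
            comp_lp.append(
                gammaln(k + r) - gammaln(r) - gammaln(k + 1.0) + lp_r + k * np.log(mu / (r + mu))
            )
        if self.n_components == 1:
            lp, l0 = comp_lp[0], comp_l0[0]
        else:
            if self.local_w:
                lw = -np.log1p(np.exp(-logitw_pts))
                l1mw = -np.log1p(np.exp(logitw_pts))
            else:
                x = theta[-1]
                lw = -np.log1p(np.exp(-x))
                l1mw = -np.log1p(np.exp(x))
            lp = np.logaddexp(lw + comp_lp[0], l1mw + comp_lp[1])
            l0 = np.logaddexp(lw + comp_l0[0], l1mw + comp_l0[1])
        return lp - _log1mexp(l0)

    def winsorized_mean(self, theta_draws, lphi_draws, frac, logitw_draws=None):
        # theta_draws: (D, P); lphi_draws: (D, T) -> (D, T)
        C = self.n_components
        lmu1 = theta_draws[:, [0]] + lphi_draws
        if C == 1:
            return _nbmix_winsorized_mean(
                np.exp(lmu1), np.exp(lmu1), np.exp(theta_draws[:, [1]]),
                np.exp(theta_draws[:, [1]]), 1.0, frac,
            )
        lmu2 = theta_draws[:, [1]] + lphi_draws
        r1 = np.exp(theta_draws[:, [2]])
        r2 = np.exp(theta_draws[:, [3]])
        if self.local_w:
            w = 1.0 / (1.0 + np.exp(-logitw_draws))
        else:
            w = 1.0 / (1.0 + np.exp(-theta_draws[:, [4]]))
        return _nbmix_winsorized_mean(np.exp(lmu1), np.exp(lmu2), r1, r2, w, frac)

    def sample_sizes(self, rng, theta, lphi_pts, logitw_pts=None):
        # Zero truncation applies to the mixture, so zero redraws must re-pick
        # the component (a mixture of truncated components is a different law).
        mus, rs = self._components(theta, lphi_pts)
        n = lphi_pts.shape[0]

        def draw(idx):
            if self.n_components == 1:
                mu = mus[0][idx]
                r = np.full(idx.size, rs[0])
            else:
                if self.local_w:
                    w = 1.0 / (1.0 + np.exp(-logitw_pts[idx]))
                else:
                    w = 1.0 / (1.0 + np.exp(-theta[-1]))
                pick1 = rng.random(idx.size) < w
                mu = np.where(pick1, mus[0][idx], mus[1][idx])
                r = np.where(pick1, rs[0], rs[1])
            return rng.negative_binomial(r, r / (r + mu))

        x = draw(np.arange(n))
        for _ in range(200):
            zero = np.flatnonzero(x == 0)
            if not zero.size:
                break
            x[zero] = draw(zero)
        x[x == 0] = 1
        return x


class _PoissonFamily:
    n_params = 1
    scale_shift = np.array([1.0])

    def init_theta(self, sizes, rng):
        m = max(float(sizes.mean()), 1.1) if sizes.size else 5.0
        return np.array([math.log(m)]) + rng.normal(0.0, 0.1, 1)

    def log_prior(self, theta):
        return float(-0.5 * (theta**2).sum() / 25.0)

    def logpmf_points(self, k, theta, lphi_pts, logitw_pts=None):
        lam = np.exp(theta[0] + lphi_pts)
        return k * np.log(lam) - lam - gammaln(k + 1.0) - _log1mexp(-lam)

    def winsorized_mean(self, theta_draws, lphi_draws, frac, logitw_draws=None):
        return _poisson_winsorized_mean(np.exp(theta_draws[:, [0]] + lphi_draws), frac)

    def sample_sizes(self, rng, theta, lphi_pts, logitw_pts=None):
        lam = np.exp(theta[0] + lphi_pts)
        x = rng.poisson(lam)
        for _ in range(200):
            zero = x == 0
            if not zero.any():
                break
            x[zero] = rng.poisson(lam[zero])
        x[x == 0] = 1
        return x


class _BnbMixFamily:
    """Zero-truncated beta-negative-binomial (mixture); guide scale acts on n.

    The shape is parametrized a = 1 + exp(la) so the fitted law always has a
    finite mean: this keeps the winsorization quantile on the data scale
    (via the Markov bound q <= mean/fraction) and makes the partial
    expectation identity k*f(k; n, a, b) = [n*b/(a-1)]*f(k-1; n+1, a-1, b+1)
    available.  Infinite-mean BNB laws remain accessible through the public
    ``count_pmf``/``winsorized_mean_of_pmf`` menu.
    """

    def __init__(self, n_components: int, local_w: bool = False):
        self.n_components = n_components
        self.local_w = local_w
        # layout: [ln_1..C, la_1..C (a = 1 + exp(la)), lb_1..C, (logit w)]
        self.n_params = 3 * n_components + (1 if (n_components == 2 and not local_w) else 0)
        self.scale_shift = np.zeros(self.n_params)
        self.scale_shift[:n_components] = 1.0

    def init_theta(self, sizes, rng):
        m = max(float(sizes.mean()), 1.5) if sizes.size else 5.0
        la0 = math.log(1.5)  # a = 2.5
        if self.n_components == 1:
            th = np.array([math.log(m), la0, 0.8])
        else:
            th = np.array(
                [math.log(max(0.4 * m, 1.0)), math.log(2.0 * m), la0, la0, 0.8, 0.8]
            )
            if not self.local_w:
                th = np.append(th, 0.0)
        return th + rng.normal(0.0, 0.1, size=th.shape)

    def log_prior(self, theta):
        lp = float(-0.5 * (theta[: 3 * self.n_components] ** 2).sum() / 25.0)
        if self.n_components == 2 and not self.local_w:
            x = theta[-1]
            lp += float(x - 2.0 * np.log1p(np.exp(x)))
        return lp

    def _pars(self, theta):
        C = self.n_components
        return (
            [theta[i] for i in range(C)],
            [1.0 + math.exp(theta[C + i]) for i in range(C)],
            [math.exp(theta[2 * C + i]) for i in range(C)],
        )

    def logpmf_points(self, k, theta, lphi_pts, logitw_pts=None):
        lns, avals, bvals = self._pars(theta)
        comp_lp, comp_l0 = [], []
        for ln, a, b in zip(lns, avals, bvals):
            n = np.exp(ln + lphi_pts)
            comp_lp.append(_bnb_logpmf(k, n, a, b))
            comp_l0.append(_bnb_logpmf(0, n, a, b))
        if self.n_components == 1:
            lp, l0 = comp_lp[0], comp_l0[0]
        else:
            if self.local_w:
                lw = -np.log1p(np.exp(-logitw_pts))
                l1mw = -np.log1p(np.exp(logitw_pts))
            else:
                x = theta[-1]
                lw = -np.log1p(np.exp(-x))
                l1mw = -np.log1p(np.exp(x))
            lp = np.logaddexp(lw + comp_lp[0], l1mw + comp_lp[1])
            l0 = np.logaddexp(lw + comp_l0[0], l1mw + comp_l0[1])
        return lp - _log1mexp(l0)

    def winsorized_mean(self, theta_draws, lphi_draws, frac, logitw_draws=None):
        # Explicit pmf grid per draw, bounded by the Markov bound
        # q <= mean/frac (finite mean is guaranteed by a > 1).  Thinned draws
        # keep the grid evaluations affordable.
        C = self.n_components
        D, T = lphi_draws.shape
        out = np.empty((D, T))
        for d in range(D):
            lns, avals, bvals = self._pars(theta_draws[d])
            ns = [np.exp(ln + lphi_draws[d]) for ln in lns]  # (T,)
            if C == 1:
                ws = [np.ones(T)]
            else:
                if self.local_w:
                    w = 1.0 / (1.0 + np.exp(-logitw_draws[d]))
                else:
                    w = np.full(T, 1.0 / (1.0 + math.exp(-theta_draws[d, -1])))
                ws = [w, 1.0 - w]
            mean = sum(
                wc * n * b / (a - 1.0) for wc, n, a, b in zip(ws, ns, avals, bvals)
            )
            if frac == 0.0:
                g0 = sum(
                    wc * np.exp(_bnb_logpmf(0, n, a, b))
                    for wc, n, a, b in zip(ws, ns, avals, bvals)
                )
                out[d] = mean / (1.0 - g0)
                continue
            kmax = int(min(np.ceil(mean.max() / frac) + 2, 60_000))
            k = np.arange(kmax + 1, dtype=float)
            pmf = sum(
                wc[:, None] * np.exp(_bnb_logpmf(k[None, :], n[:, None], a, b))
                for wc, n, a, b in zip(ws, ns, avals, bvals)
            )  # (T, K)
            cdf = np.cumsum(pmf, axis=1)
            g0 = pmf[:, 0]
            target = 1.0 - frac * (1.0 - g0)
            reached = cdf >= target[:, None]
            q = np.where(reached.any(axis=1), reached.argmax(axis=1), kmax)
            q = np.maximum(q, 1)
            kp = np.cumsum(k[None, :] * pmf, axis=1)
            rows = np.arange(T)
            partial = kp[rows, q]
            out[d] = (partial + q * (1.0 - cdf[rows, q])) / (1.0 - g0)
        return out

    def sample_sizes(self, rng, theta, lphi_pts, logitw_pts=None):
        # Zero redraws re-pick the mixture component (truncation of the mixture).
        lns, avals, bvals = self._pars(theta)
        m = lphi_pts.shape[0]

        def draw(idx):
            if self.n_components == 1:
                n = np.exp(lns[0] + lphi_pts[idx])
                a = np.full(idx.size, avals[0])
                b = np.full(idx.size, bvals[0])
            else:
                if self.local_w:
                    w = 1.0 / (1.0 + np.exp(-logitw_pts[idx]))
                else:
                    w = 1.0 / (1.0 + np.exp(-theta[-1]))
                pick1 = rng.random(idx.size) < w
                n = np.exp(np.where(pick1, lns[0], lns[1]) + lphi_pts[idx])
                a = np.where(pick1, avals[0], avals[1])
                b = np.where(pick1, bvals[0], bvals[1])
            p = rng.beta(a, b)
            return rng.negative_binomial(n, np.clip(p, 1e-9, 1 - 1e-9))

        x = draw(np.arange(m))
        for _ in range(200):
            zero = np.flatnonzero(x == 0)
            if not zero.size:
                break
            x[zero] = draw(zero)
        x[x == 0] = 1
        return x


def _ys_winsorized_mean(rho, frac: float):
    """Winsorized mean of a Yule-Simon law via the tail-sum identity.

    For a nonnegative integer variable, the mean winsorized at q equals
    sum_{j=0}^{q-1} sf(j); the Yule-Simon survival sf(j) = j*B(j, rho+1) is
    closed-form, so the sum is evaluated exactly up to 4096 terms and with
    the asymptotic tail sf(j) ~ Gamma(rho+1) * j^-rho beyond (relative error
    below 1e-3), keeping heavy tails (rho <= 1) tractable without grids.
    """
    from scipy.special import betaln

    rho = np.asarray(rho, dtype=float)

    def log_sf(j):
        # sf(j) = j * B(j, rho + 1); sf(0) = 1
        j = np.maximum(j, 1.0)
        return np.log(j) + betaln(j, rho + 1.0)

    # q = smallest k with sf(k) <= frac; bracket from the power-law inverse
    log_frac = math.log(frac)
    guess = np.exp((gammaln(rho + 1.0) - log_frac) / rho)
    hi = np.maximum(4.0 * guess + 4.0, 4.0)
    for _ in range(64):
        bad = log_sf(hi) > log_frac
        if not bad.any():
            break
        hi = np.where(bad, hi * 4.0, hi)
    lo = np.zeros_like(hi)
    for _ in range(80):
        mid = np.floor((lo + hi) / 2.0)
        ok = log_sf(mid) <= log_frac
        ok &= mid >= 1.0
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid)
        if np.all(hi - lo <= 1.0):
            break
    q = np.maximum(hi, 1.0)

    J = 4096
    j = np.arange(1, J)
    sf_grid = np.exp(
        np.log(j)[:, None] + betaln(j[:, None], rho.reshape(1, -1) + 1.0)
    )
    sf_grid = sf_grid.reshape((J - 1,) + rho.shape)
    jq = np.minimum(q - 1.0, J - 1.0)  # number of grid terms to include
    mask = j.reshape((J - 1,) + (1,) * rho.ndim) <= jq
    exact = 1.0 + (sf_grid * mask).sum(axis=0)  # sf(0) = 1
    # analytic continuation of the sum for j in [J, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.exp(gammaln(rho + 1.0))
        tail = np.where(
            np.abs(rho - 1.0) < 1e-8,
            coef * (np.log(np.maximum(q, J)) - math.log(J)),
            coef * (np.maximum(q, J) ** (1.0 - rho) - J ** (1.0 - rho)) / (1.0 - rho),
        )
    tail = np.where(q > J, tail, 0.0)
    return exact + tail


class _YuleSimonFamily:
    """Yule-Simon clone sizes; the guide factor acts inversely on the shape
    (effective log rho_t = log rho_j - log phi_t), the only monotone scale
    handle a YS law offers since its mean may be infinite."""

    n_params = 1
    # effective shape is lrho - lphi, so the likelihood-invariant direction
    # pairs lphi - delta with lrho - delta
    scale_shift = np.array([-1.0])

    def init_theta(self, sizes, rng):
        return np.array([math.log(1.5)]) + rng.normal(0.0, 0.1, 1)

    def log_prior(self, theta):
        return float(-0.5 * (theta**2).sum() / 25.0)

    def logpmf_points(self, k, theta, lphi_pts, logitw_pts=None):
        rho = np.exp(theta[0] - lphi_pts)
        return np.log(rho) + gammaln(k) + gammaln(rho + 1.0) - gammaln(k + rho + 1.0)

    def winsorized_mean(self, theta_draws, lphi_draws, frac, logitw_draws=None):
        rho = np.exp(theta_draws[:, [0]] - lphi_draws)
        return _ys_winsorized_mean(rho, max(frac, 1e-4))

    def sample_sizes(self, rng, theta, lphi_pts, logitw_pts=None):
        rho = np.exp(theta[0] - lphi_pts)
        # YS is a geometric with p = exp(-W), W ~ Exp(rho), shifted to k >= 1
        w = rng.exponential(1.0 / rho)
        return rng.geometric(np.clip(np.exp(-w), 1e-12, 1.0))


def _get_family(name: str):
    if name == "poisson":
        return _PoissonFamily()
    if name == "nb":
        return _NbMixFamily(1)
    if name == "mix_nb":
        return _NbMixFamily(2)
    if name == "bnb":
        return _BnbMixFamily(1)
    if name == "mix_bnb":
        return _BnbMixFamily(2)
    if name == "mix_bnb_local":
        return _BnbMixFamily(2, local_w=True)
    if name == "ys":
        return _YuleSimonFamily()
    raise ValueError(f"unknown likelihood {name!r}; choose from {COUNT_FAMILIES}")


# Families whose winsorized mean has a vectorized closed-ish form; others are
# computed on thinned draws.
_FAST_W = {"poisson", "nb", "mix_nb"}


# ---------------------------------------------------------------------------
# Model specification and posterior container
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    likelihood: str = "mix_nb"
    winsor_upper_fraction: float = 0.02
    tau_phi_scale: float = 1.0  # half-Normal hyperprior scale on tau_phi
    tau_eps_scale: float = 1.0
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    ppc_draws: int = 400  # posterior-predictive replicates for the GOF check
    slow_w_draws: int = 100  # fitness-draw thinning for families without a fast winsorized mean

    def __post_init__(self) -> None:
        if not 0.0 <= self.winsor_upper_fraction < 0.5:
            raise ValueError("winsor_upper_fraction must be in [0, 0.5)")
        if self.likelihood not in COUNT_FAMILIES:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("chains, warmup and draws must be >= 1")


@dataclass
class FitnessPosterior:
    """Posterior draws of winsorized-mean fitness, ranks and PPC mean sizes."""

    guide_ids: list[str]
    fitness: np.ndarray  # (chains, draws, T)
    ranks: np.ndarray  # (chains, draws, T), permutation of 1..T per draw
    mean_size: np.ndarray  # (chains, ppc_draws, T) posterior-predictive mean clone size
    rhat: np.ndarray  # (T,)
    converged: bool
    excluded_guides: list[str]
    clone_totals: np.ndarray  # (T,) pooled observed clone counts
    spec: ModelSpec

    @property
    def fitness_flat(self) -> np.ndarray:
        return self.fitness.reshape(-1, self.fitness.shape[-1])

    @property
    def mean_size_flat(self) -> np.ndarray:
        return self.mean_size.reshape(-1, self.mean_size.shape[-1])

    def summary(self) -> pd.DataFrame:
        f = self.fitness_flat
        r = self.ranks.reshape(-1, self.ranks.shape[-1])
        qs = np.percentile(f, [50, 2.5, 97.5, 5, 95], axis=0)
        rq = np.percentile(r, [50, 2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "guide_id": self.guide_ids,
                "median": qs[0],
                "lo95": qs[1],
                "hi95": qs[2],
                "lo90": qs[3],
                "hi90": qs[4],
                "rank_median": rq[0],
                "rank_lo95": rq[1],
                "rank_hi95": rq[2],
                "n_clones": self.clone_totals,
                "rhat": self.rhat,
            }
        )


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain R-hat per parameter from (chains, draws, T) arrays."""
    c, d, t = draws.shape
    half = d // 2
    if half < 2:
        return np.full(t, np.nan)
    seqs = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, n = seqs.shape[0], seqs.shape[1]
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


class _PreparedData:
    def __init__(self, datasets: Sequence[ScreenDataset]):
        libs = {id(d.library) for d in datasets}
        if len({d.library.name for d in datasets}) != 1 and len(libs) != 1:
            raise ValueError("all datasets must share one library")
        self.library = datasets[0].library
        initial = datasets[0].initial_counts
        all_ids = self.library.guide_ids
        self.excluded = [g for g in all_ids if initial.get(g, 0) <= 0]
        self.guide_ids = [g for g in all_ids if initial.get(g, 0) > 0]
        if self.excluded:
            logger.warning("excluding %d guides with zero initial counts", len(self.excluded))
        T = len(self.guide_ids)
        if T < 2:
            raise ValueError("need at least 2 guides with positive initial counts")
        I = np.array([initial[g] for g in self.guide_ids], dtype=float)
        self.pi = I / I.sum()
        self.lpi = np.log(self.pi)
        self.T = T
        self.J = len(datasets)
        self.K = np.zeros((self.J, T), dtype=np.int64)
        self.vals: list[np.ndarray] = []
        self.wts: list[np.ndarray] = []
        self.gidx: list[np.ndarray] = []
        self.rep_gidx: list[np.ndarray] = []  # one entry per clone, for PPC
        for j, ds in enumerate(datasets):
            v_list, w_list, g_list, rep = [], [], [], []
            for t, gid in enumerate(self.guide_ids):
                sizes = np.asarray(ds.clone_sizes.get(gid, []), dtype=np.int64)
                self.K[j, t] = sizes.size
                if sizes.size:
                    uq, ct = np.unique(sizes, return_counts=True)
                    v_list.append(uq)
                    w_list.append(ct)
                    g_list.append(np.full(uq.size, t, dtype=np.int64))
                    rep.append(np.full(sizes.size, t, dtype=np.int64))
            self.vals.append(np.concatenate(v_list).astype(float) if v_list else np.empty(0))
            self.wts.append(np.concatenate(w_list).astype(float) if w_list else np.empty(0))
            self.gidx.append(np.concatenate(g_list) if g_list else np.empty(0, dtype=np.int64))
            self.rep_gidx.append(np.concatenate(rep) if rep else np.empty(0, dtype=np.int64))
        self.Ksum_t = self.K.sum(axis=0).astype(float)
        self.clone_totals_j = self.K.sum(axis=1).astype(float)
        self.obs_mean = np.where(
            self.Ksum_t > 0,
            np.array(
                [
                    sum(sum(ds.clone_sizes.get(g, [])) for ds in datasets)
                    for g in self.guide_ids
                ],
                dtype=float,
            )
            / np.maximum(self.Ksum_t, 1.0),
            np.nan,
        )


class _AdaptiveStep:
    def __init__(self, step: float, target: float = 0.44):
        self.log_step = math.log(step)
        self.target = target
        self.n = 0

    @property
    def step(self) -> float:
        return math.exp(self.log_step)

    def adapt(self, acc_rate: float) -> None:
        self.n += 1
        self.log_step += (acc_rate - self.target) / self.n**0.6


def _run_chain(data: _PreparedData, spec: ModelSpec, family, rng: np.random.Generator,
               beta: float = 1.0, collect: bool = True):
    T, J = data.T, data.J
    local_w = getattr(family, "local_w", False)

    lphi = rng.normal(0.0, 0.05, T)
    leps = rng.normal(0.0, 0.05, T)
    ltau_phi = math.log(0.3) + rng.normal(0.0, 0.1)
    ltau_eps = math.log(0.3) + rng.normal(0.0, 0.1)
    lc = np.log(np.maximum(data.clone_totals_j, 1.0)) + rng.normal(0.0, 0.05, J)
    theta = np.stack(
        [family.init_theta(data.vals[j].repeat(data.wts[j].astype(int)) if data.vals[j].size else np.empty(0), rng) for j in range(J)]
    )
    logit_w = rng.normal(0.0, 0.1, T) if local_w else None

    pts = [
        family.logpmf_points(
            data.vals[j], theta[j], lphi[data.gidx[j]],
            logit_w[data.gidx[j]] if local_w else None,
        )
        for j in range(J)
    ]

    def guide_clone_ll(pt_list):
        acc = np.zeros(T)
        for j in range(J):
            if data.vals[j].size:
                acc += np.bincount(data.gidx[j], weights=data.wts[j] * pt_list[j], minlength=T)
        return acc

    cl_guide = guide_clone_ll(pts)

    steps = {
        "eps": _AdaptiveStep(0.2),
        "phi": _AdaptiveStep(0.2),
        "w": _AdaptiveStep(0.3),
        "sample": _AdaptiveStep(0.15, target=0.28),
        "tau_phi": _AdaptiveStep(0.3),
        "tau_eps": _AdaptiveStep(0.3),
        "scale_phi": _AdaptiveStep(0.1),
        "scale_eps": _AdaptiveStep(0.1),
    }

    kept = {"lphi": [], "leps": [], "theta": [], "logit_w": [], "loglik": []}

    def poisson_ll_t(leps_vec):
        # per-guide Poisson terms summed over samples
        lam_sum = np.exp(lc).sum() * data.pi * np.exp(leps_vec)
        return beta * (data.Ksum_t * leps_vec - lam_sum)

    n_iter = spec.warmup + spec.draws
    for it in range(n_iter):
        warm = it < spec.warmup

        # --- eps block (elementwise) ---
        prop = leps + steps["eps"].step * rng.standard_normal(T)
        tau_e = math.exp(ltau_eps)
        delta = (
            poisson_ll_t(prop)
            - poisson_ll_t(leps)
            + (leps**2 - prop**2) / (2.0 * tau_e**2)
        )
        acc = np.log(rng.random(T)) < delta
        leps = np.where(acc, prop, leps)
        if warm:
            steps["eps"].adapt(float(acc.mean()))

        # --- phi block (elementwise) ---
        prop = lphi + steps["phi"].step * rng.standard_normal(T)
        pts_p = [
            family.logpmf_points(
                data.vals[j], theta[j], prop[data.gidx[j]],
                logit_w[data.gidx[j]] if local_w else None,
            )
            for j in range(J)
        ]
        cl_prop = guide_clone_ll(pts_p)
        tau_p = math.exp(ltau_phi)
        delta = beta * (cl_prop - cl_guide) + (lphi**2 - prop**2) / (2.0 * tau_p**2)
        acc = np.log(rng.random(T)) < delta
        if acc.any():
            lphi = np.where(acc, prop, lphi)
            cl_guide = np.where(acc, cl_prop, cl_guide)
            for j in range(J):
                if data.vals[j].size:
                    m = acc[data.gidx[j]]
                    pts[j] = np.where(m, pts_p[j], pts[j])
        if warm:
            steps["phi"].adapt(float(acc.mean()))

        # --- local mixture weights (elementwise) ---
        if local_w:
            prop_w = logit_w + steps["w"].step * rng.standard_normal(T)
            pts_p = [
                family.logpmf_points(
                    data.vals[j], theta[j], lphi[data.gidx[j]], prop_w[data.gidx[j]]
                )
                for j in range(J)
            ]
            cl_prop = guide_clone_ll(pts_p)
            prior_delta = (
                prop_w - 2.0 * np.log1p(np.exp(prop_w)) - (logit_w - 2.0 * np.log1p(np.exp(logit_w)))
            )
            delta = beta * (cl_prop - cl_guide) + prior_delta
            acc = np.log(rng.random(T)) < delta
            if acc.any():
                logit_w = np.where(acc, prop_w, logit_w)
                cl_guide = np.where(acc, cl_prop, cl_guide)
                for j in range(J):
                    if data.vals[j].size:
                        m = acc[data.gidx[j]]
                        pts[j] = np.where(m, pts_p[j], pts[j])
            if warm:
                steps["w"].adapt(float(acc.mean()))

        # --- per-sample joint block (theta_j, lc_j) ---
        s = steps["sample"].step
        n_acc = 0
        eps_weighted = (data.pi * np.exp(leps)).sum()
        for j in range(J):
            th_p = theta[j] + s * rng.standard_normal(family.n_params)
            lc_p = lc[j] + s * rng.standard_normal()
            pts_pj = family.logpmf_points(
                data.vals[j], th_p, lphi[data.gidx[j]],
                logit_w[data.gidx[j]] if local_w else None,
            )
            d_clone = float((data.wts[j] * (pts_pj - pts[j])).sum()) if data.vals[j].size else 0.0
            d_pois = data.clone_totals_j[j] * (lc_p - lc[j]) - (
                math.exp(lc_p) - math.exp(lc[j])
            ) * eps_weighted
            d_prior = family.log_prior(th_p) - family.log_prior(theta[j]) + (
                lc[j] ** 2 - lc_p**2
            ) / (2.0 * 20.0**2)
            if math.log(rng.random()) < beta * (d_clone + d_pois) + d_prior:
                theta[j] = th_p
                lc[j] = lc_p
                pts[j] = pts_pj
                n_acc += 1
        cl_guide = guide_clone_ll(pts)
        if warm:
            steps["sample"].adapt(n_acc / J)

        # --- hyper tau updates ---
        for nm, vec, scale in (
            ("tau_phi", lphi, spec.tau_phi_scale),
            ("tau_eps", leps, spec.tau_eps_scale),
        ):
            cur = ltau_phi if nm == "tau_phi" else ltau_eps
            prop_l = cur + steps[nm].step * rng.standard_normal()
            def tau_lp(lt):
                tau = math.exp(lt)
                return (
                    -0.5 * float((vec**2).sum()) / tau**2
                    - T * lt
                    - 0.5 * tau**2 / scale**2
                    + lt  # Jacobian of tau = exp(lt) for the half-Normal prior
                )
            a = tau_lp(prop_l) - tau_lp(cur)
            if math.log(rng.random()) < a:
                if nm == "tau_phi":
                    ltau_phi = prop_l
                else:
                    ltau_eps = prop_l
                if warm:
                    steps[nm].adapt(1.0)
            elif warm:
                steps[nm].adapt(0.0)

        # --- scale-decorrelation moves (likelihood-invariant directions) ---
        dlt = steps["scale_phi"].step * rng.standard_normal()
        lphi_p = lphi - dlt
        th_p_all = theta + dlt * family.scale_shift
        tau_p = math.exp(ltau_phi)
        d_prior = float(((lphi**2 - lphi_p**2) / (2.0 * tau_p**2)).sum()) + sum(
            family.log_prior(th_p_all[j]) - family.log_prior(theta[j]) for j in range(J)
        )
        if math.log(rng.random()) < d_prior:
            lphi = lphi_p
            theta = th_p_all
            # pointwise clone logpmfs are invariant along this direction
            if warm:
                steps["scale_phi"].adapt(1.0)
        elif warm:
            steps["scale_phi"].adapt(0.0)

        dlt = steps["scale_eps"].step * rng.standard_normal()
        leps_p = leps - dlt
        lc_p = lc + dlt
        tau_e = math.exp(ltau_eps)
        d_prior = float(((leps**2 - leps_p**2) / (2.0 * tau_e**2)).sum()) + float(
            ((lc**2 - lc_p**2) / (2.0 * 20.0**2)).sum()
        )
        if math.log(rng.random()) < d_prior:
            leps = leps_p
            lc = lc_p
            if warm:
                steps["scale_eps"].adapt(1.0)
        elif warm:
            steps["scale_eps"].adapt(0.0)

        if collect and not warm:
            kept["lphi"].append(lphi.copy())
            kept["leps"].append(leps.copy())
            kept["theta"].append(theta.copy())
            if local_w:
                kept["logit_w"].append(logit_w.copy())
            ll = float(cl_guide.sum()) + float(
                (data.K * (np.log(data.pi)[None, :] + leps[None, :] + lc[:, None])).sum()
                - (np.exp(lc)[:, None] * data.pi[None, :] * np.exp(leps)[None, :]).sum()
            )
            kept["loglik"].append(ll)

    return kept


def _chain_fitness(data: _PreparedData, spec: ModelSpec, family, kept, rng):
    """Winsorized-mean fitness, ranks and PPC mean sizes for one chain."""
    local_w = getattr(family, "local_w", False)
    lphi = np.asarray(kept["lphi"])  # (D, T)
    leps = np.asarray(kept["leps"])
    theta = np.asarray(kept["theta"])  # (D, J, P)
    logit_w = np.asarray(kept["logit_w"]) if local_w else None
    D, T = lphi.shape
    frac = spec.winsor_upper_fraction

    if spec.likelihood in _FAST_W:
        w_idx = np.arange(D)
    else:
        w_idx = np.unique(np.linspace(0, D - 1, min(spec.slow_w_draws, D)).astype(int))
    Wsum = np.zeros((len(w_idx), T))
    for j in range(data.J):
        Wj = family.winsorized_mean(
            theta[w_idx, j, :], lphi[w_idx], frac,
            logit_w[w_idx] if local_w else None,
        )
        Wsum += data.clone_totals_j[j] * Wj
    W = Wsum / max(data.clone_totals_j.sum(), 1.0)
    fitness = np.exp(leps[w_idx]) * W
    order = np.argsort(fitness, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(len(w_idx))[:, None]
    ranks[rows, order] = np.arange(1, T + 1)[None, :]

    ppc_idx = np.unique(np.linspace(0, D - 1, min(spec.ppc_draws, D)).astype(int))
    mean_size = np.full((len(ppc_idx), T), np.nan)
    denom = np.maximum(data.Ksum_t, 1.0)
    for i, d in enumerate(ppc_idx):
        tot = np.zeros(T)
        for j in range(data.J):
            g = data.rep_gidx[j]
            if not g.size:
                continue
            sizes = family.sample_sizes(
                rng, theta[d, j], lphi[d][g],
                logit_w[d][g] if local_w else None,
            )
            tot += np.bincount(g, weights=sizes.astype(float), minlength=T)
        mean_size[i] = np.where(data.Ksum_t > 0, tot / denom, np.nan)
    return fitness, ranks, mean_size


def fit_fitness_model(
    datasets: "ScreenDataset | Sequence[ScreenDataset]", spec: Optional[ModelSpec] = None
) -> FitnessPosterior:
    """Fit the hierarchical model by MCMC; grouped when several datasets are given.

    Returns per-guide posterior draws of fitness f_t = eps_t * W_t, per-draw
    ranks, posterior-predictive mean clone sizes, and split-chain R-hat
    diagnostics.  Guides with zero initial counts are excluded (logged).
    A fit with R-hat > 1.05 on more than 5% of guides is flagged
    (``converged = False``) rather than silently returned.
    """
    if isinstance(datasets, ScreenDataset):
        datasets = [datasets]
    spec = spec or ModelSpec()
    family = _get_family(spec.likelihood)
    data = _PreparedData(datasets)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)

    fit_list, rank_list, ppc_list = [], [], []
    for c in range(spec.chains):
        rng = np.random.default_rng(seeds[c])
        kept = _run_chain(data, spec, family, rng)
        f, r, m = _chain_fitness(data, spec, family, kept, rng)
        fit_list.append(f)
        rank_list.append(r)
        ppc_list.append(m)

    fitness = np.stack(fit_list)
    ranks = np.stack(rank_list)
    mean_size = np.stack(ppc_list)
    rhat = split_rhat(fitness)
    frac_bad = float(np.mean(rhat > 1.05)) if np.isfinite(rhat).any() else 0.0
    converged = frac_bad <= 0.05
    if not converged:
        logger.warning(
            "fitness fit flagged: split R-hat > 1.05 for %.1f%% of guides", 100 * frac_bad
        )
    return FitnessPosterior(
        guide_ids=data.guide_ids,
        fitness=fitness,
        ranks=ranks,
        mean_size=mean_size,
        rhat=rhat,
        converged=converged,
        excluded_guides=data.excluded,
        clone_totals=data.Ksum_t.astype(int),
        spec=spec,
    )


def gof_coverage(
    datasets: "ScreenDataset | Sequence[ScreenDataset]",
    posterior: FitnessPosterior,
    level: float = 0.90,
) -> float:
    """Percentage of guides whose observed mean clone size lies inside the
    equal-tailed ``level`` posterior-predictive interval of the modeled mean.

    Guides with zero observed clones are excluded from the denominator.
    Close to 100*level indicates a well-fitting clone-size likelihood.
    """
    if isinstance(datasets, ScreenDataset):
        datasets = [datasets]
    data = _PreparedData(datasets)
    if data.guide_ids != posterior.guide_ids:
        raise ValueError("posterior and datasets disagree on guide set")
    ok = data.Ksum_t > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("gof_coverage: excluding %d guides with zero clones", n_excluded)
    m = posterior.mean_size_flat[:, ok]
    alpha = (1.0 - level) / 2.0
    lo = np.nanpercentile(m, 100 * alpha, axis=0)
    hi = np.nanpercentile(m, 100 * (1 - alpha), axis=0)
    obs = data.obs_mean[ok]
    inside = (obs >= lo) & (obs <= hi)
    return float(100.0 * inside.mean())


# ---------------------------------------------------------------------------
# Stepping-stone marginal likelihood (optional)
# ---------------------------------------------------------------------------


def stepping_stone_evidence(
    log_prior: Callable[[np.ndarray], float],
    log_lik: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    seed: int,
    n_rungs: int = 16,
    warmup: int = 200,
    draws: int = 200,
    step0: float = 0.3,
    ladder_power: float = 3.0,
) -> tuple[float, float]:
    """Generic stepping-stone estimate of log marginal likelihood.

    Power posteriors prior * lik^beta over a cubic temperature ladder
    beta_s = (s / S)**ladder_power, one adaptive random-walk Metropolis chain
    per rung.  Returns (log_ml, mc_standard_error); the SE is a per-rung
    delta-method estimate summed under an independence approximation and is
    therefore an optimistic lower bound when chains mix slowly.
    """
    rng = np.random.default_rng(seed)
    dim = len(theta0)
    betas = (np.arange(n_rungs + 1) / n_rungs) ** ladder_power
    theta = np.asarray(theta0, dtype=float).copy()
    log_ml = 0.0
    var_total = 0.0
    for s in range(n_rungs):
        beta = betas[s]
        dbeta = betas[s + 1] - beta
        step = step0
        cur_lp = log_prior(theta) + beta * log_lik(theta)
        ll_draws = np.empty(draws)
        n = 0
        for it in range(warmup + draws):
            prop = theta + step * rng.standard_normal(dim)
            lp = log_prior(prop)
            if np.isfinite(lp):
                lp += beta * log_lik(prop)
                if math.log(rng.random()) < lp - cur_lp:
                    theta, cur_lp = prop, lp
                    accepted = True
                else:
                    accepted = False
            else:
                accepted = False
            if it < warmup:
                n += 1
                step = math.exp(math.log(step) + (float(accepted) - 0.28) / n**0.6)
            else:
                ll_draws[it - warmup] = log_lik(theta)
        x = dbeta * ll_draws
        xmax = x.max()
        ex = np.exp(x - xmax)
        log_ml += xmax + math.log(ex.mean())
        var_total += float(ex.var(ddof=1) / (len(ex) * ex.mean() ** 2))
    return log_ml, math.sqrt(var_total)


def log_marginal_likelihood(
    dataset: ScreenDataset,
    spec: Optional[ModelSpec] = None,
    n_rungs: int = 16,
    warmup: int = 300,
    draws: int = 300,
) -> tuple[float, float]:
    """Stepping-stone log marginal likelihood of the hierarchical model for one
    dataset; returns (estimate, MC standard error).  Reproducible under
    ``spec.seed``.  Intended for likelihood-family comparison at small scale;
    the random-walk kernel limits accuracy on large guide sets."""
    spec = spec or ModelSpec()
    family = _get_family(spec.likelihood)
    data = _PreparedData([dataset])
    local_w = getattr(family, "local_w", False)
    T = data.T
    P = family.n_params
    # state: [lphi(T), leps(T), theta(P), lc, ltau_phi, ltau_eps, (logit_w(T))]
    n_dim = 2 * T + P + 3 + (T if local_w else 0)

    def unpack(x):
        lphi = x[:T]
        leps = x[T : 2 * T]
        theta = x[2 * T : 2 * T + P]
        lc = x[2 * T + P]
        lt_phi = x[2 * T + P + 1]
        lt_eps = x[2 * T + P + 2]
        lw = x[2 * T + P + 3 :] if local_w else None
        return lphi, leps, theta, lc, lt_phi, lt_eps, lw

    def log_prior(x):
        lphi, leps, theta, lc, lt_phi, lt_eps, lw = unpack(x)
        t_phi, t_eps = math.exp(lt_phi), math.exp(lt_eps)
        lp = -0.5 * float((lphi**2).sum()) / t_phi**2 - T * lt_phi
        lp += -0.5 * float((leps**2).sum()) / t_eps**2 - T * lt_eps
        lp += -0.5 * t_phi**2 / spec.tau_phi_scale**2 + lt_phi
        lp += -0.5 * t_eps**2 / spec.tau_eps_scale**2 + lt_eps
        lp += -0.5 * lc**2 / 20.0**2
        lp += family.log_prior(theta)
        if local_w:
            lp += float((lw - 2.0 * np.log1p(np.exp(lw))).sum())
        return lp

    def log_lik(x):
        lphi, leps, theta, lc, _, _, lw = unpack(x)
        ll = float(
            (data.K[0] * (data.lpi + leps + lc)).sum()
            - math.exp(lc) * float((data.pi * np.exp(leps)).sum())
            - gammaln(data.K[0] + 1.0).sum()
        )
        if data.vals[0].size:
            pts = family.logpmf_points(
                data.vals[0], theta, lphi[data.gidx[0]],
                lw[data.gidx[0]] if local_w else None,
            )
            if not np.all(np.isfinite(pts)):
                return -np.inf
            ll += float((data.wts[0] * pts).sum())
        return ll

    rng0 = np.random.default_rng(spec.seed)
    sizes = data.vals[0].repeat(data.wts[0].astype(int)) if data.vals[0].size else np.empty(0)
    theta0 = np.concatenate(
        [
            np.zeros(2 * T),
            family.init_theta(sizes, rng0),
            [math.log(max(data.clone_totals_j[0], 1.0)), math.log(0.3), math.log(0.3)],
        ]
        + ([np.zeros(T)] if local_w else [])
    )
    return stepping_stone_evidence(
        log_prior, log_lik, theta0, seed=spec.seed, n_rungs=n_rungs, warmup=warmup, draws=draws
    )
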