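"""Statistical comparison of topologies and marker scores.

ΔLL (free minus constrained log-likelihood), RELL bootstrap of
per-site log-likelihood vectors, the approximately-unbiased (AU) test
via Shimodaira's multiscale bootstrap, Bonferroni thresholds, and the
Wilcoxon rank-sum and Pearson correlation wrappers used in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import Alignment
from .likelihood import log_likelihood, optimize_branch_lengths
from .model import SubstitutionModel

DEFAULT_AU_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


class TopologyTestError(ValueError):
    pass


@dataclass
class TopologyTestResult:
    gene_id: str
    ll_free: float
    ll_constrained: float
    delta_ll: float
    au_p: dict[str, float] = field(default_factory=dict)
    n_rell_replicates: int = 0
    scales: tuple = ()
    bonferroni_alpha: float | None = None


def delta_ll(ll_free: float, ll_constrained: float, tol: float = 1e-6) -> float:
    """ΔLL = ll_free − ll_constrained, clipped at zero.

    The free search explores a superset of the constrained space, so a
    constrained likelihood exceeding the free one beyond tolerance
    indicates a failed search and raises.
    """
    if not (np.isfinite(ll_free) and np.isfinite(ll_constrained)):
        raise TopologyTestError("non-finite log-likelihoods")
    d = ll_free - ll_constrained
    if d < -tol:
        raise TopologyTestError(
            f"constrained tree better than free tree by {-d:.6g}: search failure"
        )
    return max(d, 0.0)


def site_ll_matrix(trees, alignment: Alignment, model: SubstitutionModel,
                   optimize: bool = True) -> np.ndarray:
    """(n_trees, n_sites) per-site log-likelihoods, one row per topology."""
    rows = []
    for tree in trees:
        if optimize:
            _, res = optimize_branch_lengths(tree, alignment, model)
        else:
            res = log_likelihood(tree, alignment, model)
        rows.append(res.site_ll)
    return np.vstack(rows)


def rell_bootstrap(site_ll: np.ndarray, n_reps: int = 1000,
                   scale: float = 1.0, seed: int = 0) -> np.ndarray:
    """Winning proportion per tree under RELL resampling at one scale.

    Each replicate resamples ``round(scale * n_sites)`` site indices
    with replacement, sums the per-site log-likelihoods per tree and
    awards the replicate to the argmax; exact ties split the win
    equally among the tied trees.
    """
    site_ll = np.asarray(site_ll, dtype=float)
    if site_ll.ndim != 2 or site_ll.shape[0] < 2:
        raise TopologyTestError("need a (trees x sites) matrix with >=2 trees")
    if scale <= 0:
        raise TopologyTestError("scale must be positive")
    n_trees, n_sites = site_ll.shape
    m = max(int(round(scale * n_sites)), 1)
    rng = np.random.default_rng(seed)
    wins = np.zeros(n_trees)
    chunk = max(1, min(n_reps, int(2e7 / max(m, 1))))
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        idx = rng.integers(n_sites, size=(b, m))
        sums = site_ll[:, idx].sum(axis=2)          # (trees, b)
        best = sums.max(axis=0)
        tied = np.abs(sums - best[None, :]) <= 1e-10
        wins += (tied / tied.sum(axis=0)[None, :]).sum(axis=1)
        done += b
    return wins / n_reps


def au_test(site_ll: np.ndarray, n_reps_per_scale: int = 1000,
            scales=DEFAULT_AU_SCALES, seed: int = 0) -> np.ndarray:
    """Approximately-unbiased p-value per tree (multiscale RELL bootstrap).

    For each scale r the bootstrap proportion BP_r is transformed to
    z_r = Φ⁻¹(1 − BP_r) and the model z_r = d·√r + c/√r is fitted by
    weighted least squares with binomial-variance weights; the AU
    p-value is 1 − Φ(d − c).  BP identically 0 (or 1) across scales
    short-circuits to p = 0 (or 1).
    """
    site_ll = np.asarray(site_ll, dtype=float)
    scales = [s for s in scales if s > 0]
    if len(scales) < 2:
        raise TopologyTestError("need at least 2 usable scales")
    n_trees = site_ll.shape[0]
    bp = np.empty((len(scales), n_trees))
    for si, r in enumerate(scales):
        bp[si] = rell_bootstrap(site_ll, n_reps=n_reps_per_scale,
                                scale=r, seed=seed + si)
    eps = 1.0 / (2.0 * n_reps_per_scale)
    pvals = np.empty(n_trees)
    sqrt_r = np.sqrt(np.asarray(scales))
    X = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    for t in range(n_trees):
        if np.all(bp[:, t] <= 0.0):
            pvals[t] = 0.0
            continue
        if np.all(bp[:, t] >= 1.0):
            pvals[t] = 1.0
            continue
        bpc = np.clip(bp[:, t], eps, 1.0 - eps)
        z = stats.norm.ppf(1.0 - bpc)
        # var(z) ≈ var(BP) / φ(z)²;  clamped scales keep inflated variance
        var_bp = bpc * (1.0 - bpc) / n_reps_per_scale
        w = stats.norm.pdf(z) ** 2 / var_bp
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        d, c = coef
        pvals[t] = float(1.0 - stats.norm.cdf(d - c))
    return pvals


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold under Bonferroni correction."""
    if n_tests < 1:
        raise TopologyTestError("n_tests must be >= 1")
    return alpha / n_tests


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test (exact for small tie-free samples).

    Uses exact enumeration when both samples have at most 8
    observations and no cross-sample ties; otherwise the normal
    approximation with midranks, tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise TopologyTestError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with the t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise TopologyTestError("need n >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise TopologyTestError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TopologyTestError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
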