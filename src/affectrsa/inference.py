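"""Statistical comparison of RSMs.

Averaged-level comparisons use Spearman's rank correlation over the
strictly-below-diagonal cells (the matrices are symmetric, so using both
triangles would double-count), a Monte-Carlo permutation test that jointly
permutes the rows and columns of one matrix with a random trial-label
permutation, and an interval-null Bayes factor whose null hypothesis is the
1st–95th percentile range of the permutation distribution.

Individual-level comparisons extract one similarity index (Spearman rho) per
participant and aggregate with a one-sided one-sample t-test and a
directional JZS (Cauchy-prior) Bayes factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate, stats

from .rsm import RSM

__all__ = [
    "ComparisonResult",
    "IndividualLevelResult",
    "lower_triangle",
    "spearman_lower",
    "permutation_test",
    "permutation_test_triangle",
    "correlation_bf_interval",
    "jzs_ttest_bf",
    "regress_out",
    "individual_level_test",
    "compare_with_controls",
]


class DegenerateResultError(ValueError):
    """Raised when a statistic is undefined on the given input."""


@dataclass
class ComparisonResult:
    """Averaged-level RSM comparison: observed rho, permutation null, BF."""

    rho: float
    n_cells: int
    p_perm: float
    null_distribution: np.ndarray
    null_interval: tuple[float, float]
    bf10: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class IndividualLevelResult:
    """Per-participant similarity indexes with group-level one-sided test."""

    per_participant_rho: np.ndarray
    mean_rho: float
    t_statistic: float
    df: int
    p_one_sided: float
    bf10: float
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)


def _as_matrix(rsm) -> np.ndarray:
    return rsm.values if isinstance(rsm, RSM) else np.asarray(rsm, dtype=float)


def lower_triangle(rsm) -> np.ndarray:
    """Strictly-below-diagonal cells in row-major order (length T(T−1)/2).

    Missing cells are preserved as NaN; only these cells enter any RSM
    comparison, because a symmetric matrix's upper triangle duplicates them
    and the diagonal is self-similarity.
    """
    a = _as_matrix(rsm)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("lower_triangle requires a square matrix")
    return a[np.tril_indices(a.shape[0], k=-1)]


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    return x[ok], y[ok]


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks (Pearson on ranks; no NaN allowed)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_lower(rsm_a, rsm_b) -> tuple[float, int]:
    """Spearman rho over pairwise-complete lower-triangle cells of two RSMs."""
    ta = lower_triangle(rsm_a)
    tb = lower_triangle(rsm_b)
    if ta.shape != tb.shape:
        raise ValueError("RSMs must have the same shape")
    x, y = _pairwise_complete(ta, tb)
    if x.size < 3:
        raise DegenerateResultError("fewer than 3 pairwise-complete cells")
    return _spearman(x, y), int(x.size)


def _null_distribution(tri_fixed: np.ndarray, mat_perm: np.ndarray,
                       n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Permutation null: random trial relabelings of one matrix.

    ``tri_fixed`` is the fixed comparison vector on the lower-triangle cells;
    ``mat_perm`` the matrix whose trial labels are permuted each iteration.
    """
    T = mat_perm.shape[0]
    il, jl = np.tril_indices(T, k=-1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(T)
        tri = mat_perm[p[il], p[jl]]
        x, y = _pairwise_complete(tri_fixed, tri)
        null[k] = _spearman(x, y) if x.size >= 3 else np.nan
    return null


def _perm_result(rho: float, n_cells: int, null: np.ndarray,
                 seed) -> ComparisonResult:
    null = null[~np.isnan(null)]
    n_eff = null.size
    p = (1.0 + np.sum(null >= rho)) / (1.0 + n_eff)
    interval = (float(np.percentile(null, 1)), float(np.percentile(null, 95)))
    return ComparisonResult(rho=float(rho), n_cells=n_cells, p_perm=float(p),
                            null_distribution=null, null_interval=interval,
                            seed=seed)


def permutation_test(rsm_a, rsm_b, n_perm: int = 10_000, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> ComparisonResult:
    """Monte-Carlo permutation test of the rank correspondence of two RSMs.

    The observed statistic is :func:`spearman_lower`. The null distribution
    is built by jointly permuting rows and columns of ``rsm_b`` with a random
    trial-label permutation per iteration (preserving each matrix's internal
    structure) and recomputing the statistic. One-sided p uses the add-one
    estimator ``(1 + #{null ≥ rho}) / (1 + n_perm)``; the returned
    ``null_interval`` is the (1st, 95th) percentile pair of the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rho, n_cells = spearman_lower(rsm_a, rsm_b)
    null = _null_distribution(lower_triangle(rsm_a), _as_matrix(rsm_b), n_perm, rng)
    return _perm_result(rho, n_cells, null, seed)


def permutation_test_triangle(triangle: np.ndarray, rsm, n_perm: int = 10_000,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None,
                              ) -> ComparisonResult:
    """Permutation test of a fixed lower-triangle vector against an RSM.

    Used for residualized comparisons, where the model side is a residual
    vector defined on lower-triangle cells and only the physiological RSM
    retains a permutable trial structure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = _as_matrix(rsm)
    tri_rsm = lower_triangle(mat)
    triangle = np.asarray(triangle, dtype=float)
    if triangle.shape != tri_rsm.shape:
        raise ValueError("triangle length must match the RSM's lower triangle")
    x, y = _pairwise_complete(triangle, tri_rsm)
    if x.size < 3:
        raise DegenerateResultError("fewer than 3 pairwise-complete cells")
    rho = _spearman(x, y)
    null = _null_distribution(triangle, mat, n_perm, rng)
    return _perm_result(rho, int(x.size), null, seed)


# ---------------------------------------------------------------------------
# Bayes factors


def _stretched_beta_pdf(rho: np.ndarray, prior_width: float) -> np.ndarray:
    """Stretched-beta prior on a correlation: (ρ+1)/2 ~ Beta(1/κ, 1/κ)."""
    a = 1.0 / prior_width
    return stats.beta.pdf((rho + 1.0) / 2.0, a, a) / 2.0


def correlation_bf_interval(rho: float, n_cells: int,
                            null_interval: tuple[float, float],
                            prior_width: float = 1.0 / 3.0) -> float:
    """Bayes factor for a positive correlation beyond an interval null.

    H1: ρ in (hi, 1]; H0: ρ in [lo, hi], where (lo, hi) is the null interval
    (here, the 1st–95th percentile range of a permutation distribution).
    Both hypotheses share a stretched-beta prior (scale ``prior_width``,
    the conventional "medium" 1/3), renormalized on their region. The
    likelihood of the observed correlation uses the Fisher-z normal
    approximation of the sampling distribution at ``n_cells``.

    A degenerate interval (lo == hi) falls back to a point null at that
    value with a warning.
    """
    if n_cells < 4:
        raise ValueError("need at least 4 cells for a correlation Bayes factor")
    lo, hi = float(null_interval[0]), float(null_interval[1])
    if not (-1.0 <= lo <= hi <= 1.0):
        raise ValueError("null interval must be ordered and within [-1, 1]")
    z_obs = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n_cells - 3)

    def integrand(r):
        return stats.norm.pdf(z_obs, np.arctanh(r), se) * _stretched_beta_pdf(r, prior_width)

    def prior_mass(a, b):
        aa = 1.0 / prior_width
        return stats.beta.cdf((b + 1) / 2, aa, aa) - stats.beta.cdf((a + 1) / 2, aa, aa)

    eps = 1e-12
    hi_c = min(hi, 1.0 - eps)
    peak = float(np.clip(rho, hi_c + eps, 1.0 - eps))
    m1, _ = integrate.quad(integrand, hi_c, 1.0 - eps, points=[peak], limit=200)
    p1 = prior_mass(hi_c, 1.0)
    if lo == hi:
        warnings.warn("degenerate null interval; falling back to a point null")
        m0 = stats.norm.pdf(z_obs, np.arctanh(np.clip(hi, -1 + eps, 1 - eps)), se)
        p0 = 1.0
    else:
        peak0 = float(np.clip(rho, lo + eps, hi_c - eps))
        m0, _ = integrate.quad(integrand, lo, hi_c, points=[peak0], limit=200)
        p0 = prior_mass(lo, hi_c)
    num = m1 / p1
    den = m0 / p0
    if den == 0.0:
        return np.inf
    return float(num / den)


def jzs_ttest_bf(t: float, n: int, rscale: float = np.sqrt(2) / 2,
                 alternative: str = "greater") -> float:
    """One-sample JZS Bayes factor for a t-statistic.

    Effect size δ carries a Cauchy(0, ``rscale``) prior — truncated to δ > 0
    for ``alternative="greater"`` — and the likelihood of ``t`` given δ is a
    noncentral-t density with ``n − 1`` degrees of freedom and
    noncentrality δ√n. BF10 is the prior-weighted marginal likelihood under
    H1 divided by the central-t density under H0, computed by quadrature
    over δ.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def like(delta):
        return stats.nct.pdf(t, nu, delta * sqrt_n)

    if alternative == "greater":
        def integrand(delta):
            return like(delta) * 2.0 * stats.cauchy.pdf(delta, 0.0, rscale)
        lo, hi = 0.0, np.inf
    elif alternative == "two-sided":
        def integrand(delta):
            return like(delta) * stats.cauchy.pdf(delta, 0.0, rscale)
        lo, hi = -np.inf, np.inf
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    peak = t / sqrt_n
    points = [peak] if lo < peak < np.inf and np.isfinite(peak) and peak > lo else None
    # split at the likelihood peak for stable quadrature on the infinite range
    if points:
        m1a, _ = integrate.quad(integrand, lo, peak, limit=200)
        m1b, _ = integrate.quad(integrand, peak, np.inf, limit=200)
        m1 = m1a + m1b
    else:
        m1, _ = integrate.quad(integrand, lo, hi, limit=200)
    m0 = stats.t.pdf(t, nu)
    return float(m1 / m0)


# ---------------------------------------------------------------------------
# regression and individual-level aggregation


def regress_out(target, covariate) -> np.ndarray:
    """OLS residuals of ``target`` on ``covariate`` with intercept.

    Fitted on pairwise-complete entries; incomplete entries stay NaN in the
    returned vector. Residuals are orthogonal to the covariate by
    construction.
    """
    y = np.asarray(target, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("target and covariate must have equal length")
    ok = ~np.isnan(y) & ~np.isnan(x)
    xo = x[ok]
    if xo.size < 3 or np.ptp(xo) == 0:
        raise DegenerateResultError("covariate is constant (or too few complete cells)")
    import statsmodels.api as sm

    X = sm.add_constant(xo)
    fit = sm.OLS(y[ok], X).fit()
    out = np.full_like(y, np.nan)
    out[ok] = fit.resid
    return out


def individual_level_test(per_participant_rho, direction: str = "greater",
                          rscale: float = np.sqrt(2) / 2) -> IndividualLevelResult:
    """One-sided one-sample t-test of per-participant similarity indexes.

    Tests the null of no correspondence (mean similarity index = 0) against
    a positive mean, with a directional JZS Bayes factor. Participants with
    an undefined index (NaN) are dropped and counted in ``n_excluded``.
    If every index is exactly zero the t-statistic degenerates; by
    convention t = 0 and p = 0.5 are reported.
    """
    if direction != "greater":
        raise ValueError("only direction='greater' is supported")
    x = np.asarray(per_participant_rho, dtype=float)
    n_excluded = int(np.sum(np.isnan(x)))
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise DegenerateResultError("need at least 3 finite similarity indexes")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        t_stat = 0.0 if x.mean() == 0 else np.inf * np.sign(x.mean())
        p = 0.5 if x.mean() == 0 else (0.0 if x.mean() > 0 else 1.0)
    else:
        t_stat = float(x.mean() / (sd / np.sqrt(n)))
        p = float(stats.t.sf(t_stat, n - 1))
    bf = jzs_ttest_bf(0.0 if not np.isfinite(t_stat) else t_stat, n,
                      rscale=rscale, alternative="greater")
    if not np.isfinite(t_stat):
        bf = np.inf if t_stat > 0 else 0.0
    return IndividualLevelResult(per_participant_rho=x, mean_rho=float(x.mean()),
                                 t_statistic=float(t_stat), df=n - 1,
                                 p_one_sided=p, bf10=float(bf),
                                 n_excluded=n_excluded)


def _triangle_rho(tri_a: np.ndarray, tri_b: np.ndarray) -> float:
    """Pairwise-complete Spearman of two triangle vectors; NaN if degenerate."""
    x, y = _pairwise_complete(tri_a, tri_b)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return _spearman(x, y)


def per_participant_similarity(physio_rsms: Sequence[RSM],
                               model_rsms: Sequence[RSM]) -> np.ndarray:
    """One Spearman similarity index per participant (pairwise-complete)."""
    if len(physio_rsms) != len(model_rsms):
        raise ValueError("need one model RSM per physiological RSM")
    return np.array([_triangle_rho(lower_triangle(p), lower_triangle(m))
                     for p, m in zip(physio_rsms, model_rsms)])


def compare_with_controls(physio_rsms: Sequence[RSM], focal_rsms: Sequence[RSM],
                          controls: Mapping[str, Sequence[RSM]],
                          ) -> dict[str, IndividualLevelResult]:
    """Individual-level model comparison beyond control models.

    For each named control, the control's lower triangle is regressed out of
    the focal model's per-participant lower triangle; the residuals are
    correlated (Spearman) with the participant's physiological triangle, and
    the per-participant indexes are aggregated with
    :func:`individual_level_test`. Participants whose residual vector is
    degenerate (e.g., the control equals the focal model) get a NaN index
    and are counted as excluded.
    """
    results: dict[str, IndividualLevelResult] = {}
    for name, control_rsms in controls.items():
        if len(control_rsms) != len(focal_rsms):
            raise ValueError(f"control {name!r}: RSM count mismatch")
        rhos = []
        for p_rsm, f_rsm, c_rsm in zip(physio_rsms, focal_rsms, control_rsms):
            tri_f = lower_triangle(f_rsm)
            tri_c = lower_triangle(c_rsm)
            tri_p = lower_triangle(p_rsm)
            try:
                resid = regress_out(tri_f, tri_c)
            except DegenerateResultError:
                rhos.append(np.nan)
                continue
            rhos.append(_triangle_rho(resid, tri_p))
        res = individual_level_test(np.asarray(rhos))
        res.meta["control"] = name
        results[name] = res
    return results
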