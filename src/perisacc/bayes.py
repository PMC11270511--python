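"""JZS (Jeffreys-Zellner-Siow) one-sample Bayes factors.

The alternative hypothesis places a Cauchy prior with scale r = sqrt(2)/2 =
0.707 on the standardized effect size delta = (mu - mu0) / sigma; the null
fixes delta = 0.  The Bayes factor BF10 is the ratio of the marginal
likelihood of the observed one-sample t statistic under H1 (the noncentral
t density integrated over the prior, noncentrality delta * sqrt(n)) to its
density under H0 (central t).  The integral is evaluated by adaptive
quadrature to a 1e-8 tolerance.

Evidence categories follow the conventional thresholds: BF > 3 substantial
evidence for H1 ("substantial_alt"), BF < 1/3 substantial evidence for H0
("substantial_null"), otherwise inconclusive — strict inequalities in both
cases.  For decoding accuracies the null value is chance (0.5); for
accuracy differences it is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

DEFAULT_PRIOR_SCALE = float(np.sqrt(2) / 2)  # 0.707...
BF_ALT_THRESHOLD = 3.0
BF_NULL_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class BFSettings:
    null_value: float = 0.5
    prior_scale: float = DEFAULT_PRIOR_SCALE
    sidedness: str = "two_sided"  # or "greater", "less"

    def __post_init__(self):
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be > 0")
        if self.sidedness not in ("two_sided", "greater", "less"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class BFTimecourse:
    bf: np.ndarray
    times: np.ndarray
    category: np.ndarray  # str array

    def mask(self, which: str = "substantial_alt") -> np.ndarray:
        return self.category == which


def _categorize(bf: np.ndarray) -> np.ndarray:
    cat = np.full(np.shape(bf), "inconclusive", dtype=object)
    cat[np.asarray(bf) > BF_ALT_THRESHOLD] = "substantial_alt"
    cat[np.asarray(bf) < BF_NULL_THRESHOLD] = "substantial_null"
    return cat.astype(str)


def jzs_bf_from_t(
    t: float, n: int, settings: BFSettings | None = None
) -> float:
    """BF10 for an observed one-sample t statistic with sample size n.

    The marginal-likelihood ratio is evaluated by adaptive (tanh-sinh)
    quadrature.  For the default two-sided Cauchy prior the effect-size
    integral is computed in its exactly equivalent scale-mixture form (the
    Cauchy is a normal scaled by an inverse-gamma(1/2, 1/2) variance g, so
    delta can be integrated out analytically and only the elementary
    g-integral remains), which stays numerically stable for arbitrarily
    large ``|t|``.  One-sided (half-Cauchy) priors integrate the
    noncentral-t density over the truncated prior directly.
    """
    settings = settings or BFSettings()
    df = n - 1
    r = settings.prior_scale

    if settings.sidedness == "two_sided":
        # log of the t-likelihood ratio given prior variance scale g
        def log_ratio(g):
            a = 1.0 + n * g * r**2
            return (
                -0.5 * np.log(a)
                - (df + 1) / 2 * (np.log1p(t**2 / (df * a)) - np.log1p(t**2 / df))
            )

        def integrand(g):
            return np.exp(log_ratio(g)) * stats.invgamma.pdf(g, 0.5, scale=0.5)

        res = integrate.tanhsinh(integrand, 0.0, np.inf, atol=1e-14, rtol=1e-8)
        return float(res.integral)

    # one-sided: integrate the noncentral-t density over the half-Cauchy
    sqrt_n = np.sqrt(n)
    log_m0 = stats.t.logpdf(t, df)

    def integrand(delta):
        return np.exp(stats.nct.logpdf(t, df, delta * sqrt_n) - log_m0) * (
            2.0 * stats.cauchy.pdf(delta, loc=0, scale=r)
        )

    lo, hi = (0.0, np.inf) if settings.sidedness == "greater" else (-np.inf, 0.0)
    res = integrate.tanhsinh(integrand, lo, hi, atol=1e-14, rtol=1e-8)
    return float(res.integral)


def jzs_bf(values: np.ndarray, settings: BFSettings | None = None) -> float:
    """One-sample JZS Bayes factor for per-subject statistics.

    Tests H1: mean != settings.null_value (Cauchy prior on the effect
    size) against H0: mean == null_value.

    Degenerate zero-variance samples return +inf (mean differs from the
    null value) or 0 (mean exactly at the null value), with a logged flag.

    Raises
    ------
    ValueError
        On fewer than 2 finite values.
    """
    settings = settings or BFSettings()
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 finite values")
    sd = v.std(ddof=1)
    if sd == 0:
        logger.warning("zero-variance sample in jzs_bf; returning degenerate BF")
        return np.inf if v[0] != settings.null_value else 0.0
    t = (v.mean() - settings.null_value) / (sd / np.sqrt(n))
    return jzs_bf_from_t(t, n, settings)


def bf_timecourse(
    values: np.ndarray,
    times: np.ndarray,
    settings: BFSettings | None = None,
) -> BFTimecourse:
    """Bayes factor at every timepoint of a (subjects, times) array.

    Timepoints where fewer than 2 subjects are finite get BF = NaN and
    category ``inconclusive``.
    """
    values = np.asarray(values, dtype=float)
    n_times = values.shape[1]
    bf = np.full(n_times, np.nan)
    for ti in range(n_times):
        col = values[:, ti]
        col = col[np.isfinite(col)]
        if len(col) >= 2:
            bf[ti] = jzs_bf(col, settings)
    cat = _categorize(np.where(np.isfinite(bf), bf, 1.0))
    return BFTimecourse(bf=bf, times=np.asarray(times), category=cat)


def bf_matrix(
    values: np.ndarray, settings: BFSettings | None = None
) -> np.ndarray:
    """BF per cell of a (subjects, n_bins, n_times) difference stack."""
    values = np.asarray(values, dtype=float)
    _, n_bins, n_times = values.shape
    out = np.full((n_bins, n_times), np.nan)
    for b in range(n_bins):
        for t in range(n_times):
            col = values[:, b, t]
            col = col[np.isfinite(col)]
            if len(col) >= 2:
                out[b, t] = jzs_bf(col, settings)
    return out


def bf_mask(
    matrix_values: np.ndarray,
    settings: BFSettings | None = None,
    threshold: float = 10.0,
) -> np.ndarray:
    """Boolean (n_bins, n_times) mask of cells with BF10 > threshold.

    ``matrix_values`` holds per-subject differences, shape (subjects,
    n_bins, n_times); the default null value for differences is 0.
    """
    settings = settings or BFSettings(null_value=0.0)
    bf = bf_matrix(matrix_values, settings)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(bf), bf > threshold, False)


def evidence_clusters(
    mask: np.ndarray, min_len: int = 2
) -> list[tuple[int, int]]:
    """Contiguous True runs of at least ``min_len`` samples, as (start,
    end) index pairs (end exclusive)."""
    runs = []
    m = np.asarray(mask, dtype=bool)
    d = np.diff(m.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m.size and m[0]:
        starts = [0] + starts
    if m.size and m[-1]:
        ends = ends + [m.size]
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            runs.append((int(s), int(e)))
    return runs
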