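"""Selection-coefficient inference from substitution-rate ratios.

Under weak selection in a diploid population, the fixation probability of a
new mutation with selection coefficient s is

    u(s) = (1/2N) * S / (1 - exp(-S)),        S = 4*Ne*s,

so the substitution rate at a selected locus, relative to a neutral locus
with the same mutation rate, is the fixation ratio

    r(S) = S / (1 - exp(-S)).

r is strictly increasing with r(0) = 1 and satisfies r(S) - r(-S) = S, so an
observed/expected substitution-frequency ratio determines S uniquely by
numerical inversion.  This module provides r, its inverse, exact binomial
(Clopper-Pearson) confidence intervals, the resulting per-position selection
estimates, and genome-wide drift-load summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats

__all__ = [
    "fixation_ratio",
    "invert_rate_ratio",
    "clopper_pearson",
    "SelectionEstimate",
    "estimate_selection",
    "per_locus_s",
    "LoadSummary",
    "drift_load",
]

_SERIES_CUTOFF = 1e-6


def fixation_ratio(S):
    """Substitution rate relative to neutral for scaled selection S = 4*Ne*s.

    Accepts scalars or arrays.  The removable singularity at S = 0 is
    evaluated by the series 1 + S/2 + S^2/12 for |S| < 1e-6, keeping the
    relative error below 1e-12 near zero.
    """
    arr = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("S must be finite")
    out = np.empty_like(arr)
    small = np.abs(arr) < _SERIES_CUTOFF
    s = arr[small]
    out[small] = 1.0 + s / 2.0 + s * s / 12.0
    b = arr[~small]
    with np.errstate(over="ignore"):
        out[~small] = b / (-np.expm1(-b))
    if np.isscalar(S) or np.ndim(S) == 0:
        return float(out)
    return out


def invert_rate_ratio(r: float) -> float:
    """Unique S with fixation_ratio(S) == r, for r > 0.

    Bracketed root-finding on [-100, 100], expanding the bracket when the
    target ratio falls outside; round-trips fixation_ratio to better than
    1e-8 over S in [-20, 20].
    """
    r = float(r)
    if not r > 0:
        raise ValueError(f"rate ratio must be > 0, got {r}")
    if r == 1.0:
        return 0.0
    lo, hi = -100.0, 100.0
    while fixation_ratio(lo) > r:
        lo *= 2.0
        if lo < -1e9:  # pragma: no cover - r would underflow first
            raise ValueError(f"no finite S for ratio {r}")
    while fixation_ratio(hi) < r:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            raise ValueError(f"no finite S for ratio {r}")
    return float(
        optimize.brentq(lambda s: fixation_ratio(s) - r, lo, hi, xtol=1e-12)
    )


def clopper_pearson(k, n, alpha: float = 0.05):
    """Exact central binomial confidence interval by beta-tail inversion.

    Vectorized over k, n.  Returns (lo, hi); lo = 0 when k = 0 and hi = 1
    when k = n.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if np.any(n_arr <= 0):
        raise ValueError("n must be positive")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k_f = k_arr.astype(float)
    n_f = n_arr.astype(float)
    with np.errstate(invalid="ignore"):
        lo = stats.beta.ppf(alpha / 2.0, k_f, n_f - k_f + 1.0)
        hi = stats.beta.ppf(1.0 - alpha / 2.0, k_f + 1.0, n_f - k_f)
    lo = np.where(k_arr == 0, 0.0, lo)
    hi = np.where(k_arr == n_arr, 1.0, hi)
    if np.isscalar(k) and np.isscalar(n):
        return float(lo), float(hi)
    return lo, hi


@dataclass
class SelectionEstimate:
    """Point estimate and 95% CI of 4*Ne*s for one position and direction."""

    S_hat: float
    S_low: float
    S_high: float
    r: float
    q: float
    q_exp: float
    direction: str
    site_type: str | None = None
    offset: int | None = None


def estimate_selection(rate, q_exp: float) -> SelectionEstimate:
    """Invert an observed class substitution frequency against its neutral
    expectation.

    ``rate`` is a RateEstimate (k, n, q, ci_low, ci_high, direction).  The
    CI endpoints are transformed through the same inversion, treating the
    sampling error of the neutral control as negligible.  A zero lower
    frequency bound maps to an open-ended S_low = -inf; q = 0 itself yields
    S_hat = -inf (the ratio has no finite preimage).
    """
    q_exp = float(q_exp)
    if not q_exp > 0:
        raise ValueError("q_exp must be positive")
    if rate.n == 0:
        raise ValueError("rate estimate has no opportunities (n = 0)")

    def _inv(ratio: float, side: float) -> float:
        if ratio <= 0:
            return -math.inf
        return invert_rate_ratio(ratio)

    r = rate.q / q_exp
    return SelectionEstimate(
        S_hat=_inv(r, 0.0),
        S_low=_inv(rate.ci_low / q_exp, -1.0),
        S_high=_inv(rate.ci_high / q_exp, +1.0),
        r=r,
        q=rate.q,
        q_exp=q_exp,
        direction=rate.direction,
    )


def per_locus_s(S: float, Ne: float) -> float:
    """Un-scale 4*Ne*s to a per-locus selection coefficient s = S / (4*Ne)."""
    if not Ne > 0:
        raise ValueError("Ne must be positive")
    return float(S) / (4.0 * float(Ne))


@dataclass
class LoadSummary:
    """Genome-wide drift-load summary for one splice-site class.

    ``load`` is the summed selection coefficient against all currently fixed
    nonconsensus alleles: n_ss * mean_nc * s_per_locus.
    """

    n_ss: float
    mean_nc: float
    s_per_locus: float
    load: float
    cn_fraction: float | None = None


def drift_load(
    n_ss: float, mean_nc: float, s_per_locus: float, cn_fraction: float | None = None
) -> LoadSummary:
    """Summed selection coefficient against Nc alleles across an SS class."""
    if n_ss < 0 or mean_nc < 0 or s_per_locus < 0:
        raise ValueError("drift-load inputs must be non-negative")
    if cn_fraction is not None and not 0 <= cn_fraction <= 1:
        raise ValueError("cn_fraction must lie in [0, 1]")
    return LoadSummary(
        n_ss=float(n_ss),
        mean_nc=float(mean_nc),
        s_per_locus=float(s_per_locus),
        load=float(n_ss) * float(mean_nc) * float(s_per_locus),
        cn_fraction=cn_fraction,
    )
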