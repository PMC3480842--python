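"""Model-free Poisson contrast statistics for peak-like coverage forms.

ChIP-Seq coverage at a genomic position is treated as a Poisson count with
an unspecified, position-dependent rate.  Peak-like shapes and enrichment
over a control sample are tested with normalized linear contrasts of
independently measured Poisson counts (Hoel tests): a contrast ``a·X`` with
``E[a·X] = 0`` under the null is divided by the square root of an unbiased
estimate of its variance, giving a statistic that is approximately standard
normal even at low total counts, with no background model and no fitted
parameters.

Four contrasts are used:

``z1``
    center versus the mean of both flanks (peak with two shoulders,
    equivalently a significantly negative discrete second derivative),
``z2``
    center versus left flank only (rising edge),
``z3``
    center versus right flank only (falling edge),
``z4``
    library-scaled ChIP count versus the matched control count
    (local enrichment).

All functions accept scalars or numpy arrays and broadcast; counts of zero
everywhere map to a z of exactly 0 (zero evidence), never NaN, so that
strict ``z > min_z`` detection conditions correctly fail on empty data.
"""

from __future__ import annotations

import numbers

import numpy as np
from scipy.stats import norm

__all__ = [
    "z1",
    "z2",
    "z3",
    "z4",
    "enrichment_ratio",
    "nlp_from_z",
    "min_z_from_p",
]

_LN10 = np.log(10.0)


def _contrast(num, var):
    """num / sqrt(var), with 0 wherever var == 0 (the all-zero-counts case)."""
    num = np.asarray(num, dtype=np.float64)
    var = np.asarray(var, dtype=np.float64)
    out = np.zeros(np.broadcast(num, var).shape, dtype=np.float64)
    np.divide(num, np.sqrt(var, where=var > 0, out=np.ones_like(var)),
              out=out, where=var > 0)
    if out.ndim == 0:
        return float(out)
    return out


def z1(c_left, c_center, c_right):
    """Form-1 statistic: is the center count larger than the flank average?

    Tests ``2·λ_center > λ_left + λ_right`` for independently measured
    Poisson counts.  Under equality the contrast ``2C − L − R`` has mean 0
    and variance ``6λ``, estimated without bias by ``2(L + C + R)``.

    Parameters
    ----------
    c_left, c_center, c_right
        Non-negative integer coverage counts at ``x − δ``, ``x``, ``x + δ``
        (scalars or broadcastable arrays).

    Returns
    -------
    float or ndarray
        ``(2·C − L − R) / sqrt(2·(L + C + R))``; 0 where all counts are 0.
    """
    cl = np.asarray(c_left)
    cc = np.asarray(c_center)
    cr = np.asarray(c_right)
    return _contrast(2.0 * cc - cl - cr, 2.0 * (cl + cc + cr))


def z2(c_left, c_center):
    """Form-2 statistic: center versus left flank.

    Tests ``λ_center > λ_left``; returns ``(C − L)/sqrt(L + C)``,
    0 where both counts are 0.
    """
    cl = np.asarray(c_left)
    cc = np.asarray(c_center)
    return _contrast(cc - cl, cl + cc)


def z3(c_center, c_right):
    """Form-3 statistic: center versus right flank.

    Mirror image of :func:`z2`: ``(C − R)/sqrt(C + R)``, so
    ``z3(a, b) == z2(b, a)``.
    """
    cc = np.asarray(c_center)
    cr = np.asarray(c_right)
    return _contrast(cc - cr, cc + cr)


def z4(c, b, r):
    """Enrichment statistic: library-scaled ChIP count versus control.

    Tests ``r·λ_chip > μ_control`` where ``r`` is the control/ChIP library
    size ratio.  Under equality ``Var(r·C − B) = r²λ + μ = μ(1 + r)`` and
    ``E[r·(C + B)] = μ(1 + r)``, so ``r·(C + B)`` is the unbiased variance
    estimate.

    Returns ``(r·C − B)/sqrt(r·(C + B))``; 0 where ``C == B == 0``.
    """
    if r <= 0:
        raise ValueError(f"library size ratio r must be positive, got {r}")
    c = np.asarray(c)
    b = np.asarray(b)
    return _contrast(r * c - b, r * (np.asarray(c, dtype=np.float64) + b))


def enrichment_ratio(c, b, r):
    """Pseudo-count-stabilized local enrichment ratio ``(1 + r·C)/(1 + B)``.

    The +1 pseudo-counts keep the ratio finite on zero control coverage and
    equal to 1 on doubly-empty positions.
    """
    if r <= 0:
        raise ValueError(f"library size ratio r must be positive, got {r}")
    c = np.asarray(c, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    out = (1.0 + r * c) / (1.0 + b)
    if out.ndim == 0:
        return float(out)
    return out


def nlp_from_z(z):
    """Negative log10 upper-tail standard-normal p-value of a z-score.

    Computed on the log scale (``-logsf(z)/ln 10``) so that very large z
    (e.g. z = 40, p ≈ 1e-350) yields a finite NLP instead of underflowing
    through p = 0.  Strictly increasing in ``z``.
    """
    z = np.asarray(z, dtype=np.float64)
    out = -norm.logsf(z) / _LN10
    if out.ndim == 0:
        return float(out)
    return out


def min_z_from_p(p):
    """Standard-normal upper-tail quantile for tail probability ``p``.

    ``min_z_from_p(0.1) ≈ 1.2816`` is the default detection cut-off.
    """
    if not isinstance(p, numbers.Real) or not 0.0 < p < 1.0:
        raise ValueError(f"tail probability must lie in (0, 1), got {p!r}")
    return float(norm.isf(p))
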