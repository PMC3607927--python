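"""Manders colocalization coefficients and the PDM covariation map.

The Manders coefficient M_R is the fraction of channel-R integrated
intensity found at pixels where channel G is above threshold (and
symmetrically for M_G); both lie in [0, 1] by construction.  The PDM
("product of the differences from the mean") image assigns each pixel
(R_i - mean R)(G_i - mean G): positive where the channels co-vary,
negative where they anti-vary, so its mean equals the population
covariance of the two channels over the analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColocalizationResult", "manders_coefficients", "pdm_image"]


@dataclass
class ColocalizationResult:
    m_r: float | None
    m_g: float | None
    pdm: np.ndarray
    pdm_mean: float
    analysis_mask: np.ndarray
    thr_r: float
    thr_g: float


def _as_masked(r, g, mask):
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if r.shape != g.shape:
        raise ValueError("channel shapes differ")
    if mask is None:
        mask = np.ones(r.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != r.shape:
            raise ValueError("mask shape differs from channels")
    return r, g, mask


def manders_coefficients(r, g, thr_r: float = 0.0, thr_g: float = 0.0, mask=None):
    """Per-channel Manders coefficients over an optional analysis mask.

    m_r = sum of R over pixels (in mask) with G > thr_g, divided by the sum
    of R over the mask; m_g symmetric.  A channel with zero integrated
    intensity has an undefined coefficient, reported as None.
    """
    if thr_r < 0 or thr_g < 0:
        raise ValueError("thresholds must be >= 0")
    r, g, mask = _as_masked(r, g, mask)
    r_tot = float(r[mask].sum())
    g_tot = float(g[mask].sum())
    m_r = float(r[mask & (g > thr_g)].sum() / r_tot) if r_tot > 0 else None
    m_g = float(g[mask & (r > thr_r)].sum() / g_tot) if g_tot > 0 else None
    return m_r, m_g


def pdm_image(r, g, mask=None):
    """Per-pixel product of the differences from the (in-mask) channel means.

    Returns ``(pdm, pdm_mean)``; outside the mask the map is zero.  The
    mean of the map over the mask equals the population covariance of the
    two channels within it.
    """
    r, g, mask = _as_masked(r, g, mask)
    if not mask.any():
        raise ValueError("empty analysis mask")
    r_mu = r[mask].mean()
    g_mu = g[mask].mean()
    pdm = np.zeros(r.shape, dtype=float)
    pdm[mask] = (r[mask] - r_mu) * (g[mask] - g_mu)
    return pdm, float(pdm[mask].mean())


def colocalize(r, g, thr_r: float = 0.0, thr_g: float = 0.0, mask=None) -> ColocalizationResult:
    """Manders coefficients and PDM map in one pass."""
    m_r, m_g = manders_coefficients(r, g, thr_r, thr_g, mask)
    _, _, mask_arr = _as_masked(r, g, mask)
    pdm, pdm_mean = pdm_image(r, g, mask)
    return ColocalizationResult(m_r, m_g, pdm, pdm_mean, mask_arr, thr_r, thr_g)
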