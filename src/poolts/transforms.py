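"""Variance-stabilizing angular transform of allele frequencies.

The whole analysis operates on z = 2*arcsin(sqrt(p)).  On this scale the
sampling variance of a binomial frequency estimate from m reads is ~1/m
regardless of p, and the per-generation drift variance is ~1/(2*Ne)
regardless of p, which is what makes the downstream error model and
likelihood calculations tractable.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["arcsine_transform", "back_transform", "back_transform_delta"]

logger = logging.getLogger(__name__)


def arcsine_transform(p):
    """Angular transform z = 2*arcsin(sqrt(p)), mapping [0, 1] -> [0, pi].

    Parameters
    ----------
    p : float or array-like
        Allele frequency in [0, 1].

    Returns
    -------
    float or ndarray
        Transformed frequency z in [0, pi].

    Raises
    ------
    ValueError
        If any p lies outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("allele frequency must lie in [0, 1]")
    z = 2.0 * np.arcsin(np.sqrt(p))
    return z if z.ndim else float(z)


def back_transform(z):
    """Inverse of :func:`arcsine_transform`: p = sin(z/2)**2."""
    z = np.asarray(z, dtype=float)
    p = np.sin(z / 2.0) ** 2
    return p if p.ndim else float(p)


def back_transform_delta(p0, dz):
    """Allele-frequency change implied by a change ``dz`` on the z scale.

    Returns sin((z0+dz)/2)**2 - p0 where z0 = 2*arcsin(sqrt(p0)).  If
    z0+dz leaves [0, pi] it is clipped to the boundary and a warning is
    logged (the returned change then corresponds to fixation/loss).
    """
    p0 = np.asarray(p0, dtype=float)
    z0 = 2.0 * np.arcsin(np.sqrt(p0))
    z1 = z0 + np.asarray(dz, dtype=float)
    clipped = (z1 < 0.0) | (z1 > np.pi)
    if np.any(clipped):
        logger.warning(
            "back_transform_delta: %d value(s) clipped at the [0, pi] boundary",
            int(np.sum(clipped)),
        )
        z1 = np.clip(z1, 0.0, np.pi)
    out = np.sin(z1 / 2.0) ** 2 - p0
    return out if out.ndim else float(out)
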