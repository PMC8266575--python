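"""Worm-like-chain (WLC) elasticity for single-stranded DNA.

Converts between force and fractional extension with the Marko–Siggia
interpolation, and between rupture extension jumps (nm) and released
nucleotide counts.  Unfolding a structure of ``n`` structured nucleotides at
force ``F`` lengthens the tether by ``n`` nucleotides of ssDNA stretched to
the extension-per-nucleotide at ``F``, minus the end-to-end extent the folded
structure itself contributed along the pulling axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PolymerParams",
    "SSDNA",
    "DSDNA_HANDLE",
    "wlc_force",
    "ss_extension_per_nt",
    "nt_from_step",
    "step_from_nt",
]


@dataclass(frozen=True)
class PolymerParams:
    """Elastic constants of a WLC polymer plus the folded-structure offset.

    Parameters
    ----------
    persistence_length : float
        Bending persistence length Lp in nm.
    contour_per_nt : float
        Contour length per nucleotide (or base pair) in nm.
    kBT : float
        Thermal energy in pN·nm; the default 4.11 corresponds to room
        temperature (~25 °C).
    folded_extent : float
        End-to-end extent of the folded structure along the pulling axis in
        nm, released in addition to nothing: it is *subtracted* from the
        contour gained when the structure unfolds.
    """

    persistence_length: float = 0.8
    contour_per_nt: float = 0.56
    kBT: float = 4.11
    folded_extent: float = 2.0

    def __post_init__(self) -> None:
        for field in ("persistence_length", "contour_per_nt", "kBT", "folded_extent"):
            if not getattr(self, field) > 0:
                raise ValueError(f"PolymerParams.{field} must be strictly positive")


#: Literature ssDNA constants; config-overridable.
SSDNA = PolymerParams()

#: dsDNA handle constants (Lp ~ 45 nm, 0.34 nm/bp); used only for simulated
#: trace baselines.  ``folded_extent`` is irrelevant for handles.
DSDNA_HANDLE = PolymerParams(persistence_length=45.0, contour_per_nt=0.34)


def wlc_force(relative_extension, params: PolymerParams = SSDNA):
    """Marko–Siggia force at fractional extension ``z = x / L_contour``.

    F(z) = (kBT/Lp) · [ 1/(4(1−z)²) − 1/4 + z ],  0 ≤ z < 1.

    Accepts scalars or arrays; strictly increasing and divergent as z → 1.
    """
    z = np.asarray(relative_extension, dtype=float)
    if np.any(z < 0.0) or np.any(z >= 1.0):
        raise ValueError("relative_extension must lie in [0, 1)")
    f = (params.kBT / params.persistence_length) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return float(f) if f.ndim == 0 else f


def _fractional_extension(force: float, params: PolymerParams) -> float:
    # Unique root of wlc_force(z) = force on [0, 1); Brent to machine precision.
    if force <= 0.0:
        raise ValueError("force must be strictly positive")
    return brentq(
        lambda z: wlc_force(z, params) - force,
        0.0,
        1.0 - 1e-12,
        xtol=1e-15,
        rtol=8.9e-16,
    )


def ss_extension_per_nt(force, params: PolymerParams = SSDNA):
    """Extension per nucleotide (nm/nt) of ssDNA at ``force`` (pN).

    Numeric inversion of :func:`wlc_force` scaled by the contour length per
    nucleotide.  Strictly increasing in force; tends to 0 as force → 0.
    """
    f = np.asarray(force, dtype=float)
    if f.ndim == 0:
        return params.contour_per_nt * _fractional_extension(float(f), params)
    return np.array([params.contour_per_nt * _fractional_extension(fi, params) for fi in f])


def nt_from_step(delta_x, force, params: PolymerParams = SSDNA):
    """Released nucleotides implied by an extension jump ``delta_x`` (nm) at
    rupture force ``force`` (pN).

    n = (Δx + folded_extent) / extension_per_nt(F).  Exact inverse of
    :func:`step_from_nt` at the same force.
    """
    dx = np.asarray(delta_x, dtype=float)
    if np.any(dx <= -params.folded_extent):
        raise ValueError("delta_x must exceed -folded_extent")
    per_nt = ss_extension_per_nt(force, params)
    n = (dx + params.folded_extent) / per_nt
    return float(n) if np.ndim(n) == 0 else n


def step_from_nt(n, force, params: PolymerParams = SSDNA):
    """Extension jump (nm) produced by releasing ``n`` nucleotides at force
    ``force`` (pN): Δx = n·extension_per_nt(F) − folded_extent."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("released nucleotide count must be non-negative")
    dx = n_arr * ss_extension_per_nt(force, params) - params.folded_extent
    return float(dx) if dx.ndim == 0 else dx
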