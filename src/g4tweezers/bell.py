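"""Bell rupture kinetics under a linear force ramp.

A folded state unfolds with force-dependent rate k(F) = k_unfold·exp(F·Δx‡/kBT)
(Bell model).  Under a ramp F(t) = F₀ + r·t the rupture-force distribution has
the closed-form Bell–Evans survival

    S(F) = exp[ −(kBT·k_unfold)/(r·Δx‡) · (e^{F·Δx‡/kBT} − e^{F₀·Δx‡/kBT}) ],

with density p(F) = k(F)/r · S(F) and an analytic mode and inverse CDF.  The
force domain is used throughout: the ramp is deterministic, so force and time
are interchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BellState",
    "RampProtocol",
    "DEFAULT_PROTOCOL",
    "hazard",
    "ramp_survival",
    "ramp_pdf",
    "modal_force",
    "sample_force",
    "state_from_modal_force",
]


@dataclass(frozen=True)
class BellState:
    """One folded conformation's unfolding kinetics.

    k_unfold : zero-force unfolding rate (s⁻¹)
    dx       : distance to the transition state Δx‡ (nm)
    step_nt  : nucleotides released on unfolding (used by the simulator and
               step-size summaries; 0 if unknown)
    label    : free-text species name
    """

    k_unfold: float
    dx: float
    step_nt: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.k_unfold > 0:
            raise ValueError("k_unfold must be > 0")
        if not self.dx > 0:
            raise ValueError("dx must be > 0")
        if self.step_nt < 0:
            raise ValueError("step_nt must be >= 0")


@dataclass(frozen=True)
class RampProtocol:
    """Force-ramp protocol: linear ramp f_start→f_end at ``loading_rate``,
    then a jump to ``hold_force`` for ``hold_time`` to allow refolding."""

    f_start: float = 1.0
    f_end: float = 60.0
    loading_rate: float = 2.0
    hold_force: float = 1.0
    hold_time: float = 30.0
    kBT: float = 4.11

    def __post_init__(self) -> None:
        if not self.f_start < self.f_end:
            raise ValueError("f_start must be < f_end")
        if not self.loading_rate > 0:
            raise ValueError("loading_rate must be > 0")
        if not self.kBT > 0:
            raise ValueError("kBT must be > 0")

    def ramp_duration(self) -> float:
        return (self.f_end - self.f_start) / self.loading_rate

    def with_(self, **kwargs) -> "RampProtocol":
        return replace(self, **kwargs)


#: 2 pN/s ramp from 1 to 60 pN, refold at 1 pN for 30 s.
DEFAULT_PROTOCOL = RampProtocol()


def hazard(force, state: BellState, kBT: float = 4.11):
    """Bell unfolding rate k(F) = k_unfold · exp(F·Δx‡/kBT) in s⁻¹."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    k = state.k_unfold * np.exp(f * state.dx / kBT)
    return float(k) if k.ndim == 0 else k


def _log_survival(f, state: BellState, protocol: RampProtocol):
    a = state.dx / protocol.kBT
    scale = state.k_unfold / (protocol.loading_rate * a)
    return -scale * (np.exp(a * f) - math.exp(a * protocol.f_start))


def ramp_survival(force, state: BellState, protocol: RampProtocol):
    """Probability the state is still folded when the ramp reaches ``force``."""
    f = np.asarray(force, dtype=float)
    if np.any(f < protocol.f_start):
        raise ValueError("force must be >= protocol.f_start")
    s = np.exp(_log_survival(f, state, protocol))
    return float(s) if s.ndim == 0 else s


def ramp_pdf(force, state: BellState, protocol: RampProtocol):
    """Rupture-force density p(F) = k(F)/r · S(F), per pN on [f_start, ∞)."""
    f = np.asarray(force, dtype=float)
    if np.any(f < protocol.f_start):
        raise ValueError("force must be >= protocol.f_start")
    p = hazard(f, state, protocol.kBT) / protocol.loading_rate * np.exp(
        _log_survival(f, state, protocol)
    )
    return float(p) if p.ndim == 0 else p


def modal_force(state: BellState, protocol: RampProtocol) -> float:
    """Most probable rupture force F* = (kBT/Δx‡)·ln[r·Δx‡/(k_unfold·kBT)].

    If the analytic mode falls below ``f_start`` the density is monotone
    decreasing on the ramp and ``f_start`` is returned.
    """
    f_star = (protocol.kBT / state.dx) * math.log(
        protocol.loading_rate * state.dx / (state.k_unfold * protocol.kBT)
    )
    return max(f_star, protocol.f_start)


def sample_force(state: BellState, protocol: RampProtocol, u):
    """Exact inverse-CDF rupture-force sample for uniform ``u`` ∈ (0, 1).

    Returns the force solving S(F) = 1 − u; values above ``protocol.f_end``
    correspond to cycles that survive the whole ramp (censored — the caller
    flags them).
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    a = state.dx / protocol.kBT
    arg = math.exp(a * protocol.f_start) - (
        protocol.loading_rate * a / state.k_unfold
    ) * np.log1p(-u_arr)
    f = np.log(arg) / a
    return float(f) if f.ndim == 0 else f


def state_from_modal_force(
    modal_force_pn: float,
    dx: float,
    protocol: RampProtocol = DEFAULT_PROTOCOL,
    step_nt: float = 0.0,
    label: str = "",
) -> BellState:
    """Construct a :class:`BellState` whose ramp-distribution mode equals
    ``modal_force_pn`` for a given Δx‡ (the (k_unfold, Δx‡) pair is otherwise
    under-determined by a single peak force)."""
    k0 = (
        protocol.loading_rate
        * dx
        / protocol.kBT
        * math.exp(-modal_force_pn * dx / protocol.kBT)
    )
    return BellState(k_unfold=k0, dx=dx, step_nt=step_nt, label=label)
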