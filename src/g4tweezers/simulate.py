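"""Synthetic magnetic-tweezers data generator.

Mirrors the force-ramp measurement: each pull cycle refolds the molecule at
low force, then ramps the force up; the conformation adopted in that cycle is
a categorical draw over a mixture of Bell states (plus an unfolded/misfolded
outcome that shows ssDNA-like behaviour and produces no rupture).  Rupture
forces follow the exact Bell–Evans ramp distribution; extension jumps are the
WLC forward model plus Gaussian measurement noise; refolding outcomes are
binomial under first-order kinetics; melting profiles are noisy sigmoids.

Every generator accepts either an integer ``seed`` or a ``numpy`` Generator
``rng``; the same seed reproduces the output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bell import BellState, RampProtocol, sample_force
from .polymer import DSDNA_HANDLE, SSDNA, PolymerParams, step_from_nt, wlc_force

__all__ = [
    "NoiseModel",
    "StateMixture",
    "PullCycle",
    "simulate_cycles",
    "simulate_pfold_series",
    "simulate_trace",
    "simulate_melting_curve",
    "cycles_to_frame",
    "write_cycles_tsv",
    "read_cycles_tsv",
    "forces_from_cycles",
]

CYCLE_COLUMNS = [
    "cycle_id",
    "molecule_id",
    "hold_time_s",
    "ruptured",
    "censored",
    "force_pN",
    "delta_x_nm",
    "state_label_truth",
]


def _rng_from(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: sd of the extension-jump estimate (nm), per-sample
    bead-tracking noise on traces (nm), and trace sampling rate (Hz)."""

    sigma_step: float = 0.6
    sigma_bead: float = 1.0
    trace_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma_step < 0 or self.sigma_bead < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not self.trace_rate > 0:
            raise ValueError("trace_rate must be > 0")


@dataclass(frozen=True)
class StateMixture:
    """Conformational ensemble of one sequence: Bell states with population
    weights plus the weight of the unfolded/misfolded (no-rupture) outcome.
    Weights must sum to 1."""

    states: tuple[BellState, ...]
    weights: tuple[float, ...]
    w_unfolded: float = 0.0

    def __post_init__(self) -> None:
        if len(self.states) != len(self.weights):
            raise ValueError("states and weights must have equal length")
        if len(self.states) == 0 and self.w_unfolded < 1.0:
            raise ValueError("mixture without states must be all-unfolded")
        if any(w < 0 for w in self.weights) or self.w_unfolded < 0:
            raise ValueError("weights must be non-negative")
        total = sum(self.weights) + self.w_unfolded
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, expected 1")

    @property
    def p_folded(self) -> float:
        return 1.0 - self.w_unfolded


@dataclass(frozen=True)
class PullCycle:
    """One force-ramp stretch.  ``force_pN``/``delta_x_nm`` are NaN unless a
    rupture was observed below the force ceiling; ``censored`` marks cycles
    whose folded structure survived the whole ramp."""

    cycle_id: int
    molecule_id: int
    hold_time_s: float
    ruptured: bool
    censored: bool
    force_pN: float = float("nan")
    delta_x_nm: float = float("nan")
    state_label_truth: str = "unfolded"


def simulate_cycles(
    mixture: StateMixture,
    protocol: RampProtocol,
    polymer: PolymerParams = SSDNA,
    noise: NoiseModel = NoiseModel(),
    n_cycles: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_molecules: int = 5,
    hold_time: float | None = None,
) -> list[PullCycle]:
    """Simulate ``n_cycles`` force-ramp pull cycles from a state mixture.

    Per cycle: draw the adopted conformation from the mixture; for a folded
    state draw the rupture force from the exact Bell ramp distribution
    (censored if it exceeds the force ceiling), and an extension jump from
    the WLC forward model plus N(0, sigma_step²) noise.  Cycles are assigned
    to ``n_molecules`` tethers in contiguous blocks.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if len(mixture.states) == 0 and mixture.w_unfolded < 1.0:
        raise ValueError("mixture has no states")
    rng = _rng_from(seed, rng)
    hold = protocol.hold_time if hold_time is None else hold_time

    probs = np.array(list(mixture.weights) + [mixture.w_unfolded])
    probs = probs / probs.sum()
    outcomes = rng.choice(len(probs), size=n_cycles, p=probs)
    unfolded_idx = len(mixture.states)

    cycles: list[PullCycle] = []
    for i, outcome in enumerate(outcomes):
        mol = int(i * n_molecules // n_cycles)
        if outcome == unfolded_idx:
            cycles.append(
                PullCycle(i, mol, hold, ruptured=False, censored=False)
            )
            continue
        state = mixture.states[outcome]
        f = sample_force(state, protocol, rng.uniform())
        if f > protocol.f_end:
            cycles.append(
                PullCycle(
                    i, mol, hold, ruptured=False, censored=True,
                    state_label_truth=state.label,
                )
            )
            continue
        dx = step_from_nt(state.step_nt, f, polymer) + rng.normal(0.0, noise.sigma_step)
        cycles.append(
            PullCycle(
                i, mol, hold, ruptured=True, censored=False,
                force_pN=f, delta_x_nm=dx, state_label_truth=state.label,
            )
        )
    return cycles


def simulate_pfold_series(
    p_st: float,
    k_fold: float,
    hold_times,
    n_per_time: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Binomial folded counts under p_fold(t) = p_st·[1 − exp(−k_fold·t)].

    Returns a frame with columns (t_s, n_folded, n_total).
    """
    if not 0.0 <= p_st <= 1.0:
        raise ValueError("p_st must be a probability")
    if not k_fold > 0:
        raise ValueError("k_fold must be > 0")
    rng = _rng_from(seed, rng)
    times = np.asarray(list(hold_times), dtype=float)
    p = p_st * (1.0 - np.exp(-k_fold * times))
    n_folded = rng.binomial(n_per_time, p)
    return pd.DataFrame(
        {"t_s": times, "n_folded": n_folded, "n_total": n_per_time}
    )


def simulate_trace(
    cycle: PullCycle,
    protocol: RampProtocol,
    polymer: PolymerParams = SSDNA,
    noise: NoiseModel = NoiseModel(),
    handle: PolymerParams = DSDNA_HANDLE,
    handle_nt: int = 1700,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Extension-vs-time trace for one ramp: dsDNA-handle WLC baseline plus a
    single upward step of the cycle's extension jump at its rupture force,
    plus per-sample Gaussian bead noise.

    Returns a frame with columns (time_s, force_pN, extension_nm).
    """
    rng = _rng_from(seed, rng)
    dt = 1.0 / noise.trace_rate
    t = np.arange(0.0, protocol.ramp_duration() + dt / 2, dt)
    f = protocol.f_start + protocol.loading_rate * t

    # Handle fractional extension via a dense interpolation table (the
    # Marko-Siggia inversion is smooth; 400 knots keep the error << noise).
    z_grid = np.linspace(1e-6, 0.995, 400)
    f_grid = wlc_force(z_grid, handle)
    z = np.interp(f, f_grid, z_grid)
    baseline = handle_nt * handle.contour_per_nt * z

    extension = baseline.copy()
    if cycle.ruptured and np.isfinite(cycle.force_pN):
        t_rupt = (cycle.force_pN - protocol.f_start) / protocol.loading_rate
        extension[t >= t_rupt] += cycle.delta_x_nm
    if noise.sigma_bead > 0:
        extension = extension + rng.normal(0.0, noise.sigma_bead, size=t.size)
    return pd.DataFrame({"time_s": t, "force_pN": f, "extension_nm": extension})


def simulate_melting_curve(
    tm: float,
    width: float,
    baselines: tuple[float, float] = (1.0, 0.0),
    t_grid=None,
    noise_sd: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sigmoidal thermal-denaturation profile of the normalized 265 nm signal.

    y(T) = y_f + (y_u − y_f)/(1 + exp(−(T − tm)/width)) + N(0, noise_sd²),
    evaluated on ``t_grid`` (default: 1 °C steps from 20 to 85 °C).
    """
    if not width > 0:
        raise ValueError("width must be > 0")
    rng = _rng_from(seed, rng)
    if t_grid is None:
        t_grid = np.arange(20.0, 85.0 + 1e-9, 1.0)
    t = np.asarray(t_grid, dtype=float)
    y_f, y_u = baselines
    y = y_f + (y_u - y_f) / (1.0 + np.exp(-(t - tm) / width))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"temp_C": t, "signal": y})


def cycles_to_frame(cycles: list[PullCycle]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cycle_id": c.cycle_id,
                "molecule_id": c.molecule_id,
                "hold_time_s": c.hold_time_s,
                "ruptured": c.ruptured,
                "censored": c.censored,
                "force_pN": c.force_pN,
                "delta_x_nm": c.delta_x_nm,
                "state_label_truth": c.state_label_truth,
            }
            for c in cycles
        ],
        columns=CYCLE_COLUMNS,
    )


def write_cycles_tsv(cycles: list[PullCycle], path) -> None:
    cycles_to_frame(cycles).to_csv(path, sep="\t", index=False)


def read_cycles_tsv(path) -> pd.DataFrame:
    """Read a pull-cycle table; raises with the offending line number on
    malformed input."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("ruptured", "censored", "force_pN") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[df["ruptured"].astype(bool) & ~np.isfinite(df["force_pN"])]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise ValueError(f"{path}: line {bad[0] + 2}: ruptured cycle without a force")
    return df


def forces_from_cycles(cycles) -> tuple[np.ndarray, int]:
    """Extract (observed rupture forces, censored-cycle count) from a cycle
    list or frame."""
    df = cycles if isinstance(cycles, pd.DataFrame) else cycles_to_frame(cycles)
    forces = df.loc[df["ruptured"].astype(bool), "force_pN"].to_numpy(dtype=float)
    n_censored = int(df["censored"].astype(bool).sum())
    return forces, n_censored
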