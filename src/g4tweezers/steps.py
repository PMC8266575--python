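"""Rupture-step detection in extension traces and step-size summaries.

The detector slides a two-window change-point scan over the trace: at each
candidate point the step height is estimated by least squares under a local
piecewise model with a shared slope (a drift-corrected two-window mean
difference), and compared with its standard error (noise estimated robustly
from first differences).  The single maximal upward step is reported if its
SNR clears ``min_snr``.

Summaries convert each event's extension jump to released nucleotides at its
own rupture force (WLC at-force conversion) and average per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polymer import PolymerParams, SSDNA, nt_from_step

__all__ = ["DetectedStep", "detect_step", "summarize_steps"]


@dataclass(frozen=True)
class DetectedStep:
    """One detected rupture: time (s), force at the change point (pN), step
    amplitude Δx (nm), and detection SNR."""

    time: float
    force: float
    delta_x: float
    snr: float
    index: int


def _step_kernel(w: int) -> np.ndarray:
    """OLS coefficient row for the step height in the local model
    x = a + b·i + Δ·1[i ≥ k] over the 2w samples around a candidate change
    point.  The shared slope absorbs the smooth handle-stretching drift
    during the ramp, which a plain mean difference mistakes for a step; the
    row depends only on the window length, so the whole scan is one
    correlation."""
    m = 2 * w
    rel = np.arange(m, dtype=float)
    design = np.column_stack([np.ones(m), rel, (rel >= w).astype(float)])
    h = np.linalg.solve(design.T @ design, design.T)
    return h[2]


def _boundary_gaps(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Step-height estimate Δ̂(k) at every admissible change point k."""
    kernel = _step_kernel(w)
    gap = np.convolve(x, kernel[::-1], mode="valid")
    k = np.arange(w, x.size - w + 1)
    return k, gap


def detect_step(
    trace: pd.DataFrame, window: int = 25, min_snr: float = 5.0
) -> DetectedStep | None:
    """Find the single largest upward step in a uniformly sampled trace.

    Returns None when no candidate clears ``min_snr``.  Raises if the trace
    is shorter than two windows or the window is below 5 samples.
    """
    if window < 5:
        raise ValueError("window must be >= 5 samples")
    x = trace["extension_nm"].to_numpy(dtype=float)
    if x.size < 2 * window:
        raise ValueError("trace shorter than two windows")
    t = trace["time_s"].to_numpy(dtype=float)
    f = trace["force_pN"].to_numpy(dtype=float)

    k, gap = _boundary_gaps(x, window)
    # An upward step must also raise the plain window-mean difference; this
    # vetoes sign-flipped artifacts the slope term can produce next to
    # downward transients.
    c = np.concatenate([[0.0], np.cumsum(x)])
    mean_diff = (c[k + window] - c[k]) / window - (c[k] - c[k - window]) / window
    upward = (gap > 0) & (mean_diff > 0)
    if not np.any(upward):
        return None
    # Robust noise scale from first differences (insensitive to one step and
    # to slow drift); Var(Δ̂) = sigma^2 ||kernel||^2.
    d1 = np.diff(x)
    sigma = np.median(np.abs(d1 - np.median(d1))) / (0.6745 * np.sqrt(2.0))
    if sigma == 0.0:
        masked = np.where(upward, gap, -np.inf)
        i_best = int(np.argmax(masked))
        snr_best = np.inf
    else:
        se = sigma * float(np.linalg.norm(_step_kernel(window)))
        snr = np.where(upward, gap / se, -np.inf)
        i_best = int(np.argmax(snr))
        snr_best = float(snr[i_best])
    if not snr_best >= min_snr:
        return None
    kp = int(k[i_best])
    return DetectedStep(
        time=float(t[kp]),
        force=float(f[kp]),
        delta_x=float(gap[i_best]),
        snr=snr_best,
        index=kp,
    )


def summarize_steps(
    events: pd.DataFrame,
    polymer: PolymerParams = SSDNA,
    labels=None,
    force_bins=None,
) -> pd.DataFrame:
    """Per-group mean step size in nm and released nucleotides.

    ``events`` must carry ``force_pN`` and ``delta_x_nm``.  Grouping is by
    explicit per-event ``labels`` (e.g. a mixture fit's posterior
    assignment), else by ``force_bins`` edges, else one pooled group.  Each
    event is converted to nucleotides at its own rupture force before
    averaging.  Empty groups are dropped.
    """
    df = events.dropna(subset=["force_pN", "delta_x_nm"])
    if len(df) == 0:
        raise ValueError("no events with force and step size")
    if labels is not None:
        group = np.asarray(labels)
        if group.shape[0] != len(df):
            raise ValueError("labels length must match the number of events")
    elif force_bins is not None:
        edges = np.asarray(force_bins, dtype=float)
        group = pd.cut(df["force_pN"], bins=edges).astype(str).to_numpy()
    else:
        group = np.repeat("all", len(df))

    nt = np.array(
        [
            nt_from_step(dx, f, polymer)
            for dx, f in zip(df["delta_x_nm"], df["force_pN"])
        ]
    )
    out = (
        pd.DataFrame(
            {
                "group": group,
                "force_pN": df["force_pN"].to_numpy(),
                "delta_x_nm": df["delta_x_nm"].to_numpy(),
                "step_nt": nt,
            }
        )
        .groupby("group")
        .agg(
            n=("step_nt", "size"),
            mean_force_pN=("force_pN", "mean"),
            mean_delta_x_nm=("delta_x_nm", "mean"),
            sd_delta_x_nm=("delta_x_nm", "std"),
            mean_step_nt=("step_nt", "mean"),
            sd_step_nt=("step_nt", "std"),
        )
        .reset_index()
    )
    return out
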