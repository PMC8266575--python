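"""Sigmoid fits of thermal melting profiles.

The normalized 265 nm signal of a G4 melting experiment is modelled as a
phenomenological logistic transition between a folded and an unfolded
baseline,

    y(T) = y_f + (y_u − y_f) / (1 + exp(−(T − tm)/width)),

whose inflection point ``tm`` is the melting temperature.  The fit is
nonlinear least squares with a multi-start grid on ``tm``; because the model
is affine in (y_f, y_u), the extracted ``tm`` is invariant to affine
rescaling of the signal, so raw and normalized profiles give the same Tm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["MeltingFit", "sigmoid", "fit_melting"]


@dataclass
class MeltingFit:
    """Fitted melting profile: tm and width in °C, folded/unfolded baselines,
    residual sum of squares.  ``identifiable`` is False for flat profiles
    (no resolvable transition); ``in_range`` is False when tm extrapolates
    outside the measured temperature window."""

    tm: float
    width: float
    y_folded: float
    y_unfolded: float
    rss: float
    n_points: int
    identifiable: bool = True
    in_range: bool = True

    def predict(self, t) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float), self.tm, self.width,
                       self.y_folded, self.y_unfolded)

    def to_dict(self) -> dict:
        return {
            "tm_C": self.tm,
            "width_C": self.width,
            "y_folded": self.y_folded,
            "y_unfolded": self.y_unfolded,
            "rss": self.rss,
            "n_points": self.n_points,
            "identifiable": self.identifiable,
            "in_range": self.in_range,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def sigmoid(t, tm, width, y_f, y_u):
    return y_f + (y_u - y_f) / (1.0 + np.exp(-(t - tm) / width))


def fit_melting(curve: pd.DataFrame) -> MeltingFit:
    """Fit the logistic melting model to a (temp_C, signal) table.

    Needs at least 8 points.  A flat profile (amplitude indistinguishable
    from the residual noise) is returned flagged ``identifiable=False``.
    """
    t = curve["temp_C"].to_numpy(dtype=float)
    y = curve["signal"].to_numpy(dtype=float)
    if t.size < 8:
        raise ValueError("at least 8 points are required")
    order = np.argsort(t)
    t, y = t[order], y[order]

    t_lo, t_hi = t.min(), t.max()
    span = t_hi - t_lo
    best = None
    for tm0 in np.linspace(t_lo + 0.1 * span, t_hi - 0.1 * span, 7):
        p0 = [tm0, max(span / 15.0, 0.5), float(y[:3].mean()), float(y[-3:].mean())]
        try:
            popt, _ = curve_fit(
                sigmoid, t, y, p0=p0,
                bounds=([t_lo - span, 1e-3, -np.inf, -np.inf],
                        [t_hi + span, span, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((sigmoid(t, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("melting fit did not converge from any start")
    (tm, width, y_f, y_u), rss = best

    resid_sd = np.sqrt(rss / max(t.size - 4, 1))
    amplitude = abs(y_u - y_f)
    identifiable = bool(amplitude > 3.0 * resid_sd)
    in_range = bool(t_lo <= tm <= t_hi)
    return MeltingFit(
        tm=float(tm),
        width=float(abs(width)),
        y_folded=float(y_f),
        y_unfolded=float(y_u),
        rss=rss,
        n_points=int(t.size),
        identifiable=identifiable,
        in_range=in_range,
    )
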