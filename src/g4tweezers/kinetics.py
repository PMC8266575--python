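"""Folding-probability kinetics after a low-force hold.

After each ramp the molecule is dropped to a low hold force for a time ``t``;
the probability that it has refolded by the next stretch follows first-order
saturation kinetics

    p_fold(t) = p_st · [1 − exp(−k_fold·t)],

with ``p_st`` the steady-state folding probability and ``k_fold`` the
apparent folding rate of all folded species combined.  Counts per hold time
are binomial, so the fit is a binomial MLE with standard errors from the
observed information; a per-tether mode reports the mean ± SD across tethers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "FoldingKineticsResult",
    "pfold_model",
    "fit_pfold",
    "fit_pfold_by_tether",
    "split_pst_by_stability",
]


@dataclass
class FoldingKineticsResult:
    """(p_st, k_fold) with standard errors and fit diagnostics."""

    p_st: float
    k_fold: float
    se_p_st: float
    se_k_fold: float
    deviance: float
    n_points: int
    identifiable: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_st <= 1.0:
            raise ValueError("p_st must be a probability")
        if not self.k_fold > 0:
            raise ValueError("k_fold must be > 0")

    def predict(self, t) -> np.ndarray:
        return pfold_model(t, self.p_st, self.k_fold)

    def to_dict(self) -> dict:
        return {
            "p_st": self.p_st,
            "k_fold_per_s": self.k_fold,
            "se_p_st": self.se_p_st,
            "se_k_fold_per_s": self.se_k_fold,
            "deviance": self.deviance,
            "n_points": self.n_points,
            "identifiable": self.identifiable,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pfold_model(t, p_st: float, k_fold: float):
    """p_fold(t) = p_st·[1 − exp(−k_fold·t)]; p_fold(0) = 0 exactly."""
    return p_st * (1.0 - np.exp(-k_fold * np.asarray(t, dtype=float)))


def _binom_nll(theta, t, n_folded, n_total) -> float:
    p_st, k_fold = theta
    p = np.clip(pfold_model(t, p_st, k_fold), 1e-12, 1.0 - 1e-12)
    return float(-np.sum(n_folded * np.log(p) + (n_total - n_folded) * np.log1p(-p)))


def _hessian(fun, x, eps=1e-5) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    steps = eps * np.maximum(np.abs(x), 1.0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            h[i, j] = h[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return h


def fit_pfold(table: pd.DataFrame) -> FoldingKineticsResult:
    """Binomial MLE of (p_st, k_fold) from a (t_s, n_folded, n_total) table.

    Requires at least 3 distinct positive hold times.  All-zero or
    all-saturated counts leave the model non-identifiable: the result is
    returned with ``identifiable=False`` and boundary-safe values.
    """
    t = table["t_s"].to_numpy(dtype=float)
    n_folded = table["n_folded"].to_numpy(dtype=float)
    n_total = table["n_total"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("hold times must be strictly positive")
    if np.any(n_folded < 0) or np.any(n_folded > n_total):
        raise ValueError("need 0 <= n_folded <= n_total")
    if len(np.unique(t)) < 3:
        raise ValueError("at least 3 distinct hold times are required")

    bounds = [(1e-6, 1.0), (1e-6, 50.0)]
    best = None
    for k0 in (0.01, 0.03, 0.1, 0.3, 1.0):
        res = minimize(
            _binom_nll,
            np.array([min(max(n_folded.sum() / n_total.sum(), 0.05), 0.99), k0]),
            args=(t, n_folded, n_total),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    p_st, k_fold = best.x

    identifiable = bool(
        0 < n_folded.sum() < n_total.sum() and np.std(n_folded / n_total) > 0
    )
    se_p, se_k = float("nan"), float("nan")
    if identifiable:
        h = _hessian(lambda x: _binom_nll(x, t, n_folded, n_total), best.x)
        try:
            cov = np.linalg.inv(h)
            if np.all(np.diag(cov) > 0):
                se_p, se_k = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass

    # Deviance against the saturated binomial model.
    p_hat = np.clip(pfold_model(t, p_st, k_fold), 1e-12, 1 - 1e-12)
    p_obs = np.clip(n_folded / n_total, 1e-12, 1 - 1e-12)
    dev = 2.0 * float(
        np.sum(
            n_folded * np.log(p_obs / p_hat)
            + (n_total - n_folded) * np.log((1 - p_obs) / (1 - p_hat))
        )
    )
    return FoldingKineticsResult(
        p_st=float(p_st),
        k_fold=float(k_fold),
        se_p_st=se_p,
        se_k_fold=se_k,
        deviance=dev,
        n_points=len(t),
        identifiable=identifiable,
    )


def fit_pfold_by_tether(table: pd.DataFrame) -> dict:
    """Replicated-tether mode: fit each ``tether_id`` separately and report
    the across-tether mean ± SD of p_st and k_fold (mirrors averaging over
    independent DNA tethers)."""
    if "tether_id" not in table.columns:
        raise ValueError("table must carry a tether_id column")
    fits = {
        tid: fit_pfold(sub) for tid, sub in table.groupby("tether_id", sort=True)
    }
    p = np.array([f.p_st for f in fits.values()])
    k = np.array([f.k_fold for f in fits.values()])
    return {
        "p_st_mean": float(p.mean()),
        "p_st_sd": float(p.std(ddof=1)) if len(p) > 1 else 0.0,
        "k_fold_mean": float(k.mean()),
        "k_fold_sd": float(k.std(ddof=1)) if len(k) > 1 else 0.0,
        "n_tethers": len(fits),
        "per_tether": {str(tid): f.to_dict() for tid, f in fits.items()},
    }


def split_pst_by_stability(cycles, threshold: float = 40.0) -> tuple[float, float]:
    """Apportion the folded fraction of a cycle table between mechanically
    stable (rupture force above ``threshold``; censored cycles count as
    stable) and less stable species.  Returns (p_full, p_partial), fractions
    of all cycles; their sum is the overall folded fraction."""
    from .simulate import cycles_to_frame  # local import to avoid a cycle

    df = cycles if isinstance(cycles, pd.DataFrame) else cycles_to_frame(cycles)
    n = len(df)
    if n == 0:
        raise ValueError("empty cycle table")
    ruptured = df["ruptured"].astype(bool)
    censored = df["censored"].astype(bool)
    full = int((ruptured & (df["force_pN"] > threshold)).sum() + censored.sum())
    partial = int((ruptured & (df["force_pN"] <= threshold)).sum())
    return full / n, partial / n
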