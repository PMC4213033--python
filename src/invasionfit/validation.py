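"""Model validation: leave-one-out cross-validation and spatial diagnostics.

LOOCV refits the regression n times, each time predicting the single
held-out site, giving PRESS (the summed squared held-out errors) and a
cross-validated R² whose drop from the in-sample R² measures overfitting.

Moran's I correlograms quantify spatial autocorrelation of a site-level
variable (a response, or the residuals of the averaged model) across
great-circle distance bands, with an optional permutation envelope as the
reference for "no spatial structure".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .averaging import run_model_averaging
from .predictors import pairwise_distances_km


@dataclass
class LoocvResult:
    predictions: np.ndarray  # held-out prediction per site, original row order
    press: float
    mse_cv: float
    r_squared_cv: float
    mse_fit: float
    r_squared_fit: float
    percent_r2_decrease: float
    refit_mode: str


def r2_shrinkage(r_squared_fit: float, r_squared_cv: float) -> float:
    """Percent drop in R² under cross-validation: 100·(fit − cv)/fit."""
    if r_squared_fit <= 0:
        raise ValueError("shrinkage undefined for nonpositive in-sample R²")
    return 100.0 * (r_squared_fit - r_squared_cv) / r_squared_fit


def _ols_fit_predict(Xtr, ytr, Xte):
    beta, _, _, _ = np.linalg.lstsq(
        np.column_stack([np.ones(len(ytr)), Xtr]), ytr, rcond=None
    )
    return np.column_stack([np.ones(Xte.shape[0]), Xte]) @ beta


def loocv(X: pd.DataFrame, y, refit_mode: str = "full_model",
          averaging_mode: str = "conditional") -> LoocvResult:
    """Leave-one-out cross-validation of the site-level regression.

    ``full_model`` refits the single OLS model containing all predictors
    on each n−1 subset (the model whose coefficients the averaging stage
    weights); ``reaverage`` reruns the entire all-subsets averaging
    procedure inside every fold, which is slower but propagates model
    selection uncertainty into the held-out predictions.

    R²_cv is computed as 1 − PRESS/SST with SST about the full-sample mean.
    """
    if refit_mode not in ("full_model", "reaverage"):
        raise ValueError(f"unknown refit mode {refit_mode!r}")
    y = np.asarray(y, dtype=float)
    n = y.size
    p = X.shape[1]
    if n < 10:
        raise ValueError("LOOCV requires at least 10 sites")
    if n - 1 <= p + 2:
        raise ValueError(f"n={n} too small for a {p}-predictor design")

    Xmat = X.to_numpy(dtype=float)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        if refit_mode == "full_model":
            preds[i] = _ols_fit_predict(Xmat[keep], y[keep], Xmat[i:i + 1])[0]
        else:
            avg, _ = run_model_averaging(X.iloc[keep], y[keep],
                                         mode=averaging_mode)
            preds[i] = avg.predict(X.iloc[i:i + 1])[0]

    press = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))

    if refit_mode == "full_model":
        fitted = _ols_fit_predict(Xmat, y, Xmat)
    else:
        avg, _ = run_model_averaging(X, y, mode=averaging_mode)
        fitted = avg.predict(X)
    sse_fit = float(np.sum((y - fitted) ** 2))
    r2_fit = 1.0 - sse_fit / sst if sst > 0 else 0.0
    r2_cv = 1.0 - press / sst if sst > 0 else 0.0
    pct = r2_shrinkage(r2_fit, r2_cv) if r2_fit > 0 else math.nan
    return LoocvResult(
        predictions=preds,
        press=press,
        mse_cv=press / n,
        r_squared_cv=r2_cv,
        mse_fit=sse_fit / n,
        r_squared_fit=r2_fit,
        percent_r2_decrease=pct,
        refit_mode=refit_mode,
    )


@dataclass
class CorrelogramResult:
    bin_edges: np.ndarray  # km, length n_bins + 1
    morans_i: np.ndarray  # NaN for empty bins
    n_pairs: np.ndarray  # unordered pairs per bin
    expected: float  # -1/(n-1), the no-autocorrelation expectation
    envelope_lo: np.ndarray | None = None
    envelope_hi: np.ndarray | None = None
    notes: list = field(default_factory=list)

    def to_frame(self, variable: str = "") -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "morans_i": self.morans_i,
            "n_pairs": self.n_pairs,
        })
        if self.envelope_lo is not None:
            df["env_lo"] = self.envelope_lo
            df["env_hi"] = self.envelope_hi
        if variable:
            df.insert(0, "variable", variable)
        return df


def default_lag_bins(dmat: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """10 equal-width bins to the 90th percentile of pairwise distance,
    plus one catch-all bin to the maximum so every pair is counted."""
    iu = np.triu_indices_from(dmat, k=1)
    d = dmat[iu]
    p90 = float(np.percentile(d, 90))
    dmax = float(d.max())
    edges = np.linspace(0.0, p90, n_bins + 1)
    if dmax > p90:
        edges = np.append(edges, dmax)
    return edges


def morans_i(values, coords, bin_edges_km=None, n_permutations: int = 0,
             seed: int = 0, alpha: float = 0.05) -> CorrelogramResult:
    """Moran's I per great-circle distance band, binary band weights.

    For band b with weight matrix w_ij = 1 iff d_ij falls in the band,
    I_b = (n/W)·Σ_ij w_ij z_i z_j / Σ_i z_i² with z the centered values and
    W the total (ordered) weight.  ``n_permutations ≥ 1`` adds a two-sided
    (1−alpha) permutation envelope from random relabelings of the sites.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError("Moran's I correlogram requires at least 10 sites")
    if np.ptp(values) < 1e-300 or values.std() == 0:
        raise ValueError("Moran's I is undefined for constant values")

    dmat = pairwise_distances_km(coords[:, 0], coords[:, 1])
    if bin_edges_km is None:
        bin_edges_km = default_lag_bins(dmat)
    edges = np.asarray(bin_edges_km, dtype=float)
    n_bins = edges.size - 1

    iu, ju = np.triu_indices(n, k=1)
    pair_d = dmat[iu, ju]
    # right-inclusive final bin so the maximum distance is counted
    which = np.digitize(pair_d, edges[1:-1], right=False)
    which[pair_d > edges[-1]] = -1
    which[pair_d < edges[0]] = -1

    z = values - values.mean()
    denom = float(z @ z)
    notes = []
    I = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    pair_idx = []
    for b in range(n_bins):
        m = which == b
        pair_idx.append((iu[m], ju[m]))
        n_pairs[b] = int(m.sum())
        if n_pairs[b] == 0:
            notes.append(f"bin {b} empty, skipped")
            continue
        num = 2.0 * float(np.sum(z[iu[m]] * z[ju[m]]))
        W = 2.0 * n_pairs[b]
        I[b] = (n / W) * num / denom

    res = CorrelogramResult(
        bin_edges=edges, morans_i=I, n_pairs=n_pairs,
        expected=-1.0 / (n - 1), notes=notes,
    )
    if n_permutations >= 1:
        rng = np.random.default_rng(seed)
        sims = np.full((n_permutations, n_bins), np.nan)
        for k in range(n_permutations):
            zp = z[rng.permutation(n)]
            for b, (ib, jb) in enumerate(pair_idx):
                if ib.size == 0:
                    continue
                sims[k, b] = (n / (2.0 * ib.size)) * 2.0 * float(
                    np.sum(zp[ib] * zp[jb])
                ) / denom
        res.envelope_lo = np.nanpercentile(sims, 100 * alpha / 2, axis=0)
        res.envelope_hi = np.nanpercentile(sims, 100 * (1 - alpha / 2), axis=0)
    return res
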