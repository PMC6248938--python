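"""Linear-quadratic fitting of instantaneous-irradiation clonogenic data.

Estimates the intrinsic LQ coefficients alpha0 (Gy^-1) and beta0 (Gy^-2)
from surviving fractions measured after single instantaneous irradiations:

    -ln S = alpha0 * D + beta0 * D^2        (no intercept)

by weighted least squares with nonnegativity constraints, the standard
radiobiology convention.  When replicate measurements exist at each dose,
weights are the inverse replicate variances of -ln S; otherwise uniform.
Standard errors come from the normal equations restricted to the active
(nonzero) coefficients.  The +/- on the estimates is a standard error;
with few doses and large scatter it can exceed the estimate itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = ["SurvivalDataset", "LQFit", "fit_lq", "predict_survival_curve"]


@dataclass
class SurvivalDataset:
    """Clonogenic survival observations.

    Wraps a DataFrame with columns ``dose_gy``, ``duration_h``, ``sf`` and
    ``replicate``.  When built from colony counts, the surviving fraction is
    colony_count / (plated_count * plating_efficiency); if the plating
    efficiency is not given it is taken from the mean 0 Gy control yield.
    """

    records: pd.DataFrame

    REQUIRED = ("dose_gy", "duration_h", "sf", "replicate")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("dataset is empty")
        if (df["dose_gy"] < 0).any():
            raise ValueError("doses must be >= 0")
        if (df["duration_h"] < 0).any():
            raise ValueError("durations must be >= 0")
        bad = df["sf"] <= 0
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} records have sf <= 0; surviving fractions "
                "must be positive (zero-colony wells cannot enter a log-scale fit)"
            )
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_counts(
        cls,
        dose_gy,
        duration_h,
        colony_count,
        plated_count,
        plating_efficiency: Optional[float] = None,
        replicate=None,
    ) -> "SurvivalDataset":
        dose = np.asarray(dose_gy, dtype=float)
        dur = np.asarray(duration_h, dtype=float)
        colonies = np.asarray(colony_count, dtype=float)
        plated = np.asarray(plated_count, dtype=float)
        if plating_efficiency is None:
            ctrl = (dose == 0) & (dur == 0)
            if not ctrl.any():
                raise ValueError(
                    "plating_efficiency not given and no 0 Gy control present"
                )
            plating_efficiency = float(np.sum(colonies[ctrl]) / np.sum(plated[ctrl]))
        if plating_efficiency <= 0:
            raise ValueError("plating efficiency must be > 0")
        sf = colonies / (plated * plating_efficiency)
        rep = np.zeros(dose.size, dtype=int) if replicate is None else np.asarray(replicate)
        return cls(pd.DataFrame({
            "dose_gy": dose, "duration_h": dur, "sf": sf, "replicate": rep,
        }))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurvivalDataset":
        """Read the survival CSV dialect.

        Columns: ``dose_gy``, ``duration_min``, ``replicate`` and either
        ``sf`` or ``colony_count`` + ``plated_count`` (optional scalar
        column ``plating_efficiency``).
        """
        df = pd.read_csv(path)
        if "duration_min" not in df.columns:
            raise ValueError(f"{path}: missing 'duration_min' column")
        dur_h = df["duration_min"].to_numpy(dtype=float) / 60.0
        rep = df["replicate"] if "replicate" in df.columns else 0
        if "sf" in df.columns:
            return cls(pd.DataFrame({
                "dose_gy": df["dose_gy"], "duration_h": dur_h,
                "sf": df["sf"], "replicate": rep,
            }))
        if {"colony_count", "plated_count"} <= set(df.columns):
            pe = None
            if "plating_efficiency" in df.columns:
                pe = float(df["plating_efficiency"].iloc[0])
            return cls.from_counts(
                df["dose_gy"], dur_h, df["colony_count"], df["plated_count"],
                plating_efficiency=pe,
                replicate=df["replicate"] if "replicate" in df.columns else None,
            )
        raise ValueError(f"{path}: need 'sf' or 'colony_count'+'plated_count' columns")

    def instantaneous(self) -> "SurvivalDataset":
        """Subset with duration 0 (instantaneous irradiations only)."""
        return SurvivalDataset(self.records[self.records["duration_h"] == 0].copy())


@dataclass(frozen=True)
class LQFit:
    """Result of a constrained LQ fit."""

    alpha0_hat: float
    beta0_hat: float
    alpha0_se: float
    beta0_se: float
    rss: float
    n_points: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LQFit(alpha0 = {self.alpha0_hat:.4f} +/- {self.alpha0_se:.4f} /Gy, "
            f"beta0 = {self.beta0_hat:.4f} +/- {self.beta0_se:.4f} /Gy^2, "
            f"n = {self.n_points})"
        )


# pseudo-degrees-of-freedom pulling per-dose variances toward the pooled
# value; raw few-replicate variances are too noisy to weight with directly
# and miscalibrate the standard errors
_VARIANCE_PRIOR_DF = 20.0


def _replicate_weights(dose: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Inverse moderated replicate variance of -ln S, or uniform if unusable.

    Per-dose sample variances are shrunk toward the pooled variance with
    df-proportional weight (a moderated-variance scheme): with a handful of
    replicates per dose the raw variances are so noisy that their
    reciprocals make the fit anticonservative.
    """
    weights = np.ones_like(y)
    groups = {d: np.flatnonzero(dose == d) for d in np.unique(dose)}
    if all(idx.size < 2 for idx in groups.values()):
        return weights
    variances, dfs = {}, {}
    for d, idx in groups.items():
        if idx.size >= 2:
            variances[d] = float(np.var(y[idx], ddof=1))
            dfs[d] = idx.size - 1
    if not variances:
        return weights
    pooled = sum(variances[d] * dfs[d] for d in variances) / sum(dfs.values())
    if pooled <= 0:
        return weights  # noiseless replicates: fall back to uniform
    for d, idx in groups.items():
        df = dfs.get(d, 0)
        raw = variances.get(d, pooled)
        shrunk = (df * raw + _VARIANCE_PRIOR_DF * pooled) / (df + _VARIANCE_PRIOR_DF)
        weights[idx] = 1.0 / shrunk
    return weights


def fit_lq(data: SurvivalDataset, weights=None) -> LQFit:
    """Fit -ln S = alpha0 D + beta0 D^2 to instantaneous-irradiation data.

    All records must have duration 0 and the design needs at least 3
    distinct doses, 2 of them positive (otherwise the two coefficients are
    not separable).  Coefficients are constrained nonnegative (NNLS on the
    weighted design).  ``weights`` overrides the default inverse-replicate-
    variance weighting (one value per record).
    """
    df = data.records
    if (df["duration_h"] != 0).any():
        raise ValueError(
            "fit_lq requires instantaneous (duration 0) records; use "
            ".instantaneous() to subset"
        )
    dose = df["dose_gy"].to_numpy(dtype=float)
    if np.unique(dose).size < 3:
        raise ValueError("need at least 3 distinct dose levels")
    if np.unique(dose[dose > 0]).size < 2:
        raise ValueError(
            "rank-deficient design: need at least 2 distinct positive doses "
            "to separate alpha0 and beta0"
        )
    y = -np.log(df["sf"].to_numpy(dtype=float))
    if weights is None:
        weights = _replicate_weights(dose, y)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != y.shape or np.any(weights <= 0):
            raise ValueError("weights must be positive, one per record")
    X = np.column_stack([dose, dose**2])
    sw = np.sqrt(weights)
    coef, _ = scipy.optimize.nnls(X * sw[:, None], y * sw)
    resid = y - X @ coef
    rss = float(np.sum(weights * resid**2))
    n, p = y.size, 2
    sigma2 = rss / max(n - p, 1)
    # SEs from the normal equations on the active set; a coefficient pinned
    # at the zero bound gets the SE it would have if freed (conservative).
    xtwx = (X * weights[:, None]).T @ X
    try:
        cov = sigma2 * np.linalg.inv(xtwx)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(2, np.nan)
    return LQFit(
        alpha0_hat=float(coef[0]),
        beta0_hat=float(coef[1]),
        alpha0_se=float(ses[0]),
        beta0_se=float(ses[1]),
        rss=rss,
        n_points=int(n),
    )


def predict_survival_curve(fit: LQFit, doses) -> np.ndarray:
    """Predicted surviving fraction over a dose grid (instantaneous, F = 1)."""
    d = np.asarray(doses, dtype=float)
    return np.exp(-(fit.alpha0_hat * d + fit.beta0_hat * d**2))
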