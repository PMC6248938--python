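"""Synthetic study inputs with known ground truth.

The real study obtained its inputs from Monte Carlo radiation transport
(lineal-energy spectra, y_D depth profiles) and a wet-lab clonogenic assay.
This module generates statistically matched stand-ins from known
parameters so every downstream stage is testable end to end:

- :func:`generate_spectrum` — lognormal-shaped f(y) whose binned dose-mean
  lineal energy hits a requested target (the only functional of f(y) the
  MKM consumes);
- :func:`generate_depth_profile` — linear y_D-vs-depth trend with seeded
  Gaussian jitter;
- :func:`generate_assay` — clonogenic colony counts drawn Poisson around
  the modified-MKM forward model.

Defaults mirror the study conditions: doses {2, 4, 8} Gy, delivery times
{0, 1, 5, 10, 30, 60} min, repair rate 0.46 h^-1, target y_D near
2.3 keV/um.  Same seed => bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .core import DeliverySchedule, MKMParameters, neg_log_survival
from .lq import SurvivalDataset
from .microdosimetry import DepthProfile, LinealEnergySpectrum, dose_mean_lineal_energy

__all__ = [
    "SpectrumGeneratorSpec",
    "AssayGeneratorSpec",
    "generate_spectrum",
    "generate_depth_profile",
    "generate_assay",
]

# relative tolerance on hitting the target y_D after the binned root solve
_YD_RTOL = 5e-3


@dataclass(frozen=True)
class SpectrumGeneratorSpec:
    """Recipe for a synthetic lineal-energy spectrum.

    ``shape`` is the lognormal sigma (log-space width); the log-scale mu is
    solved so the binned y_D equals ``target_yd``.  ``noise`` adds seeded
    relative jitter to the bin densities (the scale solve runs after the
    jitter, so the target still holds).
    """

    target_yd: float
    shape: float = 0.45
    n_bins: int = 120
    y_range: tuple[float, float] = (0.05, 30.0)
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_yd <= 0:
            raise ValueError(f"target_yd must be > 0, got {self.target_yd}")
        if self.n_bins < 10:
            raise ValueError(f"n_bins must be >= 10, got {self.n_bins}")
        if self.shape <= 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        lo, hi = self.y_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid y_range {self.y_range}")
        if self.noise < 0:
            raise ValueError(f"noise must be >= 0, got {self.noise}")


@dataclass(frozen=True)
class AssayGeneratorSpec:
    """Recipe for a synthetic clonogenic survival assay.

    Ground-truth survival comes from the modified MKM with the given
    parameters; observed colony counts are Poisson around
    plated * PE * SF per well.  ``noise=False`` returns the exact forward-
    model surviving fractions (no sampling).
    """

    true_alpha0: float = 0.24
    true_beta0: float = 0.06
    true_gamma: float = 2.96
    true_repair_rate: float = 0.46
    dose_levels: tuple[float, ...] = (2.0, 4.0, 8.0)
    durations_min: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 30.0, 60.0)
    replicates: int = 6
    plated_count: int = 200
    plating_efficiency: float = 0.7
    # clonogenic protocols seed more cells at higher doses so each dish
    # still yields countable colonies; scaling divides the plated count by
    # the expected surviving fraction (capped) per condition
    scale_plating_to_dose: bool = True
    max_plated: int = 10**7
    noise: bool = True
    pe_jitter_sd: float = 0.0  # lognormal sigma on per-well PE, robustness knob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_alpha0 < 0 or self.true_beta0 < 0:
            raise ValueError("true_alpha0/true_beta0 must be >= 0")
        if self.true_gamma <= 0 or self.true_repair_rate <= 0:
            raise ValueError("true_gamma and true_repair_rate must be > 0")
        if not self.dose_levels or any(d < 0 for d in self.dose_levels):
            raise ValueError("dose_levels must be non-empty and >= 0")
        if not self.durations_min or any(t < 0 for t in self.durations_min):
            raise ValueError("durations_min must be non-empty and >= 0")
        if self.replicates < 1 or self.plated_count < 1:
            raise ValueError("replicates and plated_count must be >= 1")
        if not (0 < self.plating_efficiency <= 1):
            raise ValueError("plating_efficiency must be in (0, 1]")
        if self.pe_jitter_sd < 0:
            raise ValueError("pe_jitter_sd must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def parameters(self) -> MKMParameters:
        return MKMParameters(
            alpha0=self.true_alpha0,
            beta0=self.true_beta0,
            repair_rate=self.true_repair_rate,
            gamma=self.true_gamma,
            label="synthetic-truth",
        )

    @property
    def true_lq_coefficients(self) -> tuple[float, float]:
        """Ground-truth (alpha, beta) of the instantaneous LQ curve.

        The forward model's linear term is alpha0 + gamma*beta0, so an LQ
        fit to T=0 data from this assay recovers these values, not alpha0
        itself; alpha0 follows by subtracting gamma*beta0 once gamma is
        known from microdosimetry.
        """
        return (
            self.true_alpha0 + self.true_gamma * self.true_beta0,
            self.true_beta0,
        )


def _binned_yd_for_mu(mu: float, sigma: float, edges: np.ndarray) -> float:
    """y_D of the lognormal(mu, sigma) density discretized onto the bins."""
    mid = 0.5 * (edges[:-1] + edges[1:])
    w = np.diff(edges)
    f = scipy.stats.lognorm.pdf(mid, s=sigma, scale=math.exp(mu))
    first = np.sum(mid * f * w)
    if first <= 0:
        return np.nan
    return float(np.sum(mid**2 * f * w) / first)


def generate_spectrum(spec: SpectrumGeneratorSpec) -> LinealEnergySpectrum:
    """Synthetic f(y) with a prescribed dose-mean lineal energy.

    Log-spaced bins over ``y_range``; lognormal density with the log-scale
    solved by 1-D root finding so that the binned y_D (after the seeded
    density jitter) matches ``target_yd`` within 0.5%.  Raises if the
    target is unattainable inside ``y_range``.
    """
    lo, hi = spec.y_range
    edges = np.geomspace(lo, hi, spec.n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    w = np.diff(edges)
    rng = np.random.default_rng(spec.seed)
    jitter = (
        np.exp(rng.normal(0.0, spec.noise, size=mid.size))
        if spec.noise > 0 else np.ones_like(mid)
    )

    def yd_err(mu: float) -> float:
        f = scipy.stats.lognorm.pdf(mid, s=spec.shape, scale=math.exp(mu)) * jitter
        first = np.sum(mid * f * w)
        if first <= 0:
            return np.nan
        return float(np.sum(mid**2 * f * w) / first) - spec.target_yd

    # continuous-limit mu as the bracket center: y_D = exp(mu + 1.5 sigma^2)
    mu0 = math.log(spec.target_yd) - 1.5 * spec.shape**2
    lo_mu, hi_mu = mu0 - 3.0, mu0 + 3.0
    try:
        e_lo, e_hi = yd_err(lo_mu), yd_err(hi_mu)
        if not (np.isfinite(e_lo) and np.isfinite(e_hi)) or e_lo * e_hi > 0:
            raise ValueError
        mu = scipy.optimize.brentq(yd_err, lo_mu, hi_mu, xtol=1e-12)
    except ValueError:
        raise ValueError(
            f"target y_D {spec.target_yd} keV/um unattainable with shape "
            f"{spec.shape} inside y_range {spec.y_range}"
        ) from None

    f = scipy.stats.lognorm.pdf(mid, s=spec.shape, scale=math.exp(mu)) * jitter
    f /= np.sum(f * w)
    out = LinealEnergySpectrum(
        y_edges=edges, f_density=f,
        label=f"synthetic yD={spec.target_yd} seed={spec.seed}",
    )
    achieved = dose_mean_lineal_energy(out)
    if abs(achieved - spec.target_yd) > _YD_RTOL * spec.target_yd:
        raise ValueError(
            f"solved spectrum misses target y_D: {achieved:.4f} vs {spec.target_yd}"
        )
    return out


def generate_depth_profile(
    base_yd: float,
    depths: Sequence[float],
    slope: float = -0.004,
    noise_sd: float = 0.01,
    seed: int = 0,
    ref_depth: float = 10.0,
) -> DepthProfile:
    """Linear y_D-vs-depth trend with seeded Gaussian jitter.

    y_D(depth) = base_yd + slope * (depth - ref_depth) + N(0, noise_sd).
    Emulates the slow drift of beam quality with depth in water; averaging
    a depth window then recovers the trend value at the window center to
    within the jitter's standard error.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("depths must be non-empty")
    if base_yd <= 0:
        raise ValueError(f"base_yd must be > 0, got {base_yd}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    yd = base_yd + slope * (depths - ref_depth)
    if noise_sd > 0:
        yd = yd + rng.normal(0.0, noise_sd, size=depths.size)
    if np.any(yd <= 0):
        raise ValueError("generated y_D fell to <= 0; reduce slope/noise or depth span")
    return DepthProfile(depths=depths, yd_values=yd)


def generate_assay(spec: AssayGeneratorSpec) -> SurvivalDataset:
    """Synthetic clonogenic assay from the modified-MKM forward model.

    One record per (dose, duration, replicate).  With ``noise=True`` each
    well's colony count is Poisson(plated * PE * SF_true) and the recorded
    surviving fraction is count / (plated * PE); PE may itself jitter
    lognormally per well when ``pe_jitter_sd > 0``.  With ``noise=False``
    the recorded sf is the exact model value.

    With ``scale_plating_to_dose`` (the default, mirroring lab practice)
    the plated count per condition is ``plated_count / SF_true`` rounded
    up and capped at ``max_plated``, keeping the expected colony yield
    roughly constant across doses.
    """
    params = spec.parameters()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for dose in spec.dose_levels:
        for t_min in spec.durations_min:
            sched = DeliverySchedule.from_minutes(dose, t_min)
            sf_true = neg_log_survival(params, sched).sf
            if spec.scale_plating_to_dose:
                plated = min(int(math.ceil(spec.plated_count / sf_true)), spec.max_plated)
            else:
                plated = spec.plated_count
            for rep in range(spec.replicates):
                if spec.noise:
                    pe = spec.plating_efficiency
                    if spec.pe_jitter_sd > 0:
                        pe *= float(rng.lognormal(
                            -0.5 * spec.pe_jitter_sd**2, spec.pe_jitter_sd
                        ))
                    count = int(rng.poisson(plated * pe * sf_true))
                    if count == 0:
                        continue  # zero-colony wells cannot enter a log fit
                    sf = count / (plated * spec.plating_efficiency)
                else:
                    sf = sf_true
                rows.append({
                    "dose_gy": dose,
                    "duration_h": t_min / 60.0,
                    "sf": sf,
                    "replicate": rep,
                })
    if not rows:
        raise ValueError("all wells produced zero colonies; assay is uninformative")
    return SurvivalDataset(pd.DataFrame(rows))
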