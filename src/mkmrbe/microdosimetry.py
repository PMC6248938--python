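"""Lineal-energy spectra: f(y), d(y), moments and depth averaging.

The lineal energy y (keV/um) is the energy imparted to a micron-scale site
divided by its mean chord length.  A beam's microdosimetric quality enters
the MKM solely through the dose-mean lineal energy

    y_D = int y^2 f(y) dy / int y f(y) dy,

the first moment of the dose-weighted distribution d(y) ~ y f(y).  Spectra
here are binned densities; all integrals use the midpoint rule on the
supplied bins (spectra in this field are typically log-binned; midpoints
are taken in linear y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LinealEnergySpectrum",
    "DepthProfile",
    "dose_distribution",
    "dose_mean_lineal_energy",
    "frequency_mean_lineal_energy",
    "average_yd_over_depths",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_depth_profile_csv",
    "write_depth_profile_csv",
]

logger = logging.getLogger(__name__)

# |integral - 1| <= this is silently exact; up to RENORM_MAX is corrected
# with a warning; beyond it the spectrum is rejected as corrupt.
_NORM_RTOL = 1e-6
_RENORM_MAX = 0.01


@dataclass
class LinealEnergySpectrum:
    """Binned frequency density f(y) of the lineal energy.

    ``y_edges`` are strictly increasing, nonnegative bin edges (keV/um,
    length n+1); ``f_density`` the per-bin density ((keV/um)^-1, length n).
    The density is renormalized to unit integral on construction; drift
    beyond 1% is treated as a corrupt input and rejected.
    """

    y_edges: np.ndarray
    f_density: np.ndarray
    label: str = ""
    depth: Optional[float] = None

    def __post_init__(self) -> None:
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.f_density = np.asarray(self.f_density, dtype=float)
        if self.y_edges.ndim != 1 or self.y_edges.size < 3:
            raise ValueError("need at least 2 bins (3 edges)")
        if self.f_density.shape != (self.y_edges.size - 1,):
            raise ValueError(
                f"f_density length {self.f_density.size} does not match "
                f"{self.y_edges.size - 1} bins"
            )
        if np.any(np.diff(self.y_edges) <= 0):
            raise ValueError("y_edges must be strictly increasing")
        if self.y_edges[0] < 0:
            raise ValueError("y_edges must be >= 0")
        if np.any(self.f_density < 0):
            raise ValueError("f_density must be >= 0")
        total = float(np.sum(self.f_density * self.bin_widths))
        if total <= 0:
            raise ValueError("f_density integrates to zero")
        drift = abs(total - 1.0)
        if drift > _RENORM_MAX:
            raise ValueError(
                f"f(y) integrates to {total:.6g}; drift {drift:.3g} exceeds "
                f"the {_RENORM_MAX:.0%} tolerance"
            )
        if drift > _NORM_RTOL:
            logger.warning(
                "spectrum %r: renormalizing f(y) (integral was %.8f)",
                self.label, total,
            )
        self.f_density = self.f_density / total

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.y_edges)

    @property
    def y_mid(self) -> np.ndarray:
        """Linear bin midpoints (keV/um)."""
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass(frozen=True)
class DepthProfile:
    """Dose-mean lineal energy versus depth in water."""

    depths: np.ndarray
    yd_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "yd_values", np.asarray(self.yd_values, dtype=float))
        if self.depths.ndim != 1 or self.depths.size == 0:
            raise ValueError("depths must be a non-empty 1-D array")
        if self.depths.shape != self.yd_values.shape:
            raise ValueError("depths and yd_values must have equal length")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.yd_values <= 0):
            raise ValueError("yd_values must be > 0")


def dose_distribution(spectrum: LinealEnergySpectrum) -> np.ndarray:
    """Dose-weighted density d(y) ~ y f(y), unit integral, same binning.

    Returns the per-bin density values ((keV/um)^-1) on the spectrum's bins.
    """
    raw = spectrum.y_mid * spectrum.f_density
    total = float(np.sum(raw * spectrum.bin_widths))
    if total <= 0:
        raise ValueError("y * f(y) integrates to zero; d(y) undefined")
    return raw / total


def frequency_mean_lineal_energy(spectrum: LinealEnergySpectrum) -> float:
    """Frequency-mean lineal energy y_F = int y f(y) dy (keV/um)."""
    return float(np.sum(spectrum.y_mid * spectrum.f_density * spectrum.bin_widths))


def dose_mean_lineal_energy(spectrum: LinealEnergySpectrum) -> float:
    """Dose-mean lineal energy y_D = int y^2 f dy / int y f dy (keV/um).

    Midpoint quadrature on the spectrum's bins.  Always >= y_F, with
    equality only for a point mass.
    """
    w = spectrum.bin_widths
    first = float(np.sum(spectrum.y_mid * spectrum.f_density * w))
    if first <= 0:
        raise ValueError("first moment of f(y) is zero; y_D undefined")
    second = float(np.sum(spectrum.y_mid**2 * spectrum.f_density * w))
    return second / first


def average_yd_over_depths(
    profile: DepthProfile, window_min: float, window_max: float
) -> tuple[float, float]:
    """Mean and sample SD of y_D over depths in [window_min, window_max].

    This is the depth-averaging step used to collapse a y_D-vs-depth curve
    to a single beam-quality number (e.g. averaging over 10-13 cm).
    Returns ``(mean, sd)``; sd is 0 for a single in-window depth.
    """
    mask = (profile.depths >= window_min) & (profile.depths <= window_max)
    if not np.any(mask):
        raise ValueError(
            f"no depths in window [{window_min}, {window_max}] cm"
        )
    vals = profile.yd_values[mask]
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return mean, sd


# ---------------------------------------------------------------------------
# CSV dialects
#
# Spectrum files are headered CSV with a leading comment line declaring
# whether the y column holds bin edges or midpoints:
#
#   # y_kind=edges
#   y_kev_um,f_per_kev_um
#   0.10,0.0
#   ...
#
# With edges there are n+1 rows and the last row's density is empty.
# Midpoint files assume uniform bin width (inferred from spacing).


def write_spectrum_csv(spectrum: LinealEnergySpectrum, path: str | Path) -> None:
    """Write a spectrum as an edges-dialect CSV (round-trips bit-identically)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# y_kind=edges\n")
        fh.write("y_kev_um,f_per_kev_um\n")
        for edge, f in zip(spectrum.y_edges[:-1], spectrum.f_density):
            fh.write(f"{float(edge)!r},{float(f)!r}\n")
        fh.write(f"{float(spectrum.y_edges[-1])!r},\n")


def read_spectrum_csv(path: str | Path, label: str = "") -> LinealEnergySpectrum:
    """Read a spectrum CSV in either the edges or midpoints dialect."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "y_kind=" not in first:
            raise ValueError(
                f"{path}: first line must declare '# y_kind=edges' or "
                "'# y_kind=midpoints'"
            )
        y_kind = first.split("y_kind=", 1)[1].strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    if list(df.columns) != ["y_kev_um", "f_per_kev_um"]:
        raise ValueError(f"{path}: expected columns y_kev_um,f_per_kev_um, got {list(df.columns)}")
    y = df["y_kev_um"].to_numpy(dtype=float)
    f = df["f_per_kev_um"].to_numpy(dtype=float)
    if y_kind == "edges":
        if not np.isnan(f[-1]):
            raise ValueError(f"{path}: edges dialect requires an empty density on the last row")
        return LinealEnergySpectrum(y_edges=y, f_density=f[:-1], label=label or path.stem)
    if y_kind == "midpoints":
        if y.size < 2:
            raise ValueError(f"{path}: need at least 2 midpoints")
        widths = np.diff(y)
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError(
                f"{path}: midpoint dialect assumes uniform bin width; spacing varies"
            )
        w = widths[0]
        edges = np.concatenate([[y[0] - w / 2], y + w / 2])
        if edges[0] < 0:
            edges[0] = 0.0
        return LinealEnergySpectrum(y_edges=edges, f_density=f, label=label or path.stem)
    raise ValueError(f"{path}: unknown y_kind {y_kind!r}")


def write_depth_profile_csv(profile: DepthProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("depth_cm,yd_kev_um\n")
        for d, y in zip(profile.depths, profile.yd_values):
            fh.write(f"{float(d)!r},{float(y)!r}\n")


def read_depth_profile_csv(path: str | Path) -> DepthProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["depth_cm", "yd_kev_um"]:
        raise ValueError(f"{path}: expected columns depth_cm,yd_kev_um")
    return DepthProfile(
        depths=df["depth_cm"].to_numpy(dtype=float),
        yd_values=df["yd_kev_um"].to_numpy(dtype=float),
    )
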