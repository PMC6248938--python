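"""Closed-form modified microdosimetric kinetic model (MKM).

The modified MKM expresses clonogenic survival after a single continuous
irradiation of absorbed dose ``D`` delivered over time ``T`` as

    -ln S = (alpha0 + gamma * beta0) * D + F * beta0 * D**2

where ``F`` is the Lea-Catcheside dose-protraction factor

    F = 2 / ((a+c)**2 * T**2) * ((a+c)*T + exp(-(a+c)*T) - 1)

with ``a + c`` the first-order repair rate of potentially lethal lesions
(h^-1).  The microdosimetric coupling ``gamma = y_D / (rho * pi * r_d**2)``
feeds the dose-mean lineal energy of the beam into the linear coefficient.

RBE is defined at iso-survival against instantaneous delivery (T = 0): the
instantaneous dose producing the same -ln S, divided by the physical dose.
Protraction only relaxes the quadratic term, so RBE <= 1 always.

Canonical units: dose Gy, time hours, rates h^-1, y_D keV/um, r_d um,
rho g/cm^3.  Minute-valued inputs convert once at the boundary
(:meth:`DeliverySchedule.from_minutes`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "MKMParameters",
    "DeliverySchedule",
    "SurvivalPrediction",
    "RBEResult",
    "lea_catcheside_factor",
    "gamma_from_yd",
    "neg_log_survival",
    "equivalent_instantaneous_dose",
    "rbe",
    "repair_rate_from_halftime",
    "discrete_protraction_oracle",
    "load_parameter_blocks",
    "builtin_parameters",
]

# derived-vs-supplied gamma must agree this closely (absolute, dimensionless)
GAMMA_CONSISTENCY_TOL = 0.02

# below this (a+c)*T the closed form cancels catastrophically; use the series
_SERIES_SWITCH = 1e-4


def gamma_from_yd(
    dose_mean_lineal_energy: float,
    density: float = 1.0,
    domain_radius: float = 0.5,
) -> float:
    """Microdosimetric coupling gamma = y_D / (rho * pi * r_d**2).

    Numeric convention: y_D in keV/um, ``domain_radius`` in um and
    ``density`` in g/cm^3 entering as a pure number (1.00 for water-like
    domains), so that gamma is the dimensionless coefficient that multiplies
    beta0 in the linear survival term.
    """
    if dose_mean_lineal_energy <= 0:
        raise ValueError(f"dose_mean_lineal_energy must be > 0, got {dose_mean_lineal_energy}")
    if density <= 0:
        raise ValueError(f"density must be > 0, got {density}")
    if domain_radius <= 0:
        raise ValueError(f"domain_radius must be > 0, got {domain_radius}")
    return dose_mean_lineal_energy / (density * math.pi * domain_radius**2)


def repair_rate_from_halftime(half_time: float) -> float:
    """First-order repair rate lambda = ln(2) / T_half (h^-1 for T_half in h)."""
    if half_time <= 0:
        raise ValueError(f"half_time must be > 0, got {half_time}")
    return math.log(2.0) / half_time


@dataclass(frozen=True)
class MKMParameters:
    """Cell/beam radiobiological constants of the modified MKM.

    Parameters
    ----------
    alpha0 : float
        First-order lethal-lesion coefficient (Gy^-1), from an LQ fit to
        instantaneous-irradiation survival data.
    beta0 : float
        Second-order coefficient (Gy^-2), same fit.
    repair_rate : float
        Sublethal-damage repair rate a + c (h^-1); ln 2 over the repair
        half-time.
    gamma : float, optional
        Dimensionless microdosimetric coupling.  Supply directly, or leave
        ``None`` to derive from ``yd``/``density``/``domain_radius``.  If
        both are given they must agree within 0.02.
    yd : float, optional
        Dose-mean lineal energy (keV/um) of the beam.
    density : float
        Domain density rho (g/cm^3).
    domain_radius : float
        Domain radius r_d (um).
    t_r : float, optional
        Irreparable-fixation horizon (h).  The protraction factor is only
        defined for T < t_r; durations at or past it raise.  Default
        unbounded.
    label : str
        Free-text beam/cell identifier.
    """

    alpha0: float
    beta0: float
    repair_rate: float
    gamma: Optional[float] = None
    yd: Optional[float] = None
    density: float = 1.0
    domain_radius: float = 0.5
    t_r: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        if self.beta0 < 0:
            raise ValueError(f"beta0 must be >= 0, got {self.beta0}")
        if self.repair_rate <= 0:
            raise ValueError(f"repair_rate must be > 0, got {self.repair_rate}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.domain_radius <= 0:
            raise ValueError(f"domain_radius must be > 0, got {self.domain_radius}")
        if self.t_r is not None and self.t_r <= 0:
            raise ValueError(f"t_r must be > 0 when given, got {self.t_r}")
        if self.gamma is None and self.yd is None:
            raise ValueError("supply gamma directly or yd (with density, domain_radius)")
        if self.yd is not None:
            derived = gamma_from_yd(self.yd, self.density, self.domain_radius)
            if self.gamma is None:
                object.__setattr__(self, "gamma", derived)
            elif abs(self.gamma - derived) > GAMMA_CONSISTENCY_TOL:
                raise ValueError(
                    f"gamma={self.gamma} inconsistent with y_D-derived value "
                    f"{derived:.4f} (|diff| > {GAMMA_CONSISTENCY_TOL})"
                )
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    @property
    def alpha_eff(self) -> float:
        """Effective linear coefficient alpha = alpha0 + gamma * beta0 (Gy^-1)."""
        return self.alpha0 + self.gamma * self.beta0


@dataclass(frozen=True)
class DeliverySchedule:
    """One continuous irradiation: dose D (Gy) over duration T (hours).

    ``duration == 0`` means a single instantaneous irradiation.
    """

    dose: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")

    @classmethod
    def from_minutes(cls, dose: float, duration_min: float) -> "DeliverySchedule":
        return cls(dose=dose, duration=duration_min / 60.0)

    @property
    def dose_rate(self) -> float:
        """Mean dose rate D/T (Gy/h); undefined for instantaneous delivery."""
        if self.duration <= 0:
            raise ValueError("dose_rate undefined for instantaneous delivery (duration 0)")
        return self.dose / self.duration


@dataclass(frozen=True)
class SurvivalPrediction:
    """Survival prediction with its intermediate MKM quantities."""

    neg_log_sf: float
    sf: float
    f_factor: float
    alpha_eff: float
    beta_eff: float


@dataclass(frozen=True)
class RBEResult:
    """Iso-survival RBE and the quantities it was computed from."""

    rbe: float
    iso_effective_dose: float
    schedule: DeliverySchedule
    prediction: SurvivalPrediction


def lea_catcheside_factor(
    repair_rate: float, duration: float, t_r: Optional[float] = None
) -> float:
    """Lea-Catcheside dose-protraction factor F for continuous irradiation.

    F = 2/((a+c)^2 T^2) * ((a+c) T + exp(-(a+c) T) - 1), with F -> 1 as
    T -> 0.  For (a+c)*T < 1e-4 the series 1 - x/3 + x^2/12 is used to
    avoid cancellation; closed form and series agree to ~1e-12 at the
    switch point.

    Parameters are the repair rate a+c (h^-1) and the delivery time T (h);
    ``t_r`` optionally caps the model's validity horizon.
    """
    if repair_rate <= 0:
        raise ValueError(f"repair_rate must be > 0, got {repair_rate}")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    if t_r is not None and duration >= t_r:
        raise ValueError(
            f"duration {duration} h >= t_r {t_r} h: protraction factor is only "
            "defined for T < t_r"
        )
    x = repair_rate * duration
    if x < _SERIES_SWITCH:
        return 1.0 - x / 3.0 + x * x / 12.0
    # expm1 keeps the bracket accurate where x + e^-x - 1 ~ x^2/2 cancels
    return 2.0 / (x * x) * (x + math.expm1(-x))


def discrete_protraction_oracle(
    repair_rate: float, duration: float, n_steps: int
) -> float:
    """Finite-step protraction factor from the discrete double sum.

    Splits the delivery into ``n_steps`` equal dose increments and sums the
    pairwise interaction terms exp(-(m-n)(a+c) dT) directly:

        F_N = [ N + 2 * sum_{k=1}^{N-1} (N-k) exp(-k (a+c) dT) ] / N^2

    This is the pre-limit form of the protracted quadratic term and
    converges to :func:`lea_catcheside_factor` as N -> infinity.  It exists
    as an independent brute-force cross-check, not a production path.
    """
    if repair_rate <= 0:
        raise ValueError(f"repair_rate must be > 0, got {repair_rate}")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    if duration == 0:
        return 1.0
    n = int(n_steps)
    dt = duration / n
    k = np.arange(1, n)
    cross = np.sum((n - k) * np.exp(-k * repair_rate * dt))
    return float((n + 2.0 * cross) / n**2)


def neg_log_survival(
    params: MKMParameters, schedule: DeliverySchedule
) -> SurvivalPrediction:
    """Modified-MKM survival for one continuous delivery.

    -ln S = (alpha0 + gamma beta0) D + F beta0 D^2 with F evaluated at the
    schedule's duration (and the parameter set's t_r cap, if any).
    """
    f = lea_catcheside_factor(params.repair_rate, schedule.duration, params.t_r)
    alpha = params.alpha_eff
    beta = f * params.beta0
    d = schedule.dose
    nls = alpha * d + beta * d * d
    return SurvivalPrediction(
        neg_log_sf=nls,
        sf=math.exp(-nls),
        f_factor=f,
        alpha_eff=alpha,
        beta_eff=beta,
    )


def equivalent_instantaneous_dose(params: MKMParameters, neg_log_sf: float) -> float:
    """Instantaneous dose (T=0, F=1) producing the given -ln S.

    Solves beta0 D^2 + alpha_eff D - neg_log_sf = 0 for its unique
    nonnegative root, using the cancellation-free form
    D = 2 L / (alpha + sqrt(alpha^2 + 4 beta0 L)).  Falls back to the
    linear solution when beta0 = 0.
    """
    if neg_log_sf < 0:
        raise ValueError(f"neg_log_sf must be >= 0, got {neg_log_sf}")
    if neg_log_sf == 0:
        return 0.0
    alpha = params.alpha_eff
    if params.beta0 == 0:
        if alpha == 0:
            raise ValueError("alpha_eff and beta0 both zero: dose undefined")
        return neg_log_sf / alpha
    return 2.0 * neg_log_sf / (alpha + math.sqrt(alpha * alpha + 4.0 * params.beta0 * neg_log_sf))


def rbe(params: MKMParameters, schedule: DeliverySchedule) -> RBEResult:
    """Iso-survival RBE of a protracted delivery against instantaneous reference.

    RBE = D_{T=0} / D_T where D_{T=0} yields the same -ln S with F = 1.
    Equals 1 at T = 0 and decreases with protraction; undefined at D = 0.
    """
    if schedule.dose <= 0:
        raise ValueError("RBE undefined at dose 0 (0/0 ratio)")
    pred = neg_log_survival(params, schedule)
    d_iso = equivalent_instantaneous_dose(params, pred.neg_log_sf)
    return RBEResult(
        rbe=d_iso / schedule.dose,
        iso_effective_dose=d_iso,
        schedule=schedule,
        prediction=pred,
    )


# ---------------------------------------------------------------------------
# parameter files

def _params_from_block(label: str, block: dict) -> MKMParameters:
    """Build MKMParameters from one config block (see load_parameter_blocks)."""
    known = {
        "alpha0", "beta0", "repair_rate_per_h", "repair_halftime_h", "gamma",
        "yd_kev_um", "density_g_cm3", "domain_radius_um", "t_r_h",
    }
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"parameter block '{label}': unknown keys {sorted(unknown)}")
    for key in ("alpha0", "beta0"):
        if key not in block:
            raise ValueError(f"parameter block '{label}': missing required key '{key}'")
    if "repair_rate_per_h" in block:
        rate = float(block["repair_rate_per_h"])
    elif "repair_halftime_h" in block:
        rate = repair_rate_from_halftime(float(block["repair_halftime_h"]))
    else:
        raise ValueError(
            f"parameter block '{label}': need 'repair_rate_per_h' or 'repair_halftime_h'"
        )
    if "gamma" not in block and "yd_kev_um" not in block:
        raise ValueError(f"parameter block '{label}': need 'gamma' or 'yd_kev_um'")
    try:
        return MKMParameters(
            alpha0=float(block["alpha0"]),
            beta0=float(block["beta0"]),
            repair_rate=rate,
            gamma=float(block["gamma"]) if "gamma" in block else None,
            yd=float(block["yd_kev_um"]) if "yd_kev_um" in block else None,
            density=float(block.get("density_g_cm3", 1.0)),
            domain_radius=float(block.get("domain_radius_um", 0.5)),
            t_r=float(block["t_r_h"]) if "t_r_h" in block else None,
            label=label,
        )
    except ValueError as exc:
        raise ValueError(f"parameter block '{label}': {exc}") from exc


def load_parameter_blocks(path: str | Path) -> dict[str, MKMParameters]:
    """Read a TOML parameter file with one ``[beam.<label>]`` block per beam.

    Keys per block: ``alpha0``, ``beta0``, ``repair_rate_per_h`` (or
    ``repair_halftime_h``), ``gamma`` (or ``yd_kev_um`` plus optional
    ``density_g_cm3``, ``domain_radius_um``), optional ``t_r_h``.
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    blocks = doc.get("beam")
    if not isinstance(blocks, dict) or not blocks:
        raise ValueError(f"{path}: no [beam.<label>] blocks found")
    return {label: _params_from_block(label, blk) for label, blk in blocks.items()}


def builtin_parameters() -> dict[str, MKMParameters]:
    """NCI-H460 FF/FFF parameter sets shipped with the package."""
    here = Path(__file__).parent / "data" / "nci_h460.toml"
    return load_parameter_blocks(here)
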