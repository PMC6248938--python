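# Methods

## Model

`mkmrbe` implements the modified microdosimetric kinetic model (MKM) for a
single continuous photon irradiation. The cell nucleus is treated as a
collection of independent micron-scale domains; potentially lethal lesions
created in a domain are either fixed to lethal lesions (first order, rate
*a*), pairwise-converted (second order), or repaired (first order, rate
*c*). Integrating the lesion kinetics over a constant-dose-rate delivery
of dose *D* (Gy) over time *T* (h) gives the survival relation

```
-ln S = (α₀ + γ β₀) D + F(a+c, T) β₀ D²
F(x=(a+c)T) = (2/x²) (x + e⁻ˣ − 1)
```

`F` is the Lea–Catcheside dose-protraction factor: it equals 1 for an
instantaneous exposure and decays toward 0 as sublethal damage is repaired
during delivery, diluting only the quadratic (two-track) term. The
microdosimetric coupling

```
γ = y_D / (ρ π r_d²)
```

injects the beam quality: `y_D` is the dose-mean lineal energy (keV/μm) of
the beam's single-event spectrum, `ρ` the domain density (g/cm³), `r_d`
the domain radius (μm). The convention used throughout (y_D in keV/μm,
r_d in μm, ρ entering as the pure number 1.00) is the one under which the
shipped NCI-H460 parameter table is internally consistent; γ is then
treated as dimensionless. A supplied γ and a supplied y_D must agree
within 0.02 or construction fails — the couplings in the literature are
printed to two decimals, so 0.02 is the resolution at which agreement is
checkable.

RBE is defined at iso-survival with instantaneous delivery as the
reference: the dose `D_{T=0}` solving `α_eff D + β₀ D² = −ln S_T`
(positive quadratic root, evaluated in the cancellation-free form
`2L/(α+√(α²+4β₀L))`), divided by the physical dose. Protraction can only
reduce effectiveness, so RBE ≤ 1, with equality at `T = 0`. RBE at zero
dose is a 0/0 ratio and is rejected rather than defined as 1.

## Parameters

| symbol | meaning | unit | NCI-H460 default |
|---|---|---|---|
| α₀ | first-order lethal-lesion coefficient | Gy⁻¹ | 0.24 (FF) / 0.21 (FFF) |
| β₀ | second-order coefficient | Gy⁻² | 0.06 (FF) / 0.07 (FFF) |
| a+c | sublethal-damage repair rate | h⁻¹ | 0.46 (= ln2 / ~90 min half-time) |
| γ | microdosimetric coupling | — | 2.96 (FF) / 2.98 (FFF) |
| y_D | dose-mean lineal energy | keV/μm | 2.32 (FF) / 2.34 (FFF) |
| ρ | domain density | g/cm³ | 1.00 |
| r_d | domain radius | μm | 0.50 |
| t_r | irreparable-fixation horizon | h | unbounded |

Internal canonical time unit is hours — the repair rate is tabulated in
h⁻¹ while delivery times are quoted in minutes, and a single canonical
unit removes the classic 60× hazard. Minute-valued inputs convert once at
the boundary (`DeliverySchedule.from_minutes`, the `duration_min` CSV
column, CLI grids).

`t_r` caps the validity of the protraction factor (the lesion kinetics
behind `F` assume `T < t_r`). The parameter is rarely quantified for a
given cell line, so the default is unbounded; when supplied, a delivery
time at or beyond it is a hard error rather than a silent extrapolation.

## Numerics

- For `(a+c)T < 10⁻⁴` the factor `F` switches to the series
  `1 − x/3 + x²/12`; the closed form is evaluated with `expm1` so the two
  branches agree to ~10⁻¹² at the switch point.
- The instantaneous-dose inversion uses the numerically stable quadratic
  root and falls back to the linear solution when β₀ = 0.
- `discrete_protraction_oracle` evaluates the pre-limit double sum of the
  protracted quadratic term over N equal dose increments. It converges to
  the closed form as N → ∞ (relative 10⁻³ at N = 10⁵ over
  `(a+c)T ∈ [0.01, 5]`) and exists purely as an independent cross-check
  on the closed form.
- Spectrum moments use midpoint Riemann sums on the supplied bins
  (midpoints in linear y even for log-spaced bins); the estimator's
  convergence order is asserted in the tests. Spectra whose density
  integrates within 1% of unity are renormalized with a logged warning;
  larger drift is rejected as a corrupt file.

## LQ fitting

α and β of the instantaneous survival curve are estimated from
clonogenic data by nonnegativity-constrained weighted least squares of
`−ln SF` on `(D, D²)` without intercept (NNLS on the weighted design).
Note the parametrization: the linear coefficient of the observable curve
is `α = α₀ + γβ₀`; recovering α₀ itself requires γ from microdosimetry.

Weights are inverse *moderated* replicate variances: per-dose sample
variances are shrunk toward the pooled variance with df-proportional
weight (prior df 20). With a handful of replicates per dose the raw
variance reciprocals are noisy enough to make the standard errors
anticonservative (2-SE coverage measured ~87% instead of ~95% in the
simulation study); moderation restores calibration while still
down-weighting genuinely noisy dose levels. Standard errors come from the
weighted normal equations (σ² = weighted RSS / (n − 2)); a coefficient
pinned at the zero bound is reported with the SE it would have if freed,
which is conservative. The ± values on the estimates are standard errors.

## Synthetic data

The generators replace the two upstream data sources of a real study of
this design — Monte Carlo radiation transport and a wet-lab clonogenic
assay — with seeded, ground-truth-known equivalents:

- **Spectra**: lognormal-shaped f(y) on log-spaced bins, log-scale solved
  by Brent root-finding so the *binned* y_D hits the requested target
  within 0.5%, with optional seeded bin-wise jitter applied before the
  solve. The lognormal family is a convenience: y_D is the only
  functional of f(y) the MKM consumes, so matching it suffices; the
  generator makes no claim to reproduce the spectral shape of a real
  6 MV beam (no electron build-up structure, no proton/alpha tail).
- **Depth profiles**: linear y_D-vs-depth trend plus seeded Gaussian
  jitter — enough structure to exercise the window-averaging step, not a
  transport calculation.
- **Assays**: colony counts Poisson-distributed around the modified-MKM
  forward model. Following standard clonogenic protocol the plated-cell
  count per condition is scaled as `plated / SF_true` (capped at 10⁷) so
  every dish has a countable expected yield (≈ plated·PE); without this,
  high-dose wells would be almost all empty and carry no information.
  Optional lognormal plating-efficiency jitter provides an
  overdispersion robustness knob (off by default). Zero-colony wells are
  dropped, as they cannot enter a log-scale fit.

Default grids are the study conditions: doses {2, 4, 8} Gy, delivery
times {0, 1, 5, 10, 30, 60} min, repair rate 0.46 h⁻¹, 6 replicates,
200 plated (baseline), plating efficiency 0.7. Same seed ⇒ bit-identical
outputs.

What passing tests on these generators do *not* show: correctness of any
transport physics, realism of the spectral shape away from its y_D, cell
cycle or oxygen effects, or inter-experiment variability beyond Poisson
counting noise.

## Pipeline problem sizes

The batch pipeline evaluates the 2 beams × 3 doses × 6 durations grid
(36 closed-form cells), a 25-point log-spaced repair-rate sweep over
0.1–5 h⁻¹ at T = 60 min (bracketing the NCI-H460 value and wide enough to
show the >10% RBE spread across cell types), and one 120-bin synthetic
spectrum per beam. The simulation study behind the fitting-coverage test
uses 200 seeded assays. Everything is deterministic under a fixed seed;
reports embed the package version, seed and a config hash, and reruns are
byte-identical.

## Known limitations

- Single continuous irradiations only: no fractionation, pulsed or
  IMRT/VMAT-style interrupted delivery.
- The γ coupling convention is numeric, matched to the shipped parameter
  table; users supplying y_D in other units must convert first.
- `t_r` is unbounded by default, so very long delivery times extrapolate
  the lesion kinetics outside their derivation regime unless a cap is
  given.
- The iso-survival RBE compares like-for-like photon deliveries; it is
  not an inter-modality RBE.
- Uncertainties on the tabulated α₀/β₀ (± values) are stored but not
  propagated through the RBE chain.
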