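# mkmrbe

Cell survival and relative biological effectiveness (RBE) of protracted
photon irradiation, computed with the modified microdosimetric kinetic
model (MKM).

When a radiotherapy fraction takes minutes instead of seconds — gated or
tumor-tracking delivery, large stereotactic doses — sublethal damage is
repaired *during* the exposure and the same physical dose kills fewer
cells. `mkmrbe` quantifies that effect for flattened (FF) and
flattening-filter-free (FFF) 6 MV photon beams: it couples the beam's
microdosimetric quality (dose-mean lineal energy y_D) to linear-quadratic
survival through the MKM, applies the Lea–Catcheside dose-protraction
factor, and reports iso-survival RBE against instantaneous delivery. It
is aimed at medical physicists and radiobiologists who want a tested,
scriptable implementation rather than a spreadsheet.

## Model

For a single continuous delivery of dose *D* (Gy) over time *T*:

```
-ln S = (α₀ + γ β₀) D + F β₀ D²
F      = 2/((a+c)²T²) · ((a+c)T + e^(−(a+c)T) − 1)      (F→1 as T→0)
γ      = y_D / (ρ π r_d²)
RBE    = D_{T=0} / D_T   at equal −ln S  (positive quadratic root)
```

where α₀ (Gy⁻¹), β₀ (Gy⁻²) come from an LQ fit to instantaneous-
irradiation clonogenic data, *a+c* (h⁻¹) is the sublethal-damage repair
rate (ln 2 / repair half-time), and r_d ≈ 0.5 μm is the MKM domain
radius. Parameter sets for NCI-H460 lung-cancer cells under FF and FFF
beams ship with the package.

Five modules: `mkmrbe.core` (closed-form survival/RBE), `.microdosimetry`
(f(y), d(y), y_D, depth averaging), `.lq` (constrained LQ fitting),
`.synthetic` (seeded generators for spectra, depth profiles and
clonogenic assays with known ground truth), `.pipeline` + `.cli` (batch
tables and the `mkmrbe` command).

## Worked example

```python
from mkmrbe import builtin_parameters, DeliverySchedule, rbe

ff = builtin_parameters()["FF"]
result = rbe(ff, DeliverySchedule.from_minutes(dose=8.0, duration_min=60.0))
print(f"F    = {result.prediction.f_factor:.4f}")
print(f"-lnS = {result.prediction.neg_log_sf:.4f}")
print(f"RBE  = {result.rbe:.3f}")
```

prints

```
F    = 0.8628
-lnS = 6.6539
RBE  = 0.951
```

Stretching an 8 Gy fraction over an hour leaves only 86% of the
quadratic damage (F = 0.8628), and the delivery is biologically
equivalent to 7.61 Gy given instantaneously — an RBE of 0.951, a ~5%
loss of effect. The same table for the whole study grid, from the shell:

```sh
$ mkmrbe rbe-table | head -4
beam,dose_gy,duration_min,f_factor,neg_log_sf,sf,rbe
FF,2,0,1,1.0752,0.341229502575,1
FF,2,1,0.997449335092,1.07458784042,0.341438453433,0.999534510659
FF,2,5,0.987343743079,1.07216249834,0.342267563514,0.997689489895
```

Other subcommands: `repair-sweep` (RBE vs a+c at fixed T — the repair
rate is the dominant cell-specific sensitivity), `spectrum-yd` (y_D and γ
from a spectrum CSV), `fit-lq`, `simulate` (synthetic spectra/assays),
and `pipeline` (full chain with CSV/JSON reports, byte-deterministic
under a fixed seed).

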