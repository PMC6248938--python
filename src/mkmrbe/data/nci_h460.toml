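# Modified-MKM parameters for NCI-H460 non-small-cell lung cancer cells,
# 6 MV FF and FFF photon beams.  alpha0/beta0 from an instantaneous-
# irradiation LQ fit; a+c from the literature DNA repair half-time via
# lambda = ln2/T_half; gamma from the dose-mean lineal energy averaged over
# 10-13 cm depth in water (yd_kev_um) with rho = 1 g/cm^3, r_d = 0.5 um.

[beam.FF]
alpha0 = 0.24
beta0 = 0.06
repair_rate_per_h = 0.46
gamma = 2.96
yd_kev_um = 2.32
density_g_cm3 = 1.0
domain_radius_um = 0.5

[beam.FFF]
alpha0 = 0.21
beta0 = 0.07
repair_rate_per_h = 0.46
gamma = 2.98
yd_kev_um = 2.34
density_g_cm3 = 1.0
domain_radius_um = 0.5
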