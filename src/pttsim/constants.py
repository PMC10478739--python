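"""Physical constants and scenario parameters for the skin-SCC photothermal model.

All tissue values in this file come from a single published property table for
squamous cell carcinoma embedded in four-layer skin, irradiated by a 1064 nm CW
laser.  The rendered source table concatenates digits, so the parse is pinned
here, in one place, with units:

==================  =====  ======  =====  =====  ======  =====  =====  ====
layer               t(mm)  k       c_v    rho    w_b     mu_a   mu_s   g
                           W/mK    J/kgK  kg/m3  1/s     1/mm   1/mm
==================  =====  ======  =====  =====  ======  =====  =====  ====
tumor (SCC)         2      0.49    3421   1070   0.0063  0.047  0.883  0.8
epidermis           0.08   0.235   3589   1200   --      0.4    45     0.8
papillary dermis    0.5    0.445   3300   1200   0.0031  0.38   30     0.9
reticular dermis    0.6    0.445   3300   1200   0.0031  0.48   25     0.8
subcutaneous fat    18.82  0.19    2500   1000   0.0031  0.4    35     0.75
==================  =====  ======  =====  =====  ======  =====  =====  ====

The epidermis is avascular (no perfusion entry); its perfusion rate is 0 here.

The AuNP-loaded tumor optics per volume fraction (the four-decade table) are
stored verbatim: the mu_abs column is exactly linear in f_v through the mixing
rule (inverted Q_abs = 50.163 at 1064 nm for the r_eff = 20 nm rod); the
reduced-scattering column as printed is *not* linear and is therefore kept as
tabulated data rather than recomputed.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Geometry (mm)
# ---------------------------------------------------------------------------
DOMAIN_RADIUS_MM = 10.0      # cylindrical normal-tissue domain radius
DOMAIN_DEPTH_MM = 20.0       # cylinder depth
TUMOR_RADIUS_MM = 1.5        # SCC modeled as a right cylinder, 3 mm diameter
TUMOR_DEPTH_MM = 2.0         # flush with the surface, 2 mm deep
AUNP_SPHERE_RADIUS_MM = 1.0  # injected AuNP region: sphere at tumor center
AUNP_SPHERE_CENTER_MM = (0.0, 0.0, 1.0)  # (x, y, z); z is depth from surface

# Cumulative skin-layer boundaries in depth (mm): epidermis / papillary /
# reticular dermis / subcutaneous fat.
LAYER_BOUNDARIES_MM = (0.08, 0.58, 1.18, 20.0)

# ---------------------------------------------------------------------------
# Laser (CW, Gaussian)
# ---------------------------------------------------------------------------
WAVELENGTH_NM = 1064.0
BEAM_RADIUS_MM = 1.5         # 1/e^2 intensity radius
IRRADIATION_TIME_S = 600.0

# ---------------------------------------------------------------------------
# Nanoparticle
# ---------------------------------------------------------------------------
NP_EFFECTIVE_RADIUS_NM = 20.0
NP_ASPECT_RATIO = 6.67       # rod length / diameter
# Q_abs at 1064 nm inverted from the f_v = 1e-3 row of the composite-optics
# table through mu_abs = 0.75 f_v Q_abs / r_eff + mu_abs,m (r_eff in mm).
QABS_TABLE_INVERTED = 50.163

# ---------------------------------------------------------------------------
# Tissue layers: (thickness mm, k W/mK, c_v J/kgK, rho kg/m3, w_b 1/s,
#                 mu_abs 1/mm, mu_sca 1/mm, g)
# ---------------------------------------------------------------------------
TISSUE_TABLE = {
    "tumor":            (2.0,   0.49,  3421.0, 1070.0, 0.0063, 0.047, 0.883, 0.8),
    "epidermis":        (0.08,  0.235, 3589.0, 1200.0, 0.0,    0.4,   45.0,  0.8),
    "papillary_dermis": (0.5,   0.445, 3300.0, 1200.0, 0.0031, 0.38,  30.0,  0.9),
    "reticular_dermis": (0.6,   0.445, 3300.0, 1200.0, 0.0031, 0.48,  25.0,  0.8),
    "subcutaneous_fat": (18.82, 0.19,  2500.0, 1000.0, 0.0031, 0.4,   35.0,  0.75),
}

# AuNP-loaded tumor composite optics at 1064 nm per nanoparticle volume
# fraction: f_v -> (mu_abs 1/mm, reduced mu'_sca 1/mm).  Tabulated verbatim.
AUNP_TUMOR_OPTICS = {
    1e-3: (1881.163, 79.619),
    1e-4: (188.158, 40.604),
    1e-5: (18.858, 4.855),
    1e-6: (1.928, 1.280),
}

# ---------------------------------------------------------------------------
# Blood / thermal boundary defaults.  The perfusion source is
# q_perf = rho_b * w_b * c_b * (T_b - T); the blood constants are standard
# literature values (they are configurable in ThermalScenario).
# ---------------------------------------------------------------------------
BLOOD_DENSITY = 1050.0       # kg/m^3
BLOOD_SPECIFIC_HEAT = 3617.0  # J/kgK
ARTERIAL_TEMPERATURE_C = 37.0
INITIAL_TEMPERATURE_C = 37.0

# ---------------------------------------------------------------------------
# Apoptosis / hazard temperature bands (deg C).  Apoptosis occurs in
# [43, 50); necrosis at >= 50.
# ---------------------------------------------------------------------------
APOPTOSIS_LOW_C = 43.0
APOPTOSIS_HIGH_C = 50.0

# ---------------------------------------------------------------------------
# Parametric-study grid: 6 angles x 4 volume fractions x 76 powers = 1824.
# ---------------------------------------------------------------------------
SWEEP_ANGLES_DEG = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0)
SWEEP_VOLUME_FRACTIONS = (1e-3, 1e-4, 1e-5, 1e-6)
SWEEP_POWER_MIN_W = 0.0
SWEEP_POWER_MAX_W = 0.150
SWEEP_POWER_STEP_W = 0.002
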