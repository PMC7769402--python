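# NCI-H460 (human non-small-cell lung cancer) under 6-MV photons.
# beta0 multiplies D^2 and is therefore Gy^-2.  y_D is a packaged constant
# (Monte Carlo track-structure transport is outside this package's scope);
# the depth-averaged alternate value is 2.32 keV/um.  Dose rate 3 Gy/min
# (equivalently 300 MU/min at 1 MU = 0.01 Gy calibration); it is metadata
# only, as fields are modelled as instantaneous pulses.
label: NCI-H460_6MV
alpha0: 0.21          # Gy^-1
beta0: 0.07           # Gy^-2
repair_rate: 0.46     # (a + c), h^-1
y_d: 2.34             # keV/um, dose-mean lineal energy
rho: 1.0              # g/cm^3
r_d: 0.5              # um
dose_rate: 3.0        # Gy/min
metadata:
  alpha0_sd: 0.16
  beta0_sd: 0.03
  y_d_sd: 0.01
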