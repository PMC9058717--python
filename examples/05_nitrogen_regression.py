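"""Red-band reflectance versus leaf nitrogen content.

Generates the synthetic 120-sample data set (four crop types, 660 nm ROI
MGV of dried ground leaf samples) and fits nitrogen content against MGV by
ordinary least squares.
"""

import ledmsi as L

nitrogen, mgv, labels = L.simulate_nitrogen_mgv(n_samples=120, seed=1)
fit = L.fit_reflectance_analyte(mgv, nitrogen)

print(f"n = {fit.n} samples across {len(set(labels))} crops")
print(f"slope     = {fit.slope:.5f} %N per gray unit")
print(f"intercept = {fit.intercept:.3f} %N")
print(f"pearson r = {fit.pearson_r:.3f}")

# The negative slope and correlation reproduce the expected optics: leaves
# richer in nitrogen (hence chlorophyll) absorb more red light, so their
# dried samples reflect less at 660 nm.
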