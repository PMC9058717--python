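"""Render single-band frames of the built-in fixtures.

Builds the certified-reflectance-standard (CRS) and pink-disk scenes,
renders an 8-bit frame of each under the 525 nm LED channel, and prints
their circular-ROI mean gray values (MGV).
"""

import ledmsi as L

geometry = L.Geometry()          # R=14 cm dome, r=6 cm ROP, d=8 cm, 3 LEDs
sensor = L.SensorModel()         # 8-bit webcam model with default noise
band = next(b for b in L.default_band_set() if b.name == "525")
roi = L.CircularROI((119.5, 119.5), 120.0)   # 30 mm radius at 0.25 mm/px

for name in ("crs", "pink_disk"):
    scene = L.make_fixture(name, size_px=(240, 240))
    img = L.render_band_image(scene, band, sensor, geometry, seed=1)
    print(f"{name:>9}: ROI MGV = {L.roi_mgv(img, roi):6.1f} "
          f"(range {img.pixels.min()}..{img.pixels.max()})")

# The CRS (reflectance 0.99) reads near full scale; the pink disk reads in
# the mid gray range because pink paper absorbs part of the green light.
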