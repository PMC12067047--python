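"""Full digital calibration: dilution series -> AMB curve -> 4PL -> LOD.

Simulates a dilution series with replicates, pushes every frame through
detection and digital quantification, fits the four-parameter logistic
calibration curve to AMB, and reports the limit of detection at blank
mean + 3 SD.
"""

import digibead as db
from digibead.pipeline import calibrate_quantification, quantify_conditions

optics = db.OpticsParams()
base = db.AssayParams(concentration=0.0, capture_coeff=0.1, n_beads=2500, seed=0)
concentrations = [0.0, 0.05, 0.15, 0.5, 1.5, 5.0, 15.0, 50.0]  # ng/mL

conditions, manifest = db.simulate_dilution_series(
    concentrations, base, optics, replicates=3, seed=21, n_frames=8, imaged_fraction=0.5
)
print(f"simulated {len(conditions)} framesets "
      f"({len(concentrations)} concentrations x 3 replicates)")

params = db.DetectionParams.from_optics(optics)
per_bead, quant, blank = quantify_conditions(conditions, params)
print(f"threshold from pooled blanks: {blank.threshold:.0f} a.u. "
      f"({blank.n_blank_beads} blank beads)")
print(quant.groupby("concentration")[["f_on", "amb"]].mean().round(4))

(report,) = calibrate_quantification(
    quant, readout_mode="digital", sample_volume=2.0, weighted=True
)
fit, lod = report.fit, report.lod
print(f"\n4PL: a={fit.a:.4f} b={fit.b:.3f} c={fit.c:.2f} d={fit.d:.2f} (rss {fit.rss:.3g})")
print("(c and d are extrapolated when the series does not reach its upper "
      "plateau; the LOD depends on the well-constrained low end)")
print(f"LOD = {lod.lod_concentration:.3f} ng/mL at y_lod = {lod.y_lod:.4f} AMB")
print(f"    = {lod.lod_mass:.3f} pg of analyte in a {lod.sample_volume:g} uL sample")
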