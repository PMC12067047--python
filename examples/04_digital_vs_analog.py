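"""Digital versus analog readout of the same micrographs.

The same simulated frames are quantified two ways: digitally (count "on"
beads, invert through Poisson statistics) and in analog (grand mean pixel
intensity of every fluorescence frame). Calibrating both shows why single-
molecule counting wins: the analog LOD is set by background-level
fluctuations, the digital one by bead-counting statistics.
"""

import digibead as db
from digibead.pipeline import calibrate_quantification, quantify_conditions

optics = db.OpticsParams()
base = db.AssayParams(concentration=0.0, capture_coeff=0.1, n_beads=5000, seed=0)
conditions, _ = db.simulate_dilution_series(
    [0.0, 0.05, 0.15, 0.5, 1.5, 5.0, 15.0, 50.0],
    base,
    optics,
    replicates=3,
    seed=42,
    n_frames=24,
    imaged_fraction=0.21,  # ~21% of beads land in the imaged fields
)
params = db.DetectionParams.from_optics(optics)
_, quant, _ = quantify_conditions(conditions, params)

digital, analog = calibrate_quantification(
    quant, readout_mode="both", sample_volume=2.0, weighted=True
)
d, a = digital.lod, analog.lod
print(f"digital LOD: {d.lod_concentration:.3f} ng/mL ({d.lod_mass:.3f} pg in 2 uL)")
print(f"analog  LOD: {a.lod_concentration:.3f} ng/mL ({a.lod_mass:.3f} pg in 2 uL)")
print(f"-> counting single molecules improves the LOD "
      f"{a.lod_concentration / d.lod_concentration:.1f}-fold on identical images")
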