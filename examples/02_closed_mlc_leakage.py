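"""Closed-MLC abutting leakage: simulate and measure the midline peak.

All 120 leaves abut at the midline inside a 10x10 cm^2 jaw field; the
rounded leaf ends let a narrow ridge of radiation through.  The script
runs the desk-scale Monte Carlo engine, extracts the transmitted-dose
x-profile at 1.5 cm water depth (detector plane at SDD 100 cm) and
prints the peak FWHM.  Expect roughly 0.6-0.65 cm: the ridge is a
sub-millimetre transmission spike broadened by the focal spot and by
secondary-electron transport in water.
"""

from mlcdose.benchmarks import closed_mlc_abutment_fwhm

result = closed_mlc_abutment_fwhm(n_histories=2_000_000, seed=1)
print(f"histories: {result.histories}")
print(f"abutment-peak FWHM: {result.fwhm_cm:.2f} cm")

peak = result.profile.max()
baseline = result.profile[abs(result.x_mm) > 40].mean()
print(f"peak/interleaf-pedestal dose ratio: {peak / baseline:.1f}")
print("The pedestal is interleaf leakage through the whole bank; the peak")
print("is the extra transmission through the abutted rounded tips.")
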