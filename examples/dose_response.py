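"""Viability dose-response reduction: EC50 and relative AUC.

Simulates a luminescence plate on the eight-point screening dilution
(10 -> 0.003 uM), normalizes to the DMSO control wells, fits the
four-parameter logistic model and reports EC50, Hill slope and the
relative area under the curve.
"""

from targetdecon import doseresp as dr
from targetdecon import synthetic as syn

plate = syn.gen_doseresp(ec50=0.08, hill=1.5, top=1.0, bottom=0.05,
                         noise_cv=0.03, seed=6)
samples = plate[plate.role == "sample"]
viability = dr.normalize_to_control(
    samples.signal.to_numpy(),
    plate.loc[plate.role == "dmso", "signal"].to_numpy(),
)
curve = dr.DoseResponse(samples.concentration.to_numpy(), viability)
fit = dr.fit_4pl(curve)

print(f"EC50 = {fit.ec50 * 1000:.1f} nM (true 80 nM), hill = {fit.hill:.2f}")
print(f"top = {fit.top:.3f}, bottom = {fit.bottom:.3f}, rss = {fit.rss:.2e}")
print(f"relative AUC = {fit.rel_auc:.3f}")
# Relative AUC integrates viability over log10 concentration against a
# no-effect reference: 1.0 means untouched viability, values near the
# curve's plateau indicate strong killing across the tested range.

# two-point fluorescence-polarization normalization
pct = dr.normalize_fp(125.0, fp_protein_probe_ctrl=200.0, fp_probe_ctrl=50.0)
print(f"FP sample at 125 mP between anchors 200/50 -> {pct:.0f}% inhibition")
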