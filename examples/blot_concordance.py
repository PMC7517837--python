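"""Immunoblot normalization and concordance with mass-spectrometry ratios.

Normalizes band volumes to the actin loading control, forms the NER D7/D0
ratio per dog, and calls directional agreement with the per-dog LC-MS/MS
fold changes.
"""

from canprot import blot, quantify, simulate

cfg = simulate.SimConfig(n_proteins=300, seed=42)
table, truth = simulate.simulate_cohort(cfg)
blots = blot.blot_table(simulate.make_fixture_blot(cfg, truth))
per_dog = quantify.per_dog_quant(table)

report = blot.concordance_report(blots, per_dog)
print(report.to_string(index=False))
n_called = (report["call"] != "ambiguous").sum()
n_conc = (report["call"] == "concordant").sum()
print(f"\n{n_conc}/{n_called} non-ambiguous calls concordant: both methods "
      "agree on the direction of change after supplementation; 'ambiguous' "
      "means one ratio sat inside the ±5% flat band around 1")
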