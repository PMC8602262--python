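"""Long-term adaptation metrics on a synthetic lag-trained cohort.

Simulates three groups through the long-term adaptation protocol (normal
controls, lag-trained fish whose controller recalibrates during training,
and lag-trained fish that do not change), segments first bouts per trial,
and prints the block-of-ten metrics: acute reaction, reduction of acute
reaction, and after-effect, plus a rank-test comparison between groups.
"""

from boutloop import bouts as bt
from boutloop import synth as sy

records = sy.gen_adapting_cohort(n_per_group=8, seed=0, n_adaptation=60)
m = sy.cohort_metrics(records)

print(m.groupby("group")[["acute_reaction", "reduction", "after_effect"]]
      .median().round(1))
print("\nadapting fraction per group:")
print(m.groupby("group")["adapting"].mean().round(2))

ad = m[m.group == "lag_adapting"]
ctrl = m[m.group == "control"]
p = bt.group_compare(ad["acute_reaction"], ctrl["acute_reaction"])
print(f"\nMann-Whitney U, acute reaction adapting vs control: p = {p:.2e}")
print("Positive acute reaction (bouts lengthen under the 225 ms lag),"
      "\nnegative reduction (training shortens them back) and negative"
      "\nafter-effect (bouts stay short under restored normal reafference)"
      "\nare the behavioral signature of an adapted internal model.")
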