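"""Score a duplicate-well viability screen and gate hits.

Simulates a 5292-compound, 384-well screen with 5% planted actives
(ΔPOC 95, 5% well noise), computes POC/ΔPOC against on-plate DMSO vehicle
wells, tests each compound with the two-level ANOVA, BH-adjusts, and
applies the 95th-percentile ΔPOC gate.
"""

import offsig
from offsig import simulate

plates, truth = simulate.gen_screen(seed=0)
stats = offsig.screen_stats(plates)
hits = offsig.select_hits(stats, alpha=0.05, percentile=95)
qc = offsig.spatial_bias_report(plates)

active = set(truth.loc[truth["planted"] == "active", "entity_id"])
got = set(hits["compound_id"])

print(f"compounds screened : {stats['compound_id'].nunique()}")
print(f"hits at the gate   : {len(hits)}  (ΔPOC ≥ "
      f"{hits['delta_poc_limit'].iloc[0]:.1f} and BH-adjusted p ≤ 0.05)")
print(f"top hit            : {hits['compound_id'].iloc[0]} "
      f"ΔPOC {hits['delta_poc'].iloc[0]:.2f}")
print(f"planted actives    : {len(active)}; recovered "
      f"{len(got & active)} ({100 * len(got & active) / len(active):.1f}%)")
print(f"plates flagged for spatial bias: {int(qc['flagged'].sum())} "
      f"of {len(qc)}")
# A hit list this clean reflects the planted separation: every active kills
# ~95% of cells while vehicle-level noise keeps inert ΔPOC near zero.
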