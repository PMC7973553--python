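"""Group-level statistical battery on simulated FS and RS cohorts.

Aggregates classified records into block rates, runs the mixed ANOVA
(group x block) on grammatical-fixation rates, computes learning /
interference / recovery contrasts within the FS group, and calibrates the
random-partition test on the RS cohort.
"""

import pandas as pd

import osrt
from osrt import stats as osstats

table = osrt.semantic_table()

gaze, events, _, fs_stream = osrt.simulate_cohort(10, "fs-learner", seed=1)
rec_fs = osrt.classify_isis(gaze, events, fs_stream, table)
rates_fs = osrt.block_rates(rec_fs)

gaze, events, _, rs_stream = osrt.simulate_cohort(10, "rs-grammar-only", seed=2)
rec_rs = osrt.classify_isis(gaze, events, rs_stream, table)
rates_rs = osrt.block_rates(rec_rs)

# mixed ANOVA on grammatical rate over the six learning blocks
both = pd.concat([rates_fs[rates_fs["block"] <= 6].assign(group="FS"),
                  rates_rs.assign(group="RS")])
both["participant"] = both["group"] + both["participant"]
res = osrt.rm_anova(both, dv="pct_grammatical", subject="participant",
                    within="block", between="group")
print("grammatical rate, groups x blocks 1-6:")
for _, r in res.iterrows():
    print(f"  {r['effect']:<12} F({r['df1']:.1f}, {r['df2']:.1f}) = {r['F']:.2f}, "
          f"p = {r['p']:.4f}, eta_p2 = {r['eta_p2']:.2f}")
print("the dominant block effect is grammar learning; the much smaller")
print("group terms show both cohorts acquire the grammar in a similar way\n")

# FS effect scores on Main anticipation rates
scores = [osrt.effect_scores(g, measure="pct_main")
          for _, g in rates_fs.groupby("participant")]
learning = [s.learning for s in scores]
interference = [s.interference for s in scores]
t = osrt.paired_ttest(interference, [0.0] * len(interference))
print(f"Main-anticipation interference effect (block 6 - block 7): "
      f"mean {sum(interference) / len(interference):.1f} points, "
      f"t({t.df}) = {t.statistic:.2f}, p = {t.p:.4f}")
r = osrt.pearson_corr(learning, interference)
print(f"learning vs interference correlation: r({r.df}) = {r.statistic:.2f}, "
      f"p = {r.p:.4f}")
print("a positive interference effect means Main anticipations collapse when")
print("the sequence is replaced; its negative correlation with the learning")
print("score marks both as expressions of the same sequence knowledge\n")

# partition calibration on the RS cohort
A = osstats.rate_matrix(rates_rs, "pct_main")
B = osstats.rate_matrix(rates_rs, "pct_interference")
part = osrt.partition_test(A, B, n_partitions=2000, seed=3)
print(f"random partitions with significant type effect: "
      f"{100 * part.prop_main_significant:.1f}% "
      f"(interaction: {100 * part.prop_interaction_significant:.1f}%)")
print("near the nominal 5% alpha: the two grammatical-label series of the")
print("RS group are exchangeable, as they should be without a governing sequence")
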