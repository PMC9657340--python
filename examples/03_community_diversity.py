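"""Alpha diversity and community composition of generated ASV tables.

Generates an overdispersed feature table (3 bioreplicates x AC/TC/DC x
pre/post periods) with a spiked probiotic ASV, removes that ASV (it would
trivially inflate post-dose diversity), and computes Shannon, richness and
Faith's PD per sample, an ANOVA across regions, and the
Firmicutes/Bacteroidetes ratio.
"""

import numpy as np

from gutwash import SynthConfig, gen_feature_table, gen_tree
from gutwash.community import (
    alpha_diversity_frame,
    alpha_group_test,
    fb_ratio,
    find_probiotic_asvs,
    remove_probiotic_asvs,
)

cfg = SynthConfig(seed=11)
table, taxonomy = gen_feature_table(cfg)
tree = gen_tree(table.asv_ids, seed=cfg.seed)

targets = find_probiotic_asvs(taxonomy)
stripped = remove_probiotic_asvs(table, targets)
print(f"removed probiotic ASVs before diversity: {sorted(targets)}")

alpha = alpha_diversity_frame(stripped, tree=tree)
print("\nmean alpha diversity by region (probiotic excluded):")
print(alpha.groupby("region")[["shannon", "richness", "faith_pd"]].mean().round(2))

res = alpha_group_test(alpha["shannon"].to_numpy(), alpha["region"].to_numpy())
print(f"\nShannon ~ region ANOVA: F = {res.f_statistic:.2f}, "
      f"df = ({res.df_between}, {res.df_within}), p = {res.p_value:.2e}")
print(res.pairwise.to_string(index=False))

ratio = fb_ratio(stripped, taxonomy)
by_region = ratio.groupby(stripped.metadata["region"]).median()
print("\nmedian Firmicutes/Bacteroidetes ratio by region:")
print(by_region.round(2).to_string())
print("\nthe AC is generated less even than TC/DC, so its diversity is lowest;"
      "\nthe ANOVA detects exactly that regional structure.")
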