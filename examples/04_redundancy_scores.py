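"""Score functional redundancy of strain subsets by Lempel-Ziv compression.

A pair of strains with identical enzyme repertoires compresses to little
more than one repertoire, so its redundancy approaches the maximum; strains
with complementary (disjoint) repertoires barely compress and score near 0.
The selector penalizes redundancy so chosen communities spread function
across members instead of duplicating it.
"""

import syncomdesign as scd

cfg = scd.GeneratorConfig(n_strains=12, n_enzymes=64, n_metabolites=9, seed=4)
profiles, _ = scd.generate_profiles(cfg)

# a duplicated strain: maximal overlap
dup = profiles.copy()
dup.loc["S002"] = dup.loc["S001"]
score_dup = scd.community_redundancy(dup, ["S001", "S002"])
print(f"duplicated pair:  redundancy = {score_dup.redundancy:.3f} "
      f"(LZ concat {score_dup.lz_concat} vs {sum(score_dup.lz_individual)} separate)")

score_pair = scd.community_redundancy(profiles, ["S001", "S007"])
print(f"random pair:      redundancy = {score_pair.redundancy:.3f}")

score_all = scd.community_redundancy(profiles)
print(f"full panel (12):  redundancy = {score_all.redundancy:.3f}, "
      f"mean profile entropy = {score_all.entropy_mean:.2f} bits")
print("\nRedundancy is 1 - C(concatenated profiles) / sum C(individual profiles), "
      "clipped to [0, 1]; higher means more duplicated function.")
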