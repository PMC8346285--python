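"""Overlap statistics for the eukaryote-wide and mammal-only candidate sets.

Two top-200 lists drawn independently from a 20,192-gene universe would
share about 2 genes (hypergeometric mean 200*200/20192 = 1.98); a larger
observed overlap indicates the two evolutionary scales agree on part of the
network.
"""

import coevonet as cn

print(f"expected chance overlap of two 200-gene lists from 20,192 genes: "
      f"{cn.expected_overlap(200, 200, 20192):.3f} "
      f"(rounds to {round(cn.expected_overlap(200, 200, 20192))})")

params = cn.SimulationParams(seed=42)
raw, genes, truth = cn.simulate_scores(params)
nppm = cn.npp(cn.apply_threshold(raw, cn.DEFAULT_BIT_MIN), genes)
panel = cn.simulate_species_panel(params.clade_plan, params.seed)
query = truth.module_members(0)[0]

e_set = cn.top_k(cn.rank_by_coevolution(nppm, query), 200, "E-set")
m_set = cn.top_k(cn.rank_by_coevolution(nppm, query, species=panel,
                                        clade="Mammalia"), 200, "M-set")
inter, union, res = cn.combine_sets(e_set, m_set, N=len(genes))

print(f"E-set r_min={e_set.r_min_observed:.3f}, "
      f"M-set r_min={m_set.r_min_observed:.3f}")
print(f"observed overlap {res.observed} (chance expectation {res.expected:.1f}), "
      f"union {res.union_size} genes")
print(f"hypergeometric P(overlap >= {res.observed}) = {res.p_upper:.3g}")
# The sets are not independent (mammals sit inside the eukaryote panel), so
# the hypergeometric p is a reference point, not a calibrated test here.
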