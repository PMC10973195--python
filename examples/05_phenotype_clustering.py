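"""Cluster compound phenotype profiles into mechanistic categories.

Simulates a screen with three planted effect archetypes (weak protection /
protection with microglial activation changes / protection via glial
depletion), builds the 14-column phenotype matrix, and recovers the three
categories by complete-linkage hierarchical clustering.
"""

import gliascreen as gs

comps = ([(f"weak{i}", gs.ARCHETYPES["category1"]) for i in range(6)]
         + [(f"mglia{i}", gs.ARCHETYPES["category2"]) for i in range(6)]
         + [(f"deplete{i}", gs.ARCHETYPES["category3"]) for i in range(6)])
design = gs.ScreenDesign(n_repeats=4, plates_per_repeat=3, plate_rows=8,
                         plate_cols=8, compounds=comps, seed=0,
                         controls={"DMSO": (gs.ARCHETYPES["null"], 6)})
obs, _ = gs.simulate_screen(design)

pm = gs.build_phenotype_matrix(obs, compounds=[c for c, _ in comps])
cr = gs.cluster_phenotypes(pm, k=3)
print("cluster assignments (compound -> category):")
print(cr.assignments.to_string())

# most compounds in this toy screen are active, so anchor the normalization
# on the DMSO wells rather than the all-well medians
nc, _ = gs.minmax_normalize(obs, anchor_wells="control")
hits = gs.call_hits(nc)
summary = gs.summarize_categories(cr, hits, pm)
summary["members"] = summary["members"].str.split(",").str[0] + ",..."
cols = ["category", "members", "mean_protection_percent",
        "mean_microglia_LPS+", "mean_astrocyte_LPS-"]
print("\nper-category summary (cluster ids are arbitrary):")
print(summary[cols].round(1).to_string(index=False))
print("\nEach cluster should collect one archetype: weak protection with")
print("unchanged glia; strong protection with increased LPS+ microglia;")
print("strongest protection with depleted microglia and astrocytes.")
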