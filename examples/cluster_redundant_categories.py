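"""Cluster regulated categories that share member proteins.

Hierarchical annotations (parent/child GO terms) make regulated categories
redundant. This example plants regulated categories, duplicates each with
overlapping variants to mimic that redundancy, clusters the significant
categories on the Jaccard similarity of their quantified members (average
linkage, cut at distance 0.75) and picks the |Zc|-strongest category as the
representative of each cluster — the one whose cumulative Zq curve a report
would display.
"""

from wsppq import (CategoryDB, category_similarity, cluster_categories,
                   make_fixture, run_wspp, test_category_regulation)

ds = make_fixture("planted_categories", seed=5)
result = run_wspp(ds.table, ds.design, ("G2", "G1"), ds.exclusions)

# mimic annotation redundancy: two overlapping variants of each category
cats = {}
for cid, (name, members) in ds.categories.categories.items():
    ordered = sorted(members)
    cats[cid] = (name, frozenset(ordered))
    cats[cid + "_child"] = (name + " (child term)", frozenset(ordered[:15]))
db = CategoryDB(cats)

reg = test_category_regulation(result, db, fdr=0.05, min_size=5)
hits = reg.loc[reg["regulated"]]
print(f"{len(hits)} regulated categories before redundancy reduction")

sim = category_similarity(db, list(hits["category_id"]),
                          set(result.included["protein_id"]))
assign = cluster_categories(sim, cut=0.75,
                            scores=dict(zip(hits["category_id"], hits["Zc"])),
                            sizes=dict(zip(hits["category_id"], hits["n"])))
print(f"{len(assign.clusters)} clusters after merging overlapping terms")
for k in sorted(assign.clusters)[:5]:
    rep = assign.representatives[k]
    zc = float(hits.set_index("category_id").loc[rep, "Zc"])
    print(f"  cluster {k}: {len(assign.clusters[k])} terms, "
          f"representative {rep} (Zc={zc:+.2f})")
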