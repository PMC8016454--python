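"""Rank-normalize two small DMS datasets for one protein and merge them.

Raw fitness values from different assays live on arbitrary scales; after
rank normalization both datasets are uniform with range 1 and anchored so
0 means "no change from wild type", which makes them directly mergeable.
"""

from dmsimpact import DmsDataset, VariantRecord, merge_datasets, normalize_dataset


def dataset(dataset_id, scores, wt_score):
    records = [
        VariantRecord(protein_id="TOY", position=pos, wt=wt, var=var, score=s)
        for (pos, wt, var), s in scores.items()
    ]
    return DmsDataset(dataset_id, "TOY", records, wt_score=wt_score)


# growth-rate assay: higher = fitter
growth = dataset(
    "toy_growth",
    {(1, "A", "V"): 0.95, (1, "A", "W"): 0.20, (2, "C", "Y"): 0.55, (3, "G", "P"): 0.05},
    wt_score=0.90,
)
# the same protein in a binding assay on a log scale
binding = dataset(
    "toy_binding",
    {(1, "A", "V"): -0.1, (1, "A", "W"): -3.2, (2, "C", "Y"): -1.5},
    wt_score=-0.2,
)

merged = merge_datasets([normalize_dataset(growth), normalize_dataset(binding)])
print("variant  normalized impact (quantile units, 0 = wild-type fitness)")
for (pos, wt, var), val in sorted(merged.entries.items()):
    print(f"{wt}{pos}{var:>4} {val:+.3f}")
print(
    "\nNegative values are loss-of-fitness substitutions; A1V sits near 0 in"
    "\nboth assays so its merged impact is mild, while A1W and G3P are severe."
)
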