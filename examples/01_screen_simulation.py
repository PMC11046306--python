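"""Simulate a pooled CRISPR screen and inspect its ground truth.

Builds a desk-scale two-background knockout screen (2,000 genes x 4 guides
plus 1,000 non-targeting controls), then prints the library composition and
the per-class gene counts the simulator recorded as truth.
"""

import feshift as fs

cfg = fs.ScreenSimConfig(seed=0)
ds = fs.gen_screen_dataset(cfg)

print(f"guides in library: {len(ds.counts)}")
print(f"samples:           {list(ds.counts.columns)}")
print(f"reads per sample:  {ds.counts.sum(axis=0).iloc[0]:,}")
print("gene classes (targeting genes only):")
print(ds.truth.loc[~ds.truth["is_ntc"], "gclass"].value_counts().to_string())

# The analytic design check used when sizing a real screen: how many
# selection-surviving cells cover each guide at a given MOI?
cov = fs.expected_coverage(cells=6.5e7, moi=0.5, n_guides=77_441)
print(f"\nexpected coverage at 6.5e7 cells, MOI 0.5, 77,441 guides: "
      f"{cov:.0f} cells/guide (>= 300 is the usual design floor)")
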