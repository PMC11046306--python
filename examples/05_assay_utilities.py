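"""Closed-form helpers for the small supporting assays.

Relative mtDNA copy number by delta-delta-Ct, reference-gene normalization,
RNA-IP enrichment and Fe stoichiometry from ICP-MS concentrations.
"""

import pandas as pd

import feshift as fs

# mtDNA copy number: mitochondrial vs nuclear target, test vs control cells.
q = fs.CtQuartet(ct_target_test=16.4, ct_ref_test=22.1,
                 ct_target_ctrl=16.0, ct_ref_ctrl=22.0)
ratio = fs.ddct_ratio(q)
print(f"relative mtDNA abundance (test / control): {ratio:.3f}")
print("  (1.0 means unchanged copy number; ddCt assumes doubling per cycle)")

# expression values normalized to a reference gene measured in each sample
values = pd.Series({"ctrl": 820.0, "edited": 410.0})
reference = pd.Series({"ctrl": 205.0, "edited": 102.5})
print("\nreference-normalized expression:")
print(fs.reference_normalize(values, reference).to_string())

# RNA immunoprecipitation: bait binding to a target RNA, normalized to
# input RNA and bait expression level
enr = fs.frip_enrichment(ip_12s=9.0, input_12s=3.0, construct_level=1.5)
print(f"\nRNA-IP enrichment (IP/input per unit bait): {enr:.2f}")

# metal stoichiometry from ICP-MS: an intact 4Fe-4S protein reads near 4
print(f"\nFe per polypeptide at 37 uM Fe / 10 uM protein: "
      f"{fs.fe_per_polypeptide(37.0, 10.0):.1f}")
print(f"Fe per polypeptide after mutating the cluster cysteines: "
      f"{fs.fe_per_polypeptide(2.0, 10.0):.1f}")
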