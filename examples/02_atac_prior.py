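"""Build cell-specific prior networks from chromatin accessibility.

Constructs a toy accessibility input — three regions, two of them carrying
a TF motif, only one inside the 50 kb upstream window of a target gene's
TSS — and shows how per-cell accessibility turns into per-cell prior
adjacencies: an interaction is allowed in a cell only if a region
accessible in that cell links the TF (by motif) and the target (by genomic
window) simultaneously.
"""

import numpy as np
import pandas as pd

from cellgrn import AccessibilityInputs, prior_from_atac

genes = ["tfA", "tfB", "target1", "target2"]

acc = AccessibilityInputs(
    # two cells; cell 0 has all regions open, cell 1 only the last
    region_matrix=np.array([[1, 1, 1],
                            [0, 0, 1]]),
    region_coords=pd.DataFrame(
        [("chr1", 90_000, 91_000),    # 10 kb upstream of target1 TSS
         ("chr1", 30_000, 31_000),    # 70 kb upstream: outside the window
         ("chr2", 199_000, 199_500)], # 1.5 kb upstream of target2 TSS
        columns=["chrom", "start", "end"]),
    tss_table=pd.DataFrame(
        [("target1", "chr1", 100_001, "+"),
         ("target2", "chr2", 200_001, "+")],
        columns=["gene", "chrom", "tss", "strand"]),
    motif_hits={(0, "tfA"), (1, "tfA"), (2, "tfB")},
)

prior = prior_from_atac(acc, genes, window_bp=50_000)
for i in range(2):
    pairs = [(genes[a], genes[b])
             for a, b in zip(*np.triu_indices(4, k=1))
             if prior.G_prior[i, a, b]]
    print(f"cell {i}: allowed interactions {pairs or 'none'}")
print("Cell 0 allows tfA-target1 (region 0, in-window motif region) and "
      "tfB-target2; cell 1 keeps only tfB-target2 because region 0 is "
      "closed there.  Region 1 never links: it is 70 kb upstream.")
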