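"""Amplicon-panel copy number: filters, pool normalization, gene estimates.

A targeted panel is preprocessed by removing amplicons in the lowest 5th
percentile of control means and those with CV >= 0.3 across controls,
then pool medians are equalized, and each gene's copy number is 2x the
median tumor/normal ratio of its surviving amplicons.
"""

import numpy as np
import pandas as pd

from pdxkit import filter_amplicons, gene_copy_number, pool_normalize

rng = np.random.default_rng(4)
genes = [f"GENE{i:02d}" for i in range(20)]
truth = {g: 2 for g in genes}
truth["GENE00"], truth["GENE01"] = 4, 1

rows, idx = {}, []
for g in genes:
    for j in range(8):
        mean = rng.uniform(150, 400)
        idx.append(f"{g}_amp{j}")
        rows[idx[-1]] = (
            g,
            int(rng.integers(1, 5)),
            rng.poisson(mean * truth[g] / 2),  # tumor
            rng.poisson(mean), rng.poisson(mean), rng.poisson(mean),  # controls
        )
panel = pd.DataFrame.from_dict(rows, orient="index",
                               columns=["gene_id", "pool", "TUM", "N1", "N2", "N3"])
panel.index.name = "amplicon_id"

retained, report, threshold = filter_amplicons(panel, ["N1", "N2", "N3"])
normalized = pool_normalize(retained)
profile = gene_copy_number(normalized, "TUM", ["N1", "N2", "N3"])

print(f"amplicons: {len(panel)} in, {len(retained)} kept "
      f"(removed: {report['reason'].value_counts().to_dict()}, "
      f"low-count threshold {threshold:.1f})")
for g in ("GENE00", "GENE01", "GENE05"):
    print(f"{g}: true CN {truth[g]}, estimated {profile.cn[g]:.2f}")
print("The median-of-ratios estimate lands within a fraction of a copy of")
print("the planted values; single noisy amplicons cannot drag a gene call.")
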