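"""Sample-purity check: regress a bulk profile on single-cell consensus profiles.

If a bulk RNA sample were contaminated by known somatic cell types, a
linear combination of those cell types' consensus expression profiles
would explain it (high R^2).  Here a bulk profile built as an exact 60/40
mixture of two cluster profiles is recovered perfectly, while a permuted
(independent) profile yields R^2 near zero - the signature of a pure
sample.
"""

import numpy as np
import pandas as pd

from intactrna.stats import consensus_profiles, purity_regression

rng = np.random.default_rng(11)
n_cells, n_genes, n_clusters = 100, 1000, 5
counts = pd.DataFrame(
    rng.integers(1, 60, size=(n_cells, n_genes)),
    index=[f"cell{i}" for i in range(n_cells)],
    columns=[f"g{i}" for i in range(n_genes)],
)
labels = [f"c{i % n_clusters}" for i in range(n_cells)]

profiles = consensus_profiles(counts, labels)  # genes x clusters, per-cell unit-sum
bulk = 0.6 * profiles["c0"] + 0.4 * profiles["c2"]

res = purity_regression(counts, labels, bulk)
print(f"exact mixture: R^2 = {res.r_squared:.4f}")
print("coefficients:", {k: round(v, 3) for k, v in res.coefficients.items()})

perm = rng.permutation(len(bulk))
bulk_perm = pd.Series(bulk.to_numpy()[perm], index=bulk.index)
res0 = purity_regression(counts, labels, bulk_perm)
print(f"permuted bulk: R^2 = {res0.r_squared:.4f}")
# the mixture weights (0.6, 0.4) are recovered exactly; the permuted
# profile shows no linear relationship to any cluster
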