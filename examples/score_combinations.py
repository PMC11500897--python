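"""Score SNP combinations with the three association objectives and the G-test.

Lower K2 / CE (conditional entropy) / Gini means stronger association between
a combination's joint genotypes and case-control status.  The planted pair
should score far below any noise combination, and its G-test p-value should
be tiny, while a noise pair stays near the null.
"""

import numpy as np

from epissa import Scorer, auto_ml, auto_mo, find_dnme_model, generate_dataset

rng = np.random.default_rng(1)
model = find_dnme_model(2, (0.4, 0.4), 0.1, rng=rng)
dataset, truth = generate_dataset(model, 800, 800, 100, rng=rng)

mo = auto_mo(dataset.m0, dataset.m1)
ml = auto_ml(dataset.m0, dataset.m1)
print(f"auto parameters for {dataset.m0}+{dataset.m1} samples: "
      f"max order mo = {mo}, table cap ml = {ml}")

scorer = Scorer(dataset, ml=ml)
pair = sorted(dataset.snp_names.index(n) for n in next(iter(truth.functional_sets)))
noise = [i for i in range(6) if i not in pair][:2]

for label, snps in [("planted pair", pair), ("noise pair", noise)]:
    s = scorer.scores(snps)
    stat, df, p = scorer.g_test(snps)
    names = [dataset.snp_names[i] for i in snps]
    print(f"\n{label} {names}:")
    print(f"  K2 = {s.k2:.2f}, CE = {s.ce:.4f} nats, Gini = {s.gini:.4f}")
    print(f"  G = {stat:.2f} on df = {df}  ->  p = {p:.3e}")
print("\nThe planted pair's objectives sit well below the noise pair's and "
      "its p-value is many orders of magnitude smaller.")
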