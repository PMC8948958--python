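"""Fisher's exact probability of cross-validated confusion tables.

For a near-diagonal table the probability that the actual-by-predicted
association arises by chance (all margin-preserving tables at most as
probable as the observed one, summed) is essentially zero; an
uninformative table gives 1."""

import trichospec as ts

genetics = [[238, 1], [0, 60]]        # 2 classes, 299 spectra
variety = [[54, 0, 0, 0], [0, 49, 0, 0], [0, 0, 53, 0], [1, 0, 0, 58]]

p1 = ts.fisher_2x2(genetics)
print(f"2x2 genetics table: p = {p1:.3e}  (rounds to {p1:.2f})")

p2 = ts.fisher_rxc(variety, n_mc=200_000, seed=0)
print(f"4x4 variety table:  p = {p2:.3e}  (Monte Carlo, rounds to {p2:.2f})")

print(f"uninformative [[1,1],[1,1]]: p = {ts.fisher_2x2([[1, 1], [1, 1]]):.2f}")
print(f"diagonal [[5,0],[0,5]]:      p = {ts.fisher_2x2([[5, 0], [0, 5]]):.5f} "
      "(exactly 2/252)")
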