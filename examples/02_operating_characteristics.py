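"""Operating characteristics from leave-one-variant-out call counts.

Recomputes a published-style evaluation row from raw tallies: with 42 known
benign variants (41 called benign, one no-call) and 21 known pathogenic
variants (all called pathogenic), the Jeffreys-prior Dirichlet-multinomial
posterior means and exact-Beta 95% highest-density intervals give the
familiar sensitivity/specificity table.
"""

import varcallxt as vx
from varcallxt import evaluation

benign = vx.CallCounts(evaluation.KNOWN_BENIGN, 41, 1, 0)
pathogenic = vx.CallCounts(evaluation.KNOWN_PATHOGENIC, 0, 0, 21)

for counts, name in ((benign, "known benign"), (pathogenic, "known pathogenic")):
    means = vx.dirichlet_oc(counts)
    print(f"\n{name} (n={counts.total}):")
    for category, mean in means.items():
        lo, hi = vx.dirichlet_hdr(counts, category, 0.95)
        print(f"  {category:>18}: {mean:5.1f}%  95% HDR ({100 * lo:.1f}, "
              f"{100 * hi:.1f})")

acc = vx.raw_accuracy(benign, pathogenic)
print(f"\nraw accuracy (no-calls counted as errors): {acc:.1f}%")
print("posterior means use (count + 1/2)/(n + 3/2); the sensitivity HDR "
      "lower bound is the closed form 0.05^(1/21.5) because the Beta(21.5, 1) "
      "marginal is monotone.")
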