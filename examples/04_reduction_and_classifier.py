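"""Supervised vs unsupervised reduction, and the quadratic classifier.

First: on data where the high-variance axis carries no class information,
the Karhunen-Loeve expansion keeps the wrong axis while the scatter-matrix
criterion keeps the discriminative one. Second: a quadratic discriminant
solves the concentric-classes problem that defeats any linear boundary.
"""

import numpy as np

from eegspike import (
    design_quadratic,
    evaluate_h,
    kl_reduction,
    scatter_reduction,
    scatter_stats,
    separability_index,
)

rng = np.random.default_rng(0)

# axis 1: variance 100, no class separation; axis 2: small variance, separates
n = 300
x = np.column_stack([
    10.0 * rng.standard_normal(2 * n),
    np.concatenate([rng.normal(-1, 0.2, n), rng.normal(1, 0.2, n)]),
])
labels = ["a"] * n + ["b"] * n
stats = scatter_stats(x, labels)
scat = scatter_reduction(stats, m=1)
kl = kl_reduction(x, m=1)
print(f"separability index J = {separability_index(stats):.2f}")
print(f"scatter map keeps axis {int(np.argmax(np.abs(scat.matrix[:, 0]))) + 1} "
      f"(discriminative), KL keeps axis {int(np.argmax(np.abs(kl.matrix[:, 0]))) + 1} "
      f"(high variance)")

# concentric classes: inner disc vs annulus
def ring(n, r_lo, r_hi):
    r = np.sqrt(rng.uniform(r_lo**2, r_hi**2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])

inner, outer = ring(500, 0, 1), ring(500, 2, 3)
clf = design_quadratic(inner, outer, class_neg="inner", class_pos="outer")
test_in, test_out = ring(500, 0, 1), ring(500, 2, 3)
acc = (np.sum(np.asarray(evaluate_h(clf, test_in)) < 0)
       + np.sum(np.asarray(evaluate_h(clf, test_out)) >= 0)) / 1000
print(f"quadratic classifier on concentric classes: {100 * acc:.1f}% test accuracy")
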