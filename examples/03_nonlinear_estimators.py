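"""Validate the nonlinear estimators on signals with known ground truth.

The fully chaotic logistic map (r=4) has largest Lyapunov exponent ln 2 ~
0.693 per iteration; the Henon attractor embeds in two dimensions; a uniform
cloud on the unit square has correlation dimension 2. The estimates below
should land near those values.
"""

import numpy as np

from eegspike import (
    attractor_radius,
    canonical_signal,
    cao_functions,
    correlation_dimension,
    divergence_curve,
    embed,
    largest_lyapunov,
    min_embedding_dimension,
)

# largest Lyapunov exponent of the logistic map
x = canonical_signal("logistic_map", n=4000).samples
pts = embed(x, lag=1, dim=2)
curve = divergence_curve(pts, k=10, mode="sato", theiler=2, seed=0)
lam = largest_lyapunov(curve, ts=1.0)
print(f"logistic map lyapunov: {lam:.3f}  (theory ln 2 = {np.log(2):.3f})")

# minimum embedding dimension of the Henon x-series via Cao's method
h = canonical_signal("henon_map", n=2000).samples
e, e_star = cao_functions(h, lag=1, d_max=5, max_points=2000, seed=0)
print(f"henon Cao d_min: {min_embedding_dimension(e)}  (theory 2)")

# correlation dimension of a uniform square cloud (Takens estimator)
cloud = np.random.default_rng(1).uniform(size=(2000, 2))
eps = attractor_radius(cloud, fraction=0.05, sample_size=2000)
d = correlation_dimension(cloud, eps, max_points=2000)
print(f"uniform square correlation dimension: {d:.3f}  (theory 2)")
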