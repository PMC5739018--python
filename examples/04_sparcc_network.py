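"""Compositionality-robust correlations with bootstrap pseudo-p-values.

Closes ten independent log-normal taxa plus one planted identical pair into
compositions and compares naive Pearson-on-proportions with the basis
correlation estimate.
"""

import numpy as np

import oligonet as on

rng = np.random.default_rng(3)
absab = rng.lognormal(0.0, 1.0, size=(120, 12))
absab[:, 1] = absab[:, 0]                      # planted rho = 1 pair
fracs = absab / absab.sum(axis=1, keepdims=True)
counts = np.vstack([rng.multinomial(5000, f) for f in fracs])

naive = np.corrcoef((counts / counts.sum(1, keepdims=True)).T)
net = on.sparcc(counts, n_dirichlet=10, seed=7)
pvals = on.bootstrap_pvalues(counts, n_boot=100, seed=7, observed=net)

est = net.rho.to_numpy()
off = ~np.eye(12, dtype=bool)
off[0, 1] = off[1, 0] = False
print(f"planted pair: naive r = {naive[0,1]:.2f}, basis rho = {est[0,1]:.2f}, "
      f"pseudo-p = {pvals.iloc[0,1]:.4f}")
print(f"independent pairs: mean |naive r| = {np.abs(naive[off]).mean():.3f}, "
      f"mean |basis rho| = {np.abs(est[off]).mean():.3f}")
# The basis estimate keeps the planted association and strips the spurious
# correlations that closure induces among independent taxa.
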