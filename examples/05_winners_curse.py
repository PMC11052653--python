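"""Winner's-curse correction of GWAS Z-scores.

Simulates a GWAS where 5% of variants carry true noncentrality 3, selects
the top hits by |z|, and shows that the FDR inverse-quantile-transformed
scores are closer to the true effects than the raw ones.
"""

import numpy as np

import cosmix as cx

rng = np.random.default_rng(40)
m = 10_000
mu = np.zeros(m)
mu[rng.random(m) < 0.05] = 3.0
z = mu + rng.standard_normal(m)

z_adj, q = cx.fiqt(z)

top = np.argsort(-np.abs(z))[:100]
mse_raw = np.mean((z[top] - mu[top]) ** 2)
mse_adj = np.mean((z_adj[top] - mu[top]) ** 2)

print(f"top-100 |z| of {m} variants (5% non-null, true mu = 3)")
print(f"  mean raw      |z| : {np.abs(z[top]).mean():.3f}")
print(f"  mean adjusted |z| : {np.abs(z_adj[top]).mean():.3f}")
print(f"  MSE vs truth  raw {mse_raw:.3f}  adjusted {mse_adj:.3f}")
print("  -> selected scores overshoot their true effects; shrinking through")
print("     BH-adjusted p-values removes most of the selection bias")
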