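"""Winner's-curse correction by FDR inverse quantile transformation.

Variants selected for significance have upward-biased effect estimates.
The transformation converts each Z-score to a two-sided p-value, applies
the Benjamini–Hochberg step-up adjustment, and maps the adjusted value back
through the normal quantile function:

    z_adj = sign(z) * Phi^{-1}(1 - q/2),   q = BH(2 Phi(-|z|)).

Because BH never decreases a p-value, |z_adj| <= |z| componentwise, signs
are preserved, and the (weak) ordering of |z| is preserved.  P-values are
floored at ``min_p`` (default 1e-320) before adjustment so extreme scores
stay finite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        bad = np.flatnonzero(~((p > 0) & (p <= 1)))[0]
        raise ValueError(f"p-values must lie in (0, 1]; offending index {bad}")
    return multipletests(p, method="fdr_bh")[1]


def fiqt(z: np.ndarray, min_p: float = 1e-320) -> tuple[np.ndarray, np.ndarray]:
    """Adjust a Z-score vector for the winner's curse.

    Returns ``(z_adj, q)``: the adjusted scores and the BH-adjusted
    two-sided p-values they correspond to.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        bad = int(np.flatnonzero(~np.isfinite(z))[0])
        raise ValueError(f"non-finite Z-score at index {bad}")
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.maximum(p, min_p)
    q = bh_adjust(p)
    z_adj = np.sign(z) * stats.norm.isf(q / 2.0)
    return z_adj, q
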