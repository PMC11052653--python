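"""Ancestry composition of a GWAS cohort from summary data alone.

``afmix`` fits cohort allele frequencies as a convex combination of panel
population frequencies: the mixing proportions minimize
``sum_j (af1_j - sum_k pi_k f_kj)^2`` over the probability simplex.  SNPs
are MAF-filtered and index-thinned to curb LD dependence between residuals.

``zmix`` covers cohorts publishing only association Z-scores.  Under a
predominantly null (or highly polygenic) GWAS the Z-scores of nearby SNPs
are approximately multivariate normal with covariance equal to the cohort's
LD matrix, which for an admixed cohort is the ancestry-informed mixture LD
R(pi).  The proportions are therefore estimated by maximizing a windowed
Gaussian composite likelihood: the genome is cut into short windows of
neighbouring measured SNPs, and

    pi_hat = argmin_simplex  sum_w [ log det R_w(pi) + z_w' R_w(pi)^{-1} z_w ]

A small ridge keeps each window matrix invertible.  Pairwise moment
matching of Z-score products against mixture LD targets the same signal but
is far noisier at realistic scale; the composite likelihood uses the full
window correlation structure and recovers proportions from a few thousand
SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import InsufficientDataError
from .ld import MixingProportions
from .panel import PopulationAF, ReferencePanel, population_allele_frequencies

_MIN_SNPS = 10


def afmix(
    cohort_af: pd.DataFrame,
    panel_af: PopulationAF,
    maf_min: float = 0.01,
    thin_step: int = 10,
) -> MixingProportions:
    """Estimate mixing proportions from cohort allele frequencies.

    ``cohort_af`` must be aligned to the panel (carry a ``panel_idx``
    column and af1 oriented to the panel a1 allele).  Variants are filtered
    to panel-wide MAF >= ``maf_min`` and thinned to every ``thin_step``-th
    survivor so residuals are roughly LD-independent.  The solver is
    non-negative least squares on the system augmented with a heavily
    penalized sum-to-one row, renormalized afterwards; it is deterministic
    and exact on noiseless mixtures.
    """
    idx = cohort_af["panel_idx"].to_numpy()
    F = panel_af.freqs[:, idx]  # (K, m)
    b = cohort_af["af1"].to_numpy(dtype=float)

    mean_af = F.mean(axis=0)
    usable = np.minimum(mean_af, 1 - mean_af) >= maf_min
    keep = np.flatnonzero(usable)[::max(1, int(thin_step))]
    if keep.size < _MIN_SNPS:
        raise InsufficientDataError(
            f"only {keep.size} usable SNPs after MAF/thinning filters "
            f"(need >= {_MIN_SNPS})"
        )
    A = F[:, keep].T  # (m_used, K)
    y = b[keep]

    warning = None
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warning = "population AF matrix is rank-deficient; proportions not identifiable"

    penalty = 1e4 * np.linalg.norm(A, axis=0).mean()
    A_aug = np.vstack([A, penalty * np.ones(A.shape[1])])
    y_aug = np.append(y, penalty)
    w, _ = optimize.nnls(A_aug, y_aug)
    total = w.sum()
    if total <= 0:
        raise InsufficientDataError("degenerate NNLS solution (all-zero weights)")
    return MixingProportions(list(panel_af.populations), w / total, warning=warning)


def _zmix_windows(
    zscores: pd.DataFrame,
    panel: ReferencePanel,
    window_bp: int,
    max_snps: int,
    maf_min: float,
) -> list[list[int]]:
    """Runs of neighbouring measured SNPs (panel indices), chunked to max_snps."""
    paf = population_allele_frequencies(panel)
    pooled = paf.freqs.mean(axis=0)
    ok_maf = np.minimum(pooled, 1 - pooled) >= maf_min

    sub = zscores[ok_maf[zscores["panel_idx"].to_numpy()]]
    sub = sub.sort_values(["chr", "bp"], kind="mergesort")
    idx = sub["panel_idx"].to_numpy()
    bps = sub["bp"].to_numpy(dtype=np.int64)
    chrs = sub["chr"].to_numpy()

    runs, cur = [], [0]
    for a in range(1, len(idx)):
        if chrs[a] == chrs[cur[0]] and bps[a] - bps[cur[-1]] <= window_bp:
            cur.append(a)
        else:
            runs.append(cur)
            cur = [a]
    runs.append(cur)

    windows = []
    for run in runs:
        for s in range(0, len(run), max_snps):
            chunk = run[s:s + max_snps]
            if len(chunk) >= 2:
                windows.append([int(idx[a]) for a in chunk])
    return windows


def zmix(
    zscores: pd.DataFrame,
    panel: ReferencePanel,
    window_bp: int = 100_000,
    max_snps: int = 30,
    max_windows: int | None = 500,
    maf_min: float = 0.01,
    ridge: float = 0.05,
    seed: int = 42,
) -> MixingProportions:
    """Estimate mixing proportions from association Z-scores alone.

    ``zscores`` must be aligned to the panel.  Measured SNPs are grouped
    into windows (neighbours within ``window_bp``, chunked to ``max_snps``
    SNPs); at most ``max_windows`` windows are kept, subsampled with
    ``seed`` for genome-scale inputs.  The simplex point maximizing the
    windowed Gaussian composite likelihood of the observed Z-scores under
    mixture LD is returned.  If the candidate populations have
    indistinguishable LD the result carries a non-identifiability warning.
    """
    windows = _zmix_windows(zscores, panel, window_bp, max_snps, maf_min)
    if not windows:
        raise InsufficientDataError(
            f"no window with >= 2 SNPs within {window_bp} bp; "
            "cannot estimate LD-based ancestry"
        )
    if max_windows is not None and len(windows) > max_windows:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(windows), size=max_windows, replace=False)
        windows = [windows[i] for i in sorted(pick)]

    K = len(panel.populations)
    z_of = dict(zip(zscores["panel_idx"].to_numpy(),
                    zscores["z"].to_numpy(dtype=float)))

    # batch windows of equal size for stacked linear algebra
    groups: dict[int, list[list[int]]] = {}
    for w in windows:
        groups.setdefault(len(w), []).append(w)
    batches = []
    for size, ws in groups.items():
        N = len(ws)
        C = np.empty((N, K, size, size))
        MU = np.empty((N, K, size))
        Z = np.empty((N, size))
        for n, w in enumerate(ws):
            sel = np.asarray(w)
            Z[n] = [z_of[j] for j in w]
            for k, pop in enumerate(panel.populations):
                g = panel.genotypes[pop][:, sel].astype(float)
                MU[n, k] = g.mean(axis=0)
                C[n, k] = np.atleast_2d(np.cov(g.T))
        batches.append((C, MU, Z))

    eyes = {s: np.eye(s) for s in groups}

    def negll(wt: np.ndarray) -> float:
        tot = 0.0
        for C, MU, Z in batches:
            V = np.einsum("k,nkij->nij", wt, C)
            mbar = np.einsum("k,nks->ns", wt, MU)
            d = MU - mbar[:, None, :]
            V = V + np.einsum("k,nki,nkj->nij", wt, d, d)
            diag = np.sqrt(np.clip(np.diagonal(V, axis1=1, axis2=2), 1e-12, None))
            R = V / (diag[:, :, None] * diag[:, None, :])
            R = (R + ridge * eyes[R.shape[-1]]) / (1.0 + ridge)
            _, logdet = np.linalg.slogdet(R)
            sol = np.linalg.solve(R, Z[..., None])[..., 0]
            tot += 0.5 * (logdet.sum() + np.einsum("ns,ns->", Z, sol))
        return float(tot)

    vertex_obj = [negll(np.eye(K)[k]) for k in range(K)]
    warning = None
    if K > 1 and max(vertex_obj) - min(vertex_obj) < 1e-4:
        warning = ("candidate populations yield indistinguishable LD; "
                   "proportions not identifiable")

    starts = [np.full(K, 1.0 / K)]
    starts += [0.8 * np.eye(K)[k] + 0.2 / K for k in range(K)]
    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    best_w, best_f = starts[0], np.inf
    for w0 in starts:
        res = optimize.minimize(
            negll, w0, method="SLSQP", bounds=[(0.0, 1.0)] * K,
            constraints=constraints, options={"maxiter": 80, "ftol": 1e-9},
        )
        if res.fun < best_f:
            best_w, best_f = np.clip(res.x, 0.0, None), res.fun
    best_w = best_w / best_w.sum()
    return MixingProportions(list(panel.populations), best_w, warning=warning)
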