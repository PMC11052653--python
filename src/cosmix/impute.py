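"""Conditional-Gaussian imputation of association Z-scores.

Under the standard GWAS model, Z-scores of variants in LD are jointly
multivariate normal with correlation equal to the cohort LD matrix.  The
Z-score of an unmeasured variant set u given measured variants o is
therefore predicted by the conditional mean

    zhat_u = Sigma_uo (Sigma_oo + lambda I)^{-1} z_o

with per-variant imputation quality (the variance explained, an r^2)

    info_u = diag( Sigma_uo (Sigma_oo + lambda I)^{-1} Sigma_ou ).

The ridge ``lambda`` stabilizes the solve when the observed LD block is
near-singular.  Standardized scores ``z_std = zhat / sqrt(info)`` put
imputed statistics back on the N(0,1) null scale; at lambda = 0 this is
exact, and for lambda > 0 it is slightly conservative.

Genome-scale runs tile the region into non-overlapping 1-Mb cores with
flanking buffers; each window is solved with one symmetric factorization
shared across all unmeasured variants, and results are reported for core
variants only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import NumericalError
from .ld import MixingProportions, compute_ld
from .panel import ReferencePanel, population_allele_frequencies

FLAG_OBSERVED = "observed"
FLAG_IMPUTED = "imputed"
FLAG_LOW_INFO = "skipped_low_info"
FLAG_MONOMORPHIC = "skipped_monomorphic"

RESULT_COLUMNS = ["rsid", "chr", "bp", "a1", "a2", "z", "info", "p", "flag"]


def conditional_impute(
    z_o: np.ndarray,
    sigma_oo: np.ndarray,
    sigma_uo: np.ndarray,
    lam: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional-mean prediction of unmeasured Z-scores.

    Parameters
    ----------
    z_o
        Observed Z-scores, length m_o.
    sigma_oo
        (m_o, m_o) LD among observed variants (symmetric).
    sigma_uo
        (m_u, m_o) LD between unmeasured and observed variants.
    lam
        Ridge weight added to the diagonal of ``sigma_oo``; must be >= 0.

    Returns
    -------
    (zhat, info)
        Predicted Z-scores and imputation quality r^2 per unmeasured
        variant.  Solved via a single Cholesky factorization; the explicit
        inverse is never formed.
    """
    z_o = np.asarray(z_o, dtype=float)
    sigma_oo = np.asarray(sigma_oo, dtype=float)
    sigma_uo = np.atleast_2d(np.asarray(sigma_uo, dtype=float))
    if lam < 0:
        raise ValueError("ridge weight lambda must be >= 0")
    m_o = z_o.size
    if sigma_oo.shape != (m_o, m_o):
        raise ValueError("sigma_oo shape does not match z_o")
    if sigma_uo.shape[1] != m_o:
        raise ValueError("sigma_uo column count does not match z_o")
    if m_o == 0:
        m_u = sigma_uo.shape[0]
        return np.zeros(m_u), np.zeros(m_u)

    A = sigma_oo + lam * np.eye(m_o)
    try:
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError:
        raise NumericalError(
            "observed LD block plus ridge is not positive definite; "
            "increase lambda"
        ) from None
    # cheap condition estimate from the Cholesky diagonal (squared)
    d = np.diag(cho[0])
    cond = (d.max() / d.min()) ** 2
    if cond > 1e12:
        raise NumericalError(
            f"observed LD block is near-singular (condition ~{cond:.2g}); "
            "increase lambda"
        )
    zhat = sigma_uo @ linalg.cho_solve(cho, z_o, check_finite=False)
    solved = linalg.cho_solve(cho, sigma_uo.T, check_finite=False)
    info = np.einsum("ij,ji->i", sigma_uo, solved)
    info = np.clip(info, 0.0, None)
    if (info > 1 + 1e-6).any():
        # can only occur when sigma is not a proper correlation matrix
        info = np.minimum(info, 1.0 + 1e-6)
    return zhat, info


@dataclass(frozen=True)
class Window:
    """A core interval plus flanking buffers, clipped to region bounds."""

    chrom: str
    core_start: int
    core_end: int
    flank_bp: int
    region_start: int
    region_end: int

    @property
    def full_start(self) -> int:
        return max(self.region_start, self.core_start - self.flank_bp)

    @property
    def full_end(self) -> int:
        return min(self.region_end, self.core_end + self.flank_bp)


def partition_windows(
    region: tuple[str, int, int],
    core_bp: int = 1_000_000,
    flank_bp: int = 250_000,
) -> list[Window]:
    """Tile a region into consecutive non-overlapping cores with flanks."""
    chrom, start, end = region
    if end < start:
        raise ValueError(f"empty region {chrom}:{start}-{end}")
    windows = []
    s = start
    while s <= end:
        e = min(s + core_bp - 1, end)
        windows.append(Window(chrom, s, e, flank_bp, start, end))
        s = e + 1
    return windows


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def distmix(
    zscores: pd.DataFrame,
    panel: ReferencePanel,
    pi: MixingProportions,
    region: tuple[str, int, int],
    lam: float = 0.1,
    maf_min: float = 0.001,
    info_min: float = 0.3,
    core_bp: int = 1_000_000,
    flank_bp: int = 250_000,
) -> pd.DataFrame:
    """Impute Z-scores of unmeasured panel variants in a region.

    ``zscores`` must be aligned to the panel (``panel_idx`` column, panel
    allele orientation).  Per window: measured study variants in
    core+flanks inform every unmeasured panel variant in the core with
    pooled-mixture MAF >= ``maf_min``; the ancestry-informed LD comes from
    :func:`cosmix.ld.compute_ld` under ``pi``.  Imputed rows report the
    standardized score ``z_std = zhat/sqrt(info)`` in the ``z`` column and
    its two-sided normal p-value; rows with ``info < info_min`` are flagged
    and carry no p-value.  Measured variants are echoed with info = 1.

    Returns a DataFrame with columns ``rsid chr bp a1 a2 z info p flag``.
    """
    chrom = region[0]
    obs_idx_all = zscores["panel_idx"].to_numpy()
    z_by_idx = dict(zip(obs_idx_all, zscores["z"].to_numpy(dtype=float)))

    pop_af = population_allele_frequencies(panel)
    mix_af = pop_af.mixture_af(pi.weights)
    mix_maf = np.minimum(mix_af, 1.0 - mix_af)

    bp = panel.variants["bp"].to_numpy()
    results = []
    for w in partition_windows(region, core_bp=core_bp, flank_bp=flank_bp):
        full_idx = panel.region_indices(w.chrom, w.full_start, w.full_end)
        core_idx = panel.region_indices(w.chrom, w.core_start, w.core_end)
        if core_idx.size == 0:
            continue
        obs_idx = np.array(sorted(set(full_idx) & set(obs_idx_all)), dtype=int)
        core_set = set(core_idx)
        obs_set = set(obs_idx)

        unmeas, skipped = [], []
        for j in core_idx:
            if j in obs_set:
                continue
            if mix_maf[j] < maf_min:
                skipped.append((j, FLAG_MONOMORPHIC))
            else:
                unmeas.append(j)
        unmeas = np.array(unmeas, dtype=int)

        if obs_idx.size == 0:
            for j in unmeas:
                skipped.append((j, FLAG_LOW_INFO))
            unmeas = np.array([], dtype=int)

        if unmeas.size and obs_idx.size:
            sel = np.concatenate([obs_idx, unmeas])
            ld = compute_ld(panel, pi, variant_idx=sel)
            # map surviving variants back; monomorphic ones were dropped
            kept_pos = {
                (c, int(b)): i
                for i, (c, b) in enumerate(zip(ld.variants["chr"], ld.variants["bp"]))
            }
            def ld_row(j):
                return kept_pos.get((panel.variants["chr"].iat[j], int(bp[j])))
            o_rows = [(j, ld_row(j)) for j in obs_idx]
            o_rows = [(j, r) for j, r in o_rows if r is not None]
            u_rows = []
            for j in unmeas:
                r = ld_row(j)
                if r is None:
                    skipped.append((j, FLAG_MONOMORPHIC))
                else:
                    u_rows.append((j, r))
            if o_rows and u_rows:
                o_i = np.array([r for _, r in o_rows])
                u_i = np.array([r for _, r in u_rows])
                z_o = np.array([z_by_idx[j] for j, _ in o_rows])
                zhat, info = conditional_impute(
                    z_o, ld.R[np.ix_(o_i, o_i)], ld.R[np.ix_(u_i, o_i)], lam=lam
                )
                info = np.minimum(info, 1.0)
                for (j, _), zh, inf in zip(u_rows, zhat, info):
                    if inf < info_min:
                        results.append((j, np.nan, inf, np.nan, FLAG_LOW_INFO))
                    else:
                        z_std = zh / np.sqrt(inf)
                        results.append((j, z_std, inf, float(_two_sided_p(z_std)),
                                        FLAG_IMPUTED))
            else:
                for j, _ in u_rows:
                    skipped.append((j, FLAG_LOW_INFO))

        for j in sorted(core_set & obs_set):
            z = z_by_idx[j]
            results.append((j, z, 1.0, float(_two_sided_p(z)), FLAG_OBSERVED))
        for j, flag in skipped:
            results.append((j, np.nan, 0.0 if flag == FLAG_LOW_INFO else np.nan,
                            np.nan, flag))

    if not results:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    res = pd.DataFrame(results, columns=["panel_idx", "z", "info", "p", "flag"])
    out = panel.variants.iloc[res["panel_idx"]].reset_index(drop=True)
    for col in ("z", "info", "p"):
        out[col] = res[col].to_numpy(dtype=float)
    out["flag"] = res["flag"].to_numpy()
    out = out.sort_values(["chr", "bp"], kind="mergesort").reset_index(drop=True)
    return out[RESULT_COLUMNS]


def dist(
    zscores: pd.DataFrame,
    panel: ReferencePanel,
    population: str,
    region: tuple[str, int, int],
    **options,
) -> pd.DataFrame:
    """Single-population imputation: distmix at the vertex of ``population``."""
    pi = MixingProportions.vertex(panel, population)
    return distmix(zscores, panel, pi, region, **options)
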