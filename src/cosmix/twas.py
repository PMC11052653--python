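"""Gene-level joint association tests from GWAS Z-scores and SNP weights.

Each gene carries one or more functional categories (eQTL, coding, UTR, ...)
with per-SNP weights w_c.  Within a category the weighted score
U_c = w_c' z has variance w_c' R w_c under the null (R = cohort LD), giving
a standardized score S_c.  Categories are combined with a generalized
least-squares statistic T = S' Q^+ S, where Q is the correlation matrix of
the category scores and Q^+ its eigenvalue-thresholded pseudoinverse; under
the null T is chi-square with df = rank(Q).  SNPs with weights that were
not measured in the study are first imputed from the measured ones by
conditional-Gaussian prediction, so a gene is testable as long as its
neighborhood contains measured variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateGeneError, SchemaError
from .impute import conditional_impute
from .ld import LDMatrix, MixingProportions, compute_ld
from .panel import ReferencePanel

ANNOTATION_COLUMNS = ["rsid", "gene", "category", "weight"]
_EIG_CUTOFF = 1e-8
_VAR_EPS = 1e-12

RESULT_COLUMNS = ["gene", "n_snps", "n_imputed", "stat", "df", "p", "note"]


def read_annotation(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a ``rsid gene category weight`` TSV.

    ``column_map`` renames alternative headers onto the expected ones,
    e.g. ``{"SNP": "rsid", "feature": "category"}``.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing annotation column(s) {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["weight"] = df["weight"].astype(float)
    if not np.isfinite(df["weight"]).all() or (df["weight"] == 0).any():
        raise SchemaError(f"{path}: weights must be finite and nonzero")
    if df.duplicated(["rsid", "gene", "category"]).any():
        raise SchemaError(f"{path}: duplicate (rsid, gene, category) rows")
    return df


@dataclass
class GeneTestResult:
    """Joint test outcome for one gene."""

    gene: str
    n_snps: int
    n_imputed: int
    scores: dict[str, float]  # standardized per-category score S_c
    stat: float
    df: int
    p: float


def gene_statistic(
    gene: str,
    z: np.ndarray,
    weights: dict[str, np.ndarray],
    R: np.ndarray,
    n_imputed: int = 0,
) -> GeneTestResult:
    """GLS combination of per-category weighted scores for one gene.

    ``z`` and each weight vector are aligned to the rows of ``R``.
    Categories whose weighted variance is numerically zero are dropped; if
    none remain the gene is degenerate and an error is raised.
    """
    z = np.asarray(z, dtype=float)
    R = np.asarray(R, dtype=float)
    cats, W = [], []
    for cat, w in weights.items():
        w = np.asarray(w, dtype=float)
        if w.shape != z.shape:
            raise ValueError(f"weight vector for {cat} misaligned with z")
        if float(w @ R @ w) > _VAR_EPS:
            cats.append(cat)
            W.append(w)
    if not cats:
        raise DegenerateGeneError(
            f"gene {gene}: all weight categories have zero variance under LD"
        )
    W = np.column_stack(W)  # (m, C)
    U = W.T @ z
    V = W.T @ R @ W
    s = 1.0 / np.sqrt(np.diag(V))
    S = U * s
    Q = V * np.outer(s, s)
    vals, vecs = np.linalg.eigh((Q + Q.T) / 2.0)
    keep = vals > _EIG_CUTOFF
    df = int(keep.sum())
    proj = vecs[:, keep].T @ S
    T = float(proj @ (proj / vals[keep]))
    p = float(stats.chi2.sf(T, df))
    return GeneTestResult(
        gene=gene, n_snps=int(z.size), n_imputed=n_imputed,
        scores=dict(zip(cats, S)), stat=T, df=df, p=p,
    )


def jepegmix(
    zscores: pd.DataFrame,
    annot: pd.DataFrame,
    panel: ReferencePanel,
    pi: MixingProportions,
    lam: float = 0.1,
    info_min: float = 0.3,
    flank_bp: int = 250_000,
) -> pd.DataFrame:
    """Gene-level joint tests for a (possibly admixed) cohort.

    For each gene: annotated SNPs are located in the panel by rsid (absent
    ones are dropped); SNPs missing from the study table are imputed from
    measured variants within ``flank_bp`` of the gene span (imputed scores
    are standardized; those with info < ``info_min`` are excluded); the
    ancestry-informed LD over the gene's usable SNPs feeds
    :func:`gene_statistic`.  Per-gene failures are reported in the output
    ``note`` column rather than aborting the run.

    Returns a DataFrame with columns ``gene n_snps n_imputed stat df p note``.
    """
    rsid_idx = panel.rsid_index()
    z_by_idx = dict(zip(zscores["panel_idx"].to_numpy(),
                        zscores["z"].to_numpy(dtype=float)))
    obs_idx_all = np.asarray(sorted(z_by_idx), dtype=int)
    bp = panel.variants["bp"].to_numpy()
    chrom = panel.variants["chr"].to_numpy()

    rows = []
    for gene, gdf in annot.groupby("gene", sort=True):
        snp_idx = {}
        for rsid in gdf["rsid"].unique():
            j = rsid_idx.get(rsid)
            if j is not None:
                snp_idx[rsid] = j
        if not snp_idx:
            rows.append((gene, 0, 0, np.nan, 0, np.nan, "no annotated SNP in panel"))
            continue
        gene_idx = np.asarray(sorted(set(snp_idx.values())), dtype=int)
        measured = [j for j in gene_idx if j in z_by_idx]
        missing = [j for j in gene_idx if j not in z_by_idx]

        z_of = {j: z_by_idx[j] for j in measured}
        n_imputed = 0
        if missing:
            g_chr = chrom[gene_idx[0]]
            span = (bp[gene_idx].min() - flank_bp, bp[gene_idx].max() + flank_bp)
            near = obs_idx_all[
                (chrom[obs_idx_all] == g_chr)
                & (bp[obs_idx_all] >= span[0]) & (bp[obs_idx_all] <= span[1])
            ]
            near = np.asarray([j for j in near if j not in set(missing)], dtype=int)
            if near.size:
                try:
                    sel = np.concatenate([near, np.asarray(missing, dtype=int)])
                    ld_all = compute_ld(panel, pi, variant_idx=sel)
                    pos = {r: i for i, r in enumerate(ld_all.variants["rsid"])}
                    o_i = [pos[panel.variants["rsid"].iat[j]] for j in near
                           if panel.variants["rsid"].iat[j] in pos]
                    miss_kept = [j for j in missing
                                 if panel.variants["rsid"].iat[j] in pos]
                    u_i = [pos[panel.variants["rsid"].iat[j]] for j in miss_kept]
                    if o_i and u_i:
                        z_o = np.array([z_by_idx[j] for j in near
                                        if panel.variants["rsid"].iat[j] in pos])
                        zhat, info = conditional_impute(
                            z_o, ld_all.R[np.ix_(o_i, o_i)],
                            ld_all.R[np.ix_(u_i, o_i)], lam=lam,
                        )
                        info = np.minimum(info, 1.0)
                        for j, zh, inf in zip(miss_kept, zhat, info):
                            if inf >= info_min and inf > 0:
                                z_of[j] = zh / np.sqrt(inf)
                                n_imputed += 1
                except Exception as exc:  # per-gene failures must not abort the run
                    rows.append((gene, 0, 0, np.nan, 0, np.nan,
                                 f"imputation failed: {exc}"))
                    continue

        used_idx = np.asarray(sorted(z_of), dtype=int)
        if used_idx.size == 0:
            rows.append((gene, 0, 0, np.nan, 0, np.nan, "no usable SNP"))
            continue
        try:
            ld = compute_ld(panel, pi, variant_idx=used_idx)
            pos = {r: i for i, r in enumerate(ld.variants["rsid"])}
            kept = [j for j in used_idx if panel.variants["rsid"].iat[j] in pos]
            if not kept:
                rows.append((gene, 0, 0, np.nan, 0, np.nan, "monomorphic under mixture"))
                continue
            z_vec = np.array([z_of[j] for j in kept])
            rsid_of = {panel.variants["rsid"].iat[j]: i for i, j in enumerate(kept)}
            weights = {}
            for cat, cdf in gdf.groupby("category"):
                w = np.zeros(len(kept))
                hit = False
                for rsid, wt in zip(cdf["rsid"], cdf["weight"]):
                    i = rsid_of.get(rsid)
                    if i is not None:
                        w[i] = wt
                        hit = True
                if hit:
                    weights[cat] = w
            res = gene_statistic(gene, z_vec, weights, ld.R, n_imputed=n_imputed)
            rows.append((gene, res.n_snps, res.n_imputed, res.stat, res.df,
                         res.p, ""))
        except DegenerateGeneError as exc:
            rows.append((gene, len(z_of), n_imputed, np.nan, 0, np.nan, str(exc)))
        except Exception as exc:
            rows.append((gene, len(z_of), n_imputed, np.nan, 0, np.nan,
                         f"failed: {exc}"))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def jepeg(
    zscores: pd.DataFrame,
    annot: pd.DataFrame,
    panel: ReferencePanel,
    population: str,
    **options,
) -> pd.DataFrame:
    """Homogeneous-cohort gene tests: jepegmix at a population vertex."""
    pi = MixingProportions.vertex(panel, population)
    return jepegmix(zscores, annot, panel, pi, **options)
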