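"""Ancestry-informed linkage disequilibrium.

For an admixed cohort with mixing proportions pi over the panel populations,
the pooled dosage covariance follows the law of total covariance:

    V = sum_k pi_k V_k  +  sum_k pi_k (mu_k - mu_bar)(mu_k - mu_bar)^T

where V_k and mu_k are population k's sample dosage covariance and mean and
mu_bar = sum_k pi_k mu_k.  Standardizing V yields the mixture LD matrix —
the correlation structure an individual-level pooled cohort would show,
including the between-population term that allele-frequency divergence
contributes.  A naive weighted sum of per-population correlation matrices
(``method="correlation"``) is provided for comparison; it omits that term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CosmixError, PanelError
from .panel import ReferencePanel

_ZERO_VAR_EPS = 1e-12


@dataclass
class MixingProportions:
    """Simplex weights over a panel's populations."""

    populations: list[str]
    weights: np.ndarray
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.populations),):
            raise CosmixError("one weight per population required")
        if (w < -1e-9).any():
            raise CosmixError(f"negative mixing proportions: {w}")
        if abs(w.sum() - 1.0) > 1e-6:
            raise CosmixError(f"mixing proportions sum to {w.sum():.8f}, not 1")
        self.weights = np.clip(w, 0.0, None)

    @classmethod
    def vertex(cls, panel: ReferencePanel, population: str) -> "MixingProportions":
        if population not in panel.populations:
            raise CosmixError(
                f"unknown population {population!r}; available: {panel.populations}"
            )
        w = np.zeros(len(panel.populations))
        w[panel.populations.index(population)] = 1.0
        return cls(list(panel.populations), w)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel: ReferencePanel) -> "MixingProportions":
        """Align a ``pop prop`` frame to a panel's population order."""
        mapping = dict(zip(df["pop"], df["prop"]))
        unknown = set(mapping) - set(panel.populations)
        if unknown:
            raise CosmixError(f"populations not in panel: {sorted(unknown)}")
        w = np.array([mapping.get(p, 0.0) for p in panel.populations], dtype=float)
        return cls(list(panel.populations), w / w.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pop": self.populations, "prop": self.weights})


@dataclass
class LDMatrix:
    """Correlation matrix over an ordered variant list.

    ``dropped`` lists variants excluded because they are monomorphic under
    the requested mixture.
    """

    variants: pd.DataFrame
    R: np.ndarray
    dropped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        m = len(self.variants)
        if R.shape != (m, m):
            raise CosmixError(f"LD matrix shape {R.shape} does not match {m} variants")
        if m and np.abs(R - R.T).max() > 1e-10:
            raise CosmixError("LD matrix is not symmetric")
        if m and np.abs(np.diag(R) - 1.0).max() > 1e-8:
            raise CosmixError("LD matrix diagonal deviates from 1")
        if m and (np.abs(R) > 1 + 1e-8).any():
            raise CosmixError("LD entries outside [-1, 1]")
        self.R = R


def mixture_covariance(
    panel: ReferencePanel,
    pi: MixingProportions,
    variant_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled dosage covariance and mean under mixing proportions.

    Populations with zero weight are skipped; any population entering the
    mixture must have at least two individuals (sample covariance uses the
    n_k - 1 denominator).
    """
    if pi.populations != panel.populations:
        raise CosmixError("mixing proportions are not aligned to the panel populations")
    idx = np.arange(panel.n_variants) if variant_idx is None else np.asarray(variant_idx)
    m = idx.size
    V = np.zeros((m, m))
    means = []
    active = [(k, p) for k, p in enumerate(panel.populations) if pi.weights[k] > 0]
    for k, pop in active:
        g = panel.genotypes[pop][:, idx].astype(float)
        if g.shape[0] < 2:
            raise PanelError(
                f"population {pop} has n={g.shape[0]} < 2 but weight {pi.weights[k]:.3g}"
            )
        mu_k = g.mean(axis=0)
        centered = g - mu_k
        V += pi.weights[k] * (centered.T @ centered) / (g.shape[0] - 1)
        means.append((pi.weights[k], mu_k))
    mu_bar = sum(w * mu for w, mu in means)
    for w, mu in means:
        d = mu - mu_bar
        V += w * np.outer(d, d)
    return V, mu_bar


def _standardize(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation from covariance; returns (R_kept, kept_mask)."""
    d = np.diag(V).copy()
    keep = d > _ZERO_VAR_EPS
    Vk = V[np.ix_(keep, keep)]
    s = 1.0 / np.sqrt(d[keep])
    R = Vk * np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return R, keep


def compute_ld(
    panel: ReferencePanel,
    pi: MixingProportions,
    region: tuple[str, int, int] | None = None,
    variant_idx: np.ndarray | None = None,
    method: str = "covariance",
) -> LDMatrix:
    """Ancestry-informed LD matrix for a region (or explicit variant set).

    ``method="covariance"`` (default) mixes at the covariance level and then
    standardizes — this reproduces pooled individual-level correlations.
    ``method="correlation"`` returns the naive weighted sum of per-population
    correlation matrices.  Monomorphic variants under the mixture are
    dropped with a warning and reported in ``LDMatrix.dropped``.
    """
    if region is not None:
        chrom, start, end = region
        idx = panel.region_indices(chrom, start, end)
        if idx.size == 0:
            raise PanelError(f"no panel variants in region {chrom}:{start}-{end}")
    elif variant_idx is not None:
        idx = np.asarray(variant_idx)
    else:
        idx = np.arange(panel.n_variants)

    if method == "covariance":
        V, _ = mixture_covariance(panel, pi, idx)
        R, keep = _standardize(V)
    elif method == "correlation":
        R_sum = np.zeros((idx.size, idx.size))
        keep = np.ones(idx.size, dtype=bool)
        for k, pop in enumerate(panel.populations):
            if pi.weights[k] == 0:
                continue
            V_k, _ = mixture_covariance(
                panel, MixingProportions.vertex(panel, pop), idx
            )
            keep &= np.diag(V_k) > _ZERO_VAR_EPS
        for k, pop in enumerate(panel.populations):
            if pi.weights[k] == 0:
                continue
            V_k, _ = mixture_covariance(
                panel, MixingProportions.vertex(panel, pop), idx
            )
            R_k, _ = _standardize(V_k[np.ix_(keep, keep)])
            R_sum[np.ix_(keep, keep)] += pi.weights[k] * R_k
        R = R_sum[np.ix_(keep, keep)]
        np.fill_diagonal(R, 1.0)
    else:
        raise ValueError(f"unknown LD method: {method}")

    variants = panel.variants.iloc[idx].reset_index(drop=True)
    dropped = variants.loc[~keep].reset_index(drop=True)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} monomorphic variant(s) dropped from LD matrix",
            stacklevel=2,
        )
    kept = variants.loc[keep].reset_index(drop=True)
    return LDMatrix(variants=kept, R=R, dropped=dropped)
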