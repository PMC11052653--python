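"""Synthetic reference panels, admixed cohorts and GWAS Z-scores.

Population allele frequencies follow the Balding–Nichols model: around an
ancestral frequency ``f`` drawn uniformly, population k's frequency is
Beta(f (1-F_k)/F_k, (1-f)(1-F_k)/F_k), so F_k acts as an F_ST-style
differentiation parameter.  Linkage disequilibrium is induced by a
Gaussian-threshold copula: within a block, each haplotype is a latent AR(1)
Gaussian series thresholded at the quantile of the population frequency;
two haplotypes sum to the dosage.  Blocks are independent, which gives a
block-diagonal LD truth that downstream windowing logic can rely on.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, NumericalError
from .panel import ReferencePanel

_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def _per_pop(value, n_pops: int, name: str) -> list:
    if np.isscalar(value):
        return [value] * n_pops
    value = list(value)
    if len(value) != n_pops:
        raise ConfigError(f"{name} must be scalar or length n_pops={n_pops}")
    return value


@dataclass
class SyntheticConfig:
    """Generator settings for a synthetic multi-population panel.

    ``fst`` and ``rho`` may be scalars or per-population sequences; distinct
    per-population ``rho`` values produce populations with distinct LD,
    which ancestry-from-LD estimation needs to be identifiable.
    """

    n_pops: int = 2
    n_per_pop: int | Sequence[int] = 200
    m_variants: int = 500
    fst: float | Sequence[float] = 0.1
    rho: float | Sequence[float] = 0.8
    block_size: int = 50
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    chrom: str = "1"
    bp_start: int = 1
    bp_spacing: int = 1000
    pop_labels: list[str] = field(default=None)

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.m_variants < 1 or self.block_size < 1:
            raise ConfigError("n_pops, m_variants and block_size must be >= 1")
        self._n_per_pop = [int(n) for n in _per_pop(self.n_per_pop, self.n_pops, "n_per_pop")]
        if min(self._n_per_pop) < 1:
            raise ConfigError("n_per_pop must be >= 1")
        self._fst = [float(f) for f in _per_pop(self.fst, self.n_pops, "fst")]
        if not all(0 < f < 1 for f in self._fst):
            raise ConfigError("fst must lie in (0, 1)")
        self._rho = [float(r) for r in _per_pop(self.rho, self.n_pops, "rho")]
        if not all(abs(r) < 1 for r in self._rho):
            raise ConfigError("|rho| must be < 1")
        lo, hi = self.ancestral_af_range
        if not (0.01 <= lo < hi <= 0.99):
            raise ConfigError("ancestral_af_range must satisfy 0.01 <= lo < hi <= 0.99")
        if self.pop_labels is None:
            self.pop_labels = [f"POP{i + 1}" for i in range(self.n_pops)]
        elif len(self.pop_labels) != self.n_pops:
            raise ConfigError("pop_labels length must equal n_pops")


def _ar1_normal(rng: np.random.Generator, n_rows: int, block: int, rho: float) -> np.ndarray:
    """(n_rows, block) latent Gaussians with AR(1) correlation rho."""
    eps = rng.standard_normal((n_rows, block))
    x = np.empty_like(eps)
    x[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for t in range(1, block):
        x[:, t] = rho * x[:, t - 1] + scale * eps[:, t]
    return x


def simulate_panel(config: SyntheticConfig) -> ReferencePanel:
    """Draw a reference panel under the Balding–Nichols / AR(1)-copula model."""
    rng = np.random.default_rng(config.seed)
    m = config.m_variants
    lo, hi = config.ancestral_af_range
    f_anc = rng.uniform(lo, hi, size=m)

    genotypes = {}
    for k, pop in enumerate(config.pop_labels):
        F = config._fst[k]
        a = f_anc * (1 - F) / F
        b = (1 - f_anc) * (1 - F) / F
        f_pop = rng.beta(a, b)
        # guard against numerically fixed alleles; panels should stay polymorphic
        f_pop = np.clip(f_pop, 1e-4, 1 - 1e-4)
        thresh = stats.norm.ppf(f_pop)
        n_hap = 2 * config._n_per_pop[k]
        hap_cols = []
        for start in range(0, m, config.block_size):
            block = min(config.block_size, m - start)
            x = _ar1_normal(rng, n_hap, block, config._rho[k])
            hap_cols.append(x < thresh[start:start + block])
        haps = np.hstack(hap_cols).astype(np.int8)
        genotypes[pop] = haps[0::2] + haps[1::2]

    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(m)]
    variants = pd.DataFrame(
        {
            "rsid": [f"rs{j + 1}" for j in range(m)],
            "chr": config.chrom,
            "bp": config.bp_start + config.bp_spacing * np.arange(m),
            "a1": [a for a, _ in alleles],
            "a2": [b for _, b in alleles],
        }
    )
    return ReferencePanel(variants=variants, populations=list(config.pop_labels),
                          genotypes=genotypes)


def simulate_admixed_cohort(
    panel: ReferencePanel,
    weights: Sequence[float],
    n: int,
    seed: int = 0,
    return_composition: bool = False,
) -> tuple[np.ndarray, pd.DataFrame] | tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Resample an admixed cohort of ``n`` individuals from panel rows.

    Each individual's source population is drawn from ``weights`` (aligned
    to ``panel.populations``); the genotype row is resampled with
    replacement from that population (global-ancestry admixture).

    Returns the (n, m) dosage matrix and the cohort allele-frequency table
    (``rsid chr bp a1 a2 af1``).  With ``return_composition=True`` a third
    element gives the cohort's realized ancestry fractions — the actual
    share of individuals drawn from each population, which fluctuates
    around ``weights`` by ~sqrt(w(1-w)/n) and is the generating truth an
    ancestry estimator sees in the cohort's allele frequencies.
    """
    if n < 1:
        raise ConfigError("cohort size n must be >= 1")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(panel.populations),) or (w < 0).any() or abs(w.sum() - 1) > 1e-6:
        raise ConfigError("weights must be a simplex vector over panel populations")
    rng = np.random.default_rng(seed)
    src = rng.choice(len(panel.populations), size=n, p=w / w.sum())
    dosage = np.empty((n, panel.n_variants), dtype=np.int8)
    for k, pop in enumerate(panel.populations):
        sel = np.flatnonzero(src == k)
        if sel.size:
            rows = rng.integers(0, panel.genotypes[pop].shape[0], size=sel.size)
            dosage[sel] = panel.genotypes[pop][rows]
    af = panel.variants.copy()
    af["af1"] = dosage.mean(axis=0) / 2.0
    if return_composition:
        realized = np.bincount(src, minlength=len(panel.populations)) / n
        return dosage, af, realized
    return dosage, af


def _symmetric_sqrt(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-8:
        raise NumericalError(
            f"LD matrix is not PSD (min eigenvalue {vals.min():.3g}); "
            "add a ridge before simulating"
        )
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def simulate_gwas_z(
    R: np.ndarray,
    noncentrality: np.ndarray | None = None,
    seed: int = 0,
    n_draws: int = 1,
) -> np.ndarray:
    """Draw GWAS Z-scores ``z ~ N(R mu, R)`` via the symmetric square root.

    ``noncentrality`` is the vector of per-variant noncentralities mu
    (None = the global null).  Returns an (n_draws, m) array.
    """
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    mean = np.zeros(m) if noncentrality is None else R @ np.asarray(noncentrality, float)
    S = _symmetric_sqrt(R)
    rng = np.random.default_rng(seed)
    return mean + rng.standard_normal((n_draws, m)) @ S.T


def zscore_table(panel: ReferencePanel | pd.DataFrame, z: np.ndarray,
                 idx: np.ndarray | None = None) -> pd.DataFrame:
    """Wrap a Z vector over panel variants as an ``rsid chr bp a1 a2 z`` table.

    The first argument may be a panel or a bare variant DataFrame (e.g.
    ``LDMatrix.variants``); ``idx`` optionally selects a subset of rows.
    """
    source = panel.variants if isinstance(panel, ReferencePanel) else panel
    variants = source if idx is None else source.iloc[idx]
    out = variants.copy().reset_index(drop=True)
    out["z"] = np.asarray(z, dtype=float)
    return out
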