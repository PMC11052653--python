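"""Multi-population reference panels.

A panel stores, for each population, an ``n_k x m`` matrix of a1-allele
dosages over a shared, ordered variant list.  Dosages count copies of ``a1``
(the panel reference allele); every downstream correlation and Z-score sign
convention is anchored to that orientation.

Two on-disk representations are supported: a plain-text VCF (genotypes read
with cyvcf2, ``a1 := REF``, ``a2 := ALT``) and a native cache directory —
one variant TSV, one population TSV, and one gzipped dosage matrix per
population.
"""

from __future__ import annotations

import gzip
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import PanelError, SchemaError

VARIANT_COLUMNS = ["rsid", "chr", "bp", "a1", "a2"]
_VALID_BASES = frozenset("ACGT")
_VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])


def _normalize_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a variant table (rsid, chr, bp, a1, a2)."""
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise SchemaError(f"variant table missing columns: {missing}")
    v = variants[VARIANT_COLUMNS].copy()
    v["chr"] = v["chr"].map(_normalize_chrom)
    bad_chr = ~v["chr"].isin(_VALID_CHROMS)
    if bad_chr.any():
        raise SchemaError(
            f"invalid chromosome labels: {sorted(v.loc[bad_chr, 'chr'].unique())}"
        )
    v["bp"] = v["bp"].astype(np.int64)
    if (v["bp"] < 1).any():
        raise SchemaError("bp positions must be >= 1 (1-based coordinates)")
    for col in ("a1", "a2"):
        v[col] = v[col].astype(str).str.upper()
        bad = ~v[col].isin(_VALID_BASES)
        if bad.any():
            raise SchemaError(f"non-SNV alleles in column {col} (biallelic SNVs only)")
    if (v["a1"] == v["a2"]).any():
        raise SchemaError("a1 == a2 for some variants")
    key = list(zip(v["chr"], v["bp"], map(frozenset, zip(v["a1"], v["a2"]))))
    if len(set(key)) != len(key):
        raise SchemaError("duplicate (chr, bp, {a1,a2}) variant keys in panel")
    return v.reset_index(drop=True)


@dataclass
class ReferencePanel:
    """Per-population dosage matrices over a shared variant index.

    Parameters
    ----------
    variants
        DataFrame with columns ``rsid chr bp a1 a2``, one row per variant,
        in genomic order of the source.
    populations
        Ordered population labels.
    genotypes
        Mapping label -> (n_k, m) integer dosage matrix with entries in
        {0, 1, 2} counting copies of a1.
    """

    variants: pd.DataFrame
    populations: list[str]
    genotypes: dict[str, np.ndarray]
    _pos_index: dict[tuple[str, int], int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.variants = validate_variants(self.variants)
        m = len(self.variants)
        if m == 0:
            raise PanelError("empty panel: no variants")
        if not self.populations:
            raise PanelError("empty panel: no populations")
        for pop in self.populations:
            g = np.asarray(self.genotypes[pop])
            if g.ndim != 2 or g.shape[1] != m:
                raise PanelError(
                    f"population {pop}: genotype matrix shape {g.shape} "
                    f"does not match {m} variants"
                )
            if g.shape[0] < 1:
                raise PanelError(f"population {pop}: no individuals")
            if not np.isin(g, (0, 1, 2)).all():
                raise PanelError(f"population {pop}: dosages outside {{0,1,2}}")
            self.genotypes[pop] = g.astype(np.int8)
        self._pos_index = None

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> dict[str, int]:
        return {pop: self.genotypes[pop].shape[0] for pop in self.populations}

    def position_index(self) -> dict[tuple[str, int], int]:
        """Map (chr, bp) -> column index; positions are unique per panel."""
        if self._pos_index is None:
            self._pos_index = {
                (c, int(b)): i
                for i, (c, b) in enumerate(zip(self.variants["chr"], self.variants["bp"]))
            }
        return self._pos_index

    def rsid_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.variants["rsid"])}

    def region_indices(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Column indices of variants inside a 1-based inclusive region."""
        chrom = _normalize_chrom(chrom)
        mask = (
            (self.variants["chr"] == chrom)
            & (self.variants["bp"] >= start_bp)
            & (self.variants["bp"] <= end_bp)
        )
        return np.flatnonzero(mask.to_numpy())

    def subset(self, idx: np.ndarray) -> "ReferencePanel":
        idx = np.asarray(idx)
        return ReferencePanel(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            populations=list(self.populations),
            genotypes={p: self.genotypes[p][:, idx] for p in self.populations},
        )


@dataclass
class PopulationAF:
    """Per-population a1 allele frequencies, aligned to a panel's variants."""

    populations: list[str]
    variants: pd.DataFrame
    freqs: np.ndarray  # (K, m), freqs[k, j] = f_kj in [0, 1]

    def mixture_af(self, weights: np.ndarray) -> np.ndarray:
        """Pooled a1 frequency under mixing weights (length K, simplex)."""
        return np.asarray(weights) @ self.freqs


def population_allele_frequencies(panel: ReferencePanel) -> PopulationAF:
    """a1 frequency per population: column dosage sum over 2 n_k."""
    freqs = np.vstack(
        [panel.genotypes[p].sum(axis=0) / (2.0 * panel.genotypes[p].shape[0])
         for p in panel.populations]
    )
    return PopulationAF(
        populations=list(panel.populations),
        variants=panel.variants,
        freqs=freqs,
    )


# ---------------------------------------------------------------------------
# VCF ingestion / export
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Two-column ``sample pop`` TSV mapping sample ids to population labels."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if list(df.columns[:2]) != ["sample", "pop"]:
        raise SchemaError(
            f"sample map must have header 'sample pop', got {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        raise SchemaError("duplicate sample ids in sample map")
    return df


def read_panel_vcf(
    vcf_path: str | Path,
    sample_map: str | Path | pd.DataFrame,
    region: tuple[str, int, int] | None = None,
    unmapped_samples: str = "drop",
) -> ReferencePanel:
    """Load biallelic SNVs from a VCF into a :class:`ReferencePanel`.

    ``a1 := REF`` and ``a2 := ALT``; dosage counts REF copies, i.e.
    ``2 - (# ALT alleles)``.  Variants with any missing genotype, indel or
    multiallelic records, and records outside ``region`` are skipped.

    Parameters
    ----------
    unmapped_samples
        ``"drop"`` silently excludes VCF samples absent from the map;
        ``"error"`` raises.
    """
    from cyvcf2 import VCF

    if not isinstance(sample_map, pd.DataFrame):
        sample_map = read_sample_map(sample_map)
    pop_of = dict(zip(sample_map["sample"], sample_map["pop"]))

    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise PanelError(f"cannot read VCF {vcf_path}: {exc}") from None

    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in pop_of]
    if unmapped and unmapped_samples == "error":
        raise PanelError(f"VCF samples absent from sample map: {unmapped}")
    keep_cols = np.array([i for i, s in enumerate(samples) if s in pop_of])
    if keep_cols.size == 0:
        raise PanelError("no VCF sample maps to a population")
    kept_samples = [samples[i] for i in keep_cols]
    # populations ordered by first appearance in the map file
    populations = list(dict.fromkeys(sample_map["pop"]))
    populations = [p for p in populations if p in {pop_of[s] for s in kept_samples}]

    if region is not None:
        chrom, start, end = region
        chrom = _normalize_chrom(chrom)

    rows, dosage_rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
            continue
        c = _normalize_chrom(rec.CHROM)
        if region is not None and not (c == chrom and start <= rec.POS <= end):
            continue
        gt = rec.gt_types[keep_cols]  # gts012: 0=hom-ref,1=het,2=hom-alt,3=missing
        if (gt == 3).any():
            continue  # default policy: drop variants with missing genotypes
        rows.append((rec.ID or f"{c}:{rec.POS}", c, rec.POS, ref, alt))
        dosage_rows.append(2 - gt)  # REF (=a1) dosage
    if not rows:
        raise PanelError(f"no usable biallelic SNVs in {vcf_path}"
                         + (f" region {region}" if region else ""))

    dosage = np.vstack(dosage_rows).T.astype(np.int8)  # samples x variants
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    genotypes = {}
    for pop in populations:
        sel = np.array([i for i, s in enumerate(kept_samples) if pop_of[s] == pop])
        genotypes[pop] = dosage[sel]
    return ReferencePanel(variants=variants, populations=populations, genotypes=genotypes)


def write_panel_vcf(panel: ReferencePanel, vcf_path: str | Path,
                    sample_map_path: str | Path | None = None) -> None:
    """Write the panel as an uncompressed VCF (GT only) plus a sample map."""
    vcf_path = Path(vcf_path)
    sample_names, sample_pops, columns = [], [], []
    for pop in panel.populations:
        g = panel.genotypes[pop]
        for i in range(g.shape[0]):
            sample_names.append(f"{pop}_{i + 1}")
            sample_pops.append(pop)
        columns.append(g)
    dosage = np.vstack(columns)  # all samples x m, a1 dosage
    gt_strings = np.array(["1/1", "0/1", "0/0"])  # index by a1 dosage
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(panel.variants["chr"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            gts = "\t".join(gt_strings[dosage[:, j]])
            fh.write(f"{row.chr}\t{row.bp}\t{row.rsid}\t{row.a1}\t{row.a2}"
                     f"\t.\t.\t.\tGT\t{gts}\n")
    if sample_map_path is not None:
        pd.DataFrame({"sample": sample_names, "pop": sample_pops}).to_csv(
            sample_map_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Native cache
# ---------------------------------------------------------------------------

def write_panel(panel: ReferencePanel, directory: str | Path) -> None:
    """Write the native cache: variants.tsv, populations.tsv, dosage gzips.

    Gzip members are written with mtime=0 so identical panels produce
    byte-identical caches.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel.variants.to_csv(directory / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"pop": panel.populations,
         "n": [panel.genotypes[p].shape[0] for p in panel.populations]}
    ).to_csv(directory / "populations.tsv", sep="\t", index=False)
    for pop in panel.populations:
        buf = io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
            np.savetxt(gz, panel.genotypes[pop], fmt="%d", delimiter="\t")
        (directory / f"dosage.{pop}.tsv.gz").write_bytes(buf.getvalue())


def read_panel(directory: str | Path) -> ReferencePanel:
    """Read a native cache directory written by :func:`write_panel`."""
    directory = Path(directory)
    if not (directory / "variants.tsv").exists():
        raise PanelError(f"{directory} is not a panel cache (variants.tsv missing)")
    variants = pd.read_csv(directory / "variants.tsv", sep="\t", dtype={"chr": str})
    pops = pd.read_csv(directory / "populations.tsv", sep="\t", dtype={"pop": str})
    genotypes = {}
    for pop, n in zip(pops["pop"], pops["n"]):
        g = np.loadtxt(directory / f"dosage.{pop}.tsv.gz", delimiter="\t",
                       dtype=np.int8, ndmin=2)
        if g.shape[0] != n:
            raise PanelError(f"population {pop}: expected {n} rows, found {g.shape[0]}")
        genotypes[pop] = g
    return ReferencePanel(variants=variants, populations=list(pops["pop"]),
                          genotypes=genotypes)


def load_panel(path: str | Path, sample_map: str | Path | None = None,
               region: tuple[str, int, int] | None = None) -> ReferencePanel:
    """Load a panel from a native cache directory or a VCF (+ sample map)."""
    path = Path(path)
    if path.is_dir():
        return read_panel(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        if sample_map is None:
            raise PanelError("loading a VCF panel requires a sample map")
        return read_panel_vcf(path, sample_map, region=region)
    raise PanelError(f"unrecognized panel path: {path}")


def file_checksum(path: str | Path) -> str:
    """md5 of a file's bytes, for run logs."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
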