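"""Summary-statistics tables and panel harmonization.

Z-score tables carry ``rsid chr bp a1 a2 z``; allele-frequency tables carry
``rsid chr bp a1 a2 af1``.  Harmonization matches study rows to panel
variants by (chr, bp) with allele verification, flips signs/frequencies when
the study alleles are swapped relative to the panel, and (by default) drops
strand-ambiguous palindromic SNPs (A/T, C/G), whose orientation cannot be
verified from allele labels alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import HarmonizationError, SchemaError
from .panel import ReferencePanel, _normalize_chrom, population_allele_frequencies

ZSCORE_COLUMNS = ["rsid", "chr", "bp", "a1", "a2", "z"]
AF_COLUMNS = ["rsid", "chr", "bp", "a1", "a2", "af1"]
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class HarmonizationReport:
    """Row accounting for one alignment pass."""

    n_input: int = 0
    n_matched: int = 0
    n_sign_flipped: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_unmatched: int = 0

    def __post_init__(self) -> None:
        assert self.n_matched + self.n_dropped_ambiguous + self.n_dropped_unmatched \
            == self.n_input


def _read_table(path: str | Path, value_col: str, columns: list[str],
                drop_na: bool = False, keep_extra: bool = False) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=["NA"])
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if not keep_extra:
        df = df[columns]
    df = df.copy()
    df["chr"] = df["chr"].map(_normalize_chrom)
    for col, kind in (("bp", np.int64), (value_col, float)):
        try:
            df[col] = df[col].astype(kind)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header +1 1-based
            raise SchemaError(
                f"{path}: non-numeric {col!r} value on line {line}"
            ) from None
    for col in ("a1", "a2"):
        df[col] = df[col].str.upper()
    finite = np.isfinite(df[value_col].to_numpy())
    if not finite.all():
        if drop_na:
            df = df.loc[finite].reset_index(drop=True)
        else:
            line = int(np.flatnonzero(~finite)[0]) + 2
            raise SchemaError(f"{path}: non-finite {value_col} on line {line}")
    return df


def read_zscore_table(path: str | Path, drop_na: bool = False,
                      keep_extra: bool = False) -> pd.DataFrame:
    """Read a whitespace/tab-delimited ``rsid chr bp a1 a2 z`` table.

    ``drop_na`` silently drops rows with missing/non-finite z (useful when
    consuming imputation output containing skipped variants); ``keep_extra``
    retains any additional columns after the required six.
    """
    return _read_table(path, "z", ZSCORE_COLUMNS, drop_na=drop_na,
                       keep_extra=keep_extra)


def read_af_table(path: str | Path) -> pd.DataFrame:
    """Read a ``rsid chr bp a1 a2 af1`` table; af1 must lie in [0, 1]."""
    df = _read_table(path, "af1", AF_COLUMNS)
    bad = (df["af1"] < 0) | (df["af1"] > 1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(f"{path}: af1 outside [0, 1] on line {line}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mixing_proportions(path: str | Path) -> pd.DataFrame:
    """Read a ``pop prop`` TSV of population mixing proportions."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"pop": str})
    missing = [c for c in ("pop", "prop") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df["prop"] = df["prop"].astype(float)
    return df[["pop", "prop"]]


def align_to_panel(
    table: pd.DataFrame,
    panel: ReferencePanel,
    policy: str = "drop",
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Harmonize a Z-score or AF table against a reference panel.

    Rows are matched by (chr, bp).  A row whose alleles equal the panel's
    (a1, a2) is kept; one equal to (a2, a1) is flipped (``z := -z`` or
    ``af1 := 1 - af1``) and counted; other allele pairs are dropped as
    unmatched.  Palindromic SNPs are handled per ``policy``:

    - ``"drop"`` (default): always dropped (orientation unverifiable).
    - ``"keep"``: kept on exact/swapped allele match; for AF tables the
      orientation is chosen by whichever of af1 / 1-af1 is closer to the
      panel mixture frequency.

    Returns the aligned table (panel orientation, with a ``panel_idx``
    column) and a :class:`HarmonizationReport`.
    """
    if policy not in {"drop", "keep"}:
        raise ValueError(f"unknown ambiguity policy: {policy}")
    value_col = "z" if "z" in table.columns else "af1"
    n_input = len(table)

    pos = panel.position_index()
    chrs = table["chr"].map(_normalize_chrom).to_numpy()
    bps = table["bp"].to_numpy()
    idx = np.array([pos.get((c, int(b)), -1) for c, b in zip(chrs, bps)])

    matched = idx >= 0
    sub = table.loc[matched].copy()
    sub["panel_idx"] = idx[matched]
    pv = panel.variants
    p_a1 = pv["a1"].to_numpy()[sub["panel_idx"]]
    p_a2 = pv["a2"].to_numpy()[sub["panel_idx"]]
    s_a1 = sub["a1"].to_numpy()
    s_a2 = sub["a2"].to_numpy()

    same = (s_a1 == p_a1) & (s_a2 == p_a2)
    swapped = (s_a1 == p_a2) & (s_a2 == p_a1)
    palin = np.array([(x, y) in _PALINDROMIC for x, y in zip(s_a1, s_a2)],
                     dtype=bool)

    keep = (same | swapped) & ~palin
    flip = swapped & ~palin
    n_ambiguous = 0
    if policy == "drop":
        n_ambiguous = int((palin & (same | swapped)).sum())
    else:
        palin_ok = palin & (same | swapped)
        if value_col == "af1" and palin_ok.any():
            mix_af = population_allele_frequencies(panel).freqs.mean(axis=0)
            f_panel = mix_af[sub["panel_idx"].to_numpy()[palin_ok]]
            af = sub[value_col].to_numpy()[palin_ok]
            flip_palin = np.abs(af - f_panel) > np.abs((1 - af) - f_panel)
            flip_idx = np.flatnonzero(palin_ok)
            flip[flip_idx[flip_palin]] = True
        else:
            flip |= palin & swapped
        keep |= palin_ok

    n_unmatched = int((~matched).sum()) + int((~(same | swapped)).sum()) + n_ambiguous * 0
    aligned = sub.loc[keep].copy()
    fl = flip[keep]
    if value_col == "z":
        aligned.loc[fl, "z"] = -aligned.loc[fl, "z"]
    else:
        aligned.loc[fl, "af1"] = 1.0 - aligned.loc[fl, "af1"]
    aligned["a1"] = pv["a1"].to_numpy()[aligned["panel_idx"]]
    aligned["a2"] = pv["a2"].to_numpy()[aligned["panel_idx"]]
    aligned["rsid"] = pv["rsid"].to_numpy()[aligned["panel_idx"]]

    dup = aligned["panel_idx"].duplicated(keep=False)
    if dup.any():
        keys = aligned.loc[dup, ["chr", "bp"]].drop_duplicates()
        raise HarmonizationError(
            "duplicate study rows map to one panel variant at: "
            + ", ".join(f"{c}:{b}" for c, b in zip(keys["chr"], keys["bp"]))
        )

    report = HarmonizationReport(
        n_input=n_input,
        n_matched=len(aligned),
        n_sign_flipped=int(fl.sum()),
        n_dropped_ambiguous=n_ambiguous,
        n_dropped_unmatched=n_input - len(aligned) - n_ambiguous,
    )
    return aligned.reset_index(drop=True), report
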