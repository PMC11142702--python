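"""Reading, validating and writing GWAS summary statistics and LD matrices.

The canonical on-disk format is a GWAS-SSF-style tab-separated table with
columns ``variant_id, chromosome, base_pair_location, effect_allele,
other_allele, effect_allele_frequency, beta, standard_error, p_value, n``
(plus optional ``n_case``/``n_control`` for case-control traits). Other
dialects are mapped onto this schema through an explicit ``column_map``
rather than per-consortium parsers.

Positions are 1-based; all windows elsewhere in the package are inclusive
closed intervals on these coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit.io")

VALID_ALLELES = frozenset("ACGT")

#: internal column name -> GWAS-SSF file column name
SSF_COLUMNS: dict[str, str] = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "p": "p_value",
    "n": "n",
}

REQUIRED_FIELDS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p",
    "n",
)

OPTIONAL_FIELDS = ("eaf", "n_case", "n_control")

#: smallest positive value a reported p of exactly 0 is clamped to
MIN_P = float(np.nextafter(0.0, 1.0))


@dataclass
class SummaryStatSet:
    """Per-variant GWAS association records for one trait in one ancestry.

    ``table`` holds one row per variant with the internal schema columns;
    ``variant_id`` values are unique. ``beta`` is the per-allele effect of
    the effect allele (a log odds ratio when ``binary_trait`` is set).
    """

    trait_label: str
    ancestry_label: str
    table: pd.DataFrame
    binary_trait: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.ancestry_label:
            raise ValueError("ancestry_label must be nonempty")
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant_id values: {sorted(set(dups))[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.table["variant_id"])

    def row(self, variant_id: str) -> pd.Series:
        hit = self.table[self.table["variant_id"] == variant_id]
        if hit.empty:
            raise KeyError(variant_id)
        return hit.iloc[0]

    def subset(self, variant_ids) -> "SummaryStatSet":
        keep = self.table[self.table["variant_id"].isin(set(variant_ids))]
        return SummaryStatSet(
            trait_label=self.trait_label,
            ancestry_label=self.ancestry_label,
            table=keep.copy(),
            binary_trait=self.binary_trait,
        )


@dataclass
class LDMatrix:
    """Signed pairwise correlations (r, not r²) between variants.

    Symmetric with unit diagonal; typically derived from an external
    reference panel such as 1000 Genomes and supplied as a TSV.
    """

    variant_ids: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {n} variant ids")
        if np.abs(self.r - self.r.T).max(initial=0.0) > 1e-8:
            raise ValueError("LD matrix is not symmetric within 1e-8")
        self.r = (self.r + self.r.T) / 2.0
        if n and np.abs(np.diag(self.r) - 1.0).max() > 1e-8:
            raise ValueError("LD matrix diagonal must be 1")
        if n and (np.abs(self.r) > 1.0 + 1e-8).any():
            raise ValueError("LD correlations must lie in [-1, 1]")
        np.clip(self.r, -1.0, 1.0, out=self.r)
        np.fill_diagonal(self.r, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate variant ids in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def submatrix(self, variant_ids) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Split rows into retained (all invariants hold) and dropped.

    Retained + dropped always equals the input row count.
    """
    n_in = len(df)
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = (
        ea.isin(VALID_ALLELES)
        & oa.isin(VALID_ALLELES)
        & (ea != oa)
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & (df["position"] >= 1)
        & (df["n"] > 0)
        & df["beta"].notna()
        & df["variant_id"].notna()
    )
    if "eaf" in df.columns:
        ok &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    out = df[ok].copy()
    out["effect_allele"] = ea[ok]
    out["other_allele"] = oa[ok]
    return out, n_in - len(out)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    binary_trait: bool = False,
    trait_label: str = "",
    ancestry_label: str = "NA",
    sep: str = "\t",
) -> SummaryStatSet:
    """Read a delimited summary-statistics file into a validated set.

    ``column_map`` maps internal field names (``variant_id``, ``chromosome``,
    ``position``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
    ``se``, ``p``, ``n``, ``n_case``, ``n_control``) to the file's column
    names; unmapped fields fall back to the GWAS-SSF names. Rows violating
    validation are dropped with a logged count; a p-value of exactly 0 is
    clamped to the smallest positive float with a warning.

    Raises
    ------
    KeyError
        If a required column is missing (the message names it).
    ValueError
        If no valid rows remain.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype={0: str}, comment="#", float_precision="round_trip")
    resolved = dict(SSF_COLUMNS)
    resolved.setdefault("n_case", "n_case")
    resolved.setdefault("n_control", "n_control")
    if column_map:
        resolved.update(column_map)

    data: dict[str, pd.Series] = {}
    for internal in REQUIRED_FIELDS:
        col = resolved[internal]
        if col not in raw.columns:
            raise KeyError(f"required column '{col}' (field '{internal}') missing from {path.name}")
        data[internal] = raw[col]
    for internal in OPTIONAL_FIELDS:
        col = resolved.get(internal)
        if col is not None and col in raw.columns:
            data[internal] = raw[col]

    df = pd.DataFrame(data)
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    for c in ("position", "beta", "se", "p", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in OPTIONAL_FIELDS:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")

    n_zero_p = int((df["p"] == 0).sum())
    if n_zero_p:
        logger.warning("%s: clamped %d p-value(s) of 0 to %.3g", path.name, n_zero_p, MIN_P)
        df.loc[df["p"] == 0, "p"] = MIN_P

    df, n_dropped = _validate_rows(df)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s), retained %d", path.name, n_dropped, len(df))
    if df.empty:
        raise ValueError(f"{path}: no valid summary-statistic rows after validation")
    df["position"] = df["position"].astype(int)
    order = [c for c in (*SSF_COLUMNS, "n_case", "n_control") if c in df.columns]
    df = df[order]

    return SummaryStatSet(
        trait_label=trait_label or path.stem,
        ancestry_label=ancestry_label,
        table=df,
        binary_trait=binary_trait,
        n_dropped=n_dropped,
    )


def write_summary_stats(stats: SummaryStatSet, path: str | Path) -> Path:
    """Write a set as GWAS-SSF-style TSV; round-trips through read_summary_stats.

    Optional columns that are entirely absent are omitted from the file.
    """
    if len(stats) == 0:
        raise ValueError("refusing to write an empty SummaryStatSet")
    path = Path(path)
    out = pd.DataFrame()
    for internal, col in SSF_COLUMNS.items():
        if internal == "eaf" and ("eaf" not in stats.table or stats.table["eaf"].isna().all()):
            continue
        out[col] = stats.table[internal]
    for internal in ("n_case", "n_control"):
        if internal in stats.table and not stats.table[internal].isna().all():
            out[internal] = stats.table[internal]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD correlation matrix from TSV with variant-id header and row labels.

    The matrix must be square with entries in [-1, 1] and unit diagonal;
    asymmetry within 1e-8 is silently symmetrized, anything larger is an
    error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    if list(map(str, df.index)) != ids:
        raise ValueError(f"{path}: LD matrix row labels do not match column labels")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> Path:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")
    return Path(path)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G pairs cannot be strand-resolved from alleles alone."""
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    return COMPLEMENT[allele]


def clamp_p(p: float) -> float:
    """Clamp an underflowed p-value to the smallest positive float."""
    return MIN_P if p <= 0 else min(float(p), 1.0)


def zscore_p(z: float) -> float:
    """Two-sided normal p-value, clamped away from exact zero."""
    from scipy.stats import norm

    if not math.isfinite(z):
        return MIN_P
    return clamp_p(2.0 * norm.sf(abs(z)))
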