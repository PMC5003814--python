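"""Read, validate, filter, and merge protein-group tables.

The on-disk dialect is the MaxQuant ``proteinGroups.txt`` layout: one row
per protein group keyed by the lead protein identifier, tab-separated,
with per-channel intensities (``Intensity H/M/L``), optional evidence-
weighted SILAC ratio columns (``Ratio M/H`` etc.), razor + unique peptide
counts, and ``+``-flagged reverse / potential-contaminant columns.
In-memory tables use a canonical column layout shared with the synthetic
generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PAIRS

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "protein",
    "gene",
    "unique_peptides",
    "intensity_H",
    "intensity_M",
    "intensity_L",
    "ratio_MH",
    "ratio_LM",
    "ratio_LH",
    "reverse",
    "contaminant",
]

_MAXQUANT_MAP = {
    "protein": "Protein IDs",
    "gene": "Gene names",
    "unique_peptides": "Razor + unique peptides",
    "intensity_H": "Intensity H",
    "intensity_M": "Intensity M",
    "intensity_L": "Intensity L",
    "ratio_MH": "Ratio M/H",
    "ratio_LM": "Ratio L/M",
    "ratio_LH": "Ratio L/H",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}

_MANDATORY = ["protein", "unique_peptides", "intensity_H", "intensity_M", "intensity_L"]


class FormatError(ValueError):
    """Raised when an input table does not conform to the expected dialect."""


def read_protein_groups(path, dialect: str = "maxquant") -> pd.DataFrame:
    """Parse a protein-groups TSV into the canonical table layout.

    Missing numeric cells are preserved as NaN, never as 0. Reverse and
    contaminant rows are retained on read; removal is the job of
    :func:`filter_quantifiable`. When ratio columns are absent, linear
    SILAC ratios are derived from the channel intensities (MaxQuant's own
    evidence-weighted ratios take precedence when present).
    """
    if dialect != "maxquant":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canon in _MANDATORY:
        if _MAXQUANT_MAP[canon] not in raw.columns:
            raise FormatError(
                f"{path}: missing mandatory column {_MAXQUANT_MAP[canon]!r}"
            )

    out = pd.DataFrame()
    out["protein"] = raw[_MAXQUANT_MAP["protein"]].str.split(";").str[0]
    gene_col = _MAXQUANT_MAP["gene"]
    out["gene"] = raw[gene_col] if gene_col in raw.columns else ""

    def numeric(canon: str, integer: bool = False) -> pd.Series:
        col = _MAXQUANT_MAP[canon]
        text = raw[col].str.strip()
        vals = pd.to_numeric(text.where(text != ""), errors="coerce")
        bad = vals.isna() & (text != "") & (text.str.lower() != "nan")
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after the header line
            raise FormatError(
                f"{path}: unparseable value {text[bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        if integer:
            vals = vals.fillna(0).astype(int)
        return vals

    out["unique_peptides"] = numeric("unique_peptides", integer=True)
    for ch in "HML":
        out[f"intensity_{ch}"] = numeric(f"intensity_{ch}")

    have_ratios = all(_MAXQUANT_MAP[f"ratio_{p}"] in raw.columns for p in PAIRS)
    if have_ratios:
        for p in PAIRS:
            out[f"ratio_{p}"] = numeric(f"ratio_{p}")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            h = out["intensity_H"].to_numpy(float)
            m = out["intensity_M"].to_numpy(float)
            l = out["intensity_L"].to_numpy(float)
            out["ratio_MH"] = _safe_div(m, h)
            out["ratio_LM"] = _safe_div(l, m)
            out["ratio_LH"] = _safe_div(l, h)

    for canon in ("reverse", "contaminant"):
        col = _MAXQUANT_MAP[canon]
        out[canon] = (
            raw[col].str.strip().eq("+") if col in raw.columns else False
        )
    return out[CANONICAL_COLUMNS]


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    res = np.divide(num, den, out=np.full_like(num, np.nan), where=den > 0)
    res[~np.isfinite(res)] = np.nan
    return res


def write_protein_groups(table: pd.DataFrame, path) -> None:
    """Render a canonical table as MaxQuant-dialect TSV (inverse of read)."""
    out = pd.DataFrame()
    for canon, col in _MAXQUANT_MAP.items():
        if canon in ("reverse", "contaminant"):
            out[col] = np.where(table[canon].to_numpy(bool), "+", "")
        else:
            out[col] = table[canon]
    out.to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    """Counts of proteins removed per quantifiability criterion."""

    n_input: int = 0
    removed_reverse: int = 0
    removed_contaminant: int = 0
    removed_missing_replicate: int = 0
    removed_low_peptides: int = 0
    retained: int = 0

    def to_text(self) -> str:
        return (
            f"input protein groups (union): {self.n_input}\n"
            f"removed reverse hits: {self.removed_reverse}\n"
            f"removed contaminants: {self.removed_contaminant}\n"
            f"removed absent from required replicates: {self.removed_missing_replicate}\n"
            f"removed below peptide threshold: {self.removed_low_peptides}\n"
            f"retained quantifiable: {self.retained}\n"
        )


def filter_quantifiable(
    tables: list[pd.DataFrame],
    min_unique: int = 2,
    require_all_replicates: bool = True,
) -> tuple[list[pd.DataFrame], FilterReport]:
    """Apply the quantifiability filter across replicates.

    A protein group is quantifiable when it carries at least
    ``min_unique`` sequence-unique peptides in *each* replicate (or in at
    least one replicate when ``require_all_replicates`` is False), and is
    neither a reverse hit nor a contaminant in any replicate.
    """
    if not tables:
        raise ValueError("at least one table is required")
    report = FilterReport()

    flagged_rev: set[str] = set()
    flagged_con: set[str] = set()
    peptides: dict[str, list[int]] = {}
    presence: dict[str, int] = {}
    for table in tables:
        for pid, pep, rev, con in zip(
            table["protein"], table["unique_peptides"], table["reverse"],
            table["contaminant"],
        ):
            if rev:
                flagged_rev.add(pid)
            if con:
                flagged_con.add(pid)
            peptides.setdefault(pid, []).append(int(pep))
            presence[pid] = presence.get(pid, 0) + 1

    report.n_input = len(presence)
    report.removed_reverse = len(flagged_rev)
    report.removed_contaminant = len(flagged_con - flagged_rev)

    keep: set[str] = set()
    for pid, counts in peptides.items():
        if pid in flagged_rev or pid in flagged_con:
            continue
        if require_all_replicates:
            if presence[pid] < len(tables):
                report.removed_missing_replicate += 1
                continue
            ok = all(c >= min_unique for c in counts)
        else:
            ok = any(c >= min_unique for c in counts)
        if ok:
            keep.add(pid)
        else:
            report.removed_low_peptides += 1

    report.retained = len(keep)
    if not keep:
        logger.warning("quantifiability filter retained no proteins")
    filtered = [t[t["protein"].isin(keep)].reset_index(drop=True) for t in tables]
    return filtered, report


@dataclass
class VennCounts:
    """Region counts of the replicate-identification Venn diagram.

    ``regions`` maps a membership pattern string (e.g. ``"110"`` = present
    in replicates 1 and 2 only) to the number of protein ids in that
    exclusive region.
    """

    regions: dict[str, int]
    n_replicates: int

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def in_at_least(self, m: int) -> int:
        return sum(
            c for patt, c in self.regions.items() if patt.count("1") >= m
        )

    @property
    def in_all(self) -> int:
        return self.in_at_least(self.n_replicates)


def replicate_overlap(tables: list) -> VennCounts:
    """Exclusive Venn-region counts of protein ids across replicates.

    Accepts canonical tables or plain id collections. Region counts sum to
    the size of the union by construction.
    """
    id_sets = [
        set(t["protein"]) if isinstance(t, pd.DataFrame) else set(t)
        for t in tables
    ]
    n = len(id_sets)
    union = set().union(*id_sets)
    regions = {format(i, f"0{n}b"): 0 for i in range(1, 2**n)}
    for pid in union:
        patt = "".join("1" if pid in s else "0" for s in id_sets)
        regions[patt] += 1
    return VennCounts(regions=regions, n_replicates=n)


@dataclass
class RatioMatrix:
    """Protein x (SILAC pair x replicate) log2-ratio tensor.

    ``log2`` is indexed by protein with a (pair, replicate) column
    MultiIndex; ``ref_intensity`` is the per-protein median over all
    available channel intensities and replicates.
    """

    log2: pd.DataFrame
    ref_intensity: pd.Series
    n_replicates: int
    provenance: list[str] = field(default_factory=list)

    @property
    def proteins(self) -> pd.Index:
        return self.log2.index

    def pair_frame(self, pair: str) -> pd.DataFrame:
        if pair not in PAIRS:
            raise KeyError(f"unknown SILAC pair {pair!r}")
        return self.log2[pair]

    def complete_mask(self, pair: str) -> pd.Series:
        """Proteins with a finite value in every replicate for ``pair``."""
        return self.pair_frame(pair).notna().all(axis=1)

    def mean_log2(self, require_complete: bool = True) -> pd.DataFrame:
        """Per-protein mean log2 ratio per pair (NaN where incomplete)."""
        out = {}
        for pair in PAIRS:
            frame = self.pair_frame(pair)
            means = frame.mean(axis=1)
            if require_complete:
                means = means.where(frame.notna().all(axis=1))
            out[pair] = means
        return pd.DataFrame(out)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.log2.stack(level=[0, 1], future_stack=True)
            .rename("log2_ratio")
            .reset_index()
        )
        long.columns = ["protein", "pair", "replicate", "log2_ratio"]
        long["ref_intensity"] = long["protein"].map(self.ref_intensity)
        return long


def build_ratio_matrix(
    tables: list[pd.DataFrame], provenance: list[str] | None = None
) -> RatioMatrix:
    """Merge replicate tables into the analysis-ready log2 ratio tensor.

    Linear ratios are log2-transformed; the per-protein reference
    intensity is the median over all positive channel intensities across
    replicates. Proteins with no finite ratio anywhere, or without a
    finite positive reference intensity, are excluded (logged).
    """
    if not tables:
        raise ValueError("at least one table is required")
    n_rep = len(tables)
    union: pd.Index = pd.Index(
        sorted(set().union(*(set(t["protein"]) for t in tables))), name="protein"
    )

    columns = pd.MultiIndex.from_product(
        [list(PAIRS), range(1, n_rep + 1)], names=["pair", "replicate"]
    )
    log2 = pd.DataFrame(np.nan, index=union, columns=columns)
    intensities = pd.DataFrame(
        np.nan, index=union, columns=range(3 * n_rep)
    )
    for r, table in enumerate(tables, start=1):
        t = table.set_index("protein")
        t = t[~t.index.duplicated(keep="first")]
        common = union.intersection(t.index)
        for pair in PAIRS:
            vals = t.loc[common, f"ratio_{pair}"].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                log2.loc[common, (pair, r)] = np.where(
                    vals > 0, np.log2(vals), np.nan
                )
        for ci, ch in enumerate("HML"):
            col = 3 * (r - 1) + ci
            iv = t.loc[common, f"intensity_{ch}"].astype(float)
            intensities.loc[common, col] = iv.where(iv > 0)

    ref = intensities.median(axis=1, skipna=True)
    has_ratio = log2.notna().any(axis=1)
    valid = has_ratio & ref.notna() & (ref > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info(
            "excluded %d proteins with all-missing ratios or no reference intensity",
            n_dropped,
        )
    return RatioMatrix(
        log2=log2.loc[valid],
        ref_intensity=ref.loc[valid].rename("ref_intensity"),
        n_replicates=n_rep,
        provenance=list(provenance or []),
    )


def write_ratio_matrix(matrix: RatioMatrix, path) -> None:
    """Long-format TSV export (protein, pair, replicate, log2, ref intensity)."""
    matrix.to_long().to_csv(path, sep="\t", index=False)


def read_ratio_matrix(path) -> RatioMatrix:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(
        index="protein", columns=["pair", "replicate"], values="log2_ratio",
        dropna=False,
    )
    n_rep = int(long["replicate"].max())
    columns = pd.MultiIndex.from_product(
        [list(PAIRS), range(1, n_rep + 1)], names=["pair", "replicate"]
    )
    wide = wide.reindex(columns=columns)
    ref = long.groupby("protein")["ref_intensity"].first()
    return RatioMatrix(
        log2=wide, ref_intensity=ref.loc[wide.index], n_replicates=n_rep,
        provenance=[str(path)],
    )
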