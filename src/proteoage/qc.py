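"""Dataset-characterization statistics.

Replicate concordance (pairwise Pearson r of log2 ratios), replicate PCA,
cumulative abundance curves, intensity dynamic range, sub-cellular
localization profiles from fractionation intensities, and protein-mRNA
cross-omics correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RatioMatrix
from .simulate import COMPARTMENTS, PAIRS


def replicate_correlation(matrix: RatioMatrix) -> tuple[pd.DataFrame, float]:
    """Pairwise-complete Pearson r between replicates, per SILAC pair.

    Comparisons with fewer than 3 shared finite values are reported as
    undefined (NaN). Returns the per-comparison table and the median r
    across defined comparisons.
    """
    if matrix.n_replicates < 2:
        raise ValueError("at least two replicates are required")
    rows = []
    for pair in PAIRS:
        frame = matrix.pair_frame(pair)
        for a in range(1, matrix.n_replicates + 1):
            for b in range(a + 1, matrix.n_replicates + 1):
                x = frame[a].to_numpy(float)
                y = frame[b].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(y)
                n = int(ok.sum())
                if n < 3:
                    r = np.nan
                else:
                    r = float(stats.pearsonr(x[ok], y[ok]).statistic)
                rows.append({"pair": pair, "rep_a": a, "rep_b": b, "r": r, "n": n})
    table = pd.DataFrame(rows)
    defined = table["r"].dropna()
    median_r = float(defined.median()) if len(defined) else float("nan")
    return table, median_r


def replicate_pca(
    matrix: RatioMatrix,
    n_components: int = 2,
    observations: str = "replicates",
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the replicate-by-protein log2 ratio matrix.

    With ``observations="replicates"`` (default) replicates are the
    observations and proteins (concatenated over pairs, complete cases
    only) the features; ``observations="proteins"`` transposes the view.
    Features are centered and decomposed by SVD. Returns coordinates on
    the leading components and explained-variance fractions (sum <= 1).
    """
    if observations not in ("replicates", "proteins"):
        raise ValueError("observations must be 'replicates' or 'proteins'")
    blocks = []
    index_parts = []
    for pair in PAIRS:
        frame = matrix.pair_frame(pair)
        complete = frame.dropna(axis=0)
        if len(complete):
            blocks.append(complete.to_numpy(float).T)  # replicates x proteins
            index_parts.extend(f"{p}:{pair}" for p in complete.index)
    if not blocks:
        raise ValueError("no complete proteins available for PCA")
    x = np.hstack(blocks)
    obs_index = pd.RangeIndex(1, x.shape[0] + 1, name="replicate")
    if observations == "proteins":
        x = x.T
        obs_index = pd.Index(index_parts, name="protein")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    total = float((s**2).sum())
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    coord_df = pd.DataFrame(
        coords, index=obs_index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return coord_df, evr


@dataclass
class CumulativeCurve:
    """Cumulative mass-fraction curve over descending-abundance ranks."""

    proteins: pd.Index
    cumulative_fraction: np.ndarray

    def top_n_mass_fraction(self, n: int) -> float:
        if n <= 0:
            return 0.0
        return float(self.cumulative_fraction[min(n, len(self.cumulative_fraction)) - 1])

    def n_for_mass_fraction(self, q: float) -> int:
        """Smallest rank whose cumulative fraction reaches at least ``q``."""
        if not 0 <= q <= 1:
            raise ValueError("q must lie in [0, 1]")
        return int(np.searchsorted(self.cumulative_fraction, q - 1e-12) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.proteins) + 1),
                "protein": self.proteins,
                "cumulative_fraction": self.cumulative_fraction,
            }
        )


def median_protein_intensity(tables: list[pd.DataFrame]) -> pd.Series:
    """Median over all positive channel intensities across replicates."""
    frames = []
    for t in tables:
        sub = t.set_index("protein")[
            ["intensity_H", "intensity_M", "intensity_L"]
        ].astype(float)
        frames.append(sub.where(sub > 0))
    wide = pd.concat(frames, axis=1)
    return wide.median(axis=1, skipna=True).dropna().rename("median_intensity")


def cumulative_abundance(intensities: pd.Series) -> CumulativeCurve:
    """Rank proteins by descending abundance and accumulate mass fraction."""
    vals = intensities.astype(float).fillna(0.0)
    if (vals < 0).any():
        raise ValueError("intensities must be nonnegative")
    total = float(vals.sum())
    if total <= 0:
        raise ValueError("all intensities are zero")
    order = vals.sort_values(ascending=False, kind="mergesort")
    cum = order.to_numpy().cumsum() / total
    return CumulativeCurve(proteins=order.index, cumulative_fraction=cum)


def dynamic_range(
    intensities, percentiles: tuple[float, float] | None = None
) -> float:
    """Span of positive intensities in decades: log10(max / min).

    With ``percentiles=(lo, hi)`` the span is measured between those
    percentiles instead of the extremes (a trimmed estimate, matching how
    a histogram's visual span is usually read).
    """
    vals = np.asarray(intensities, dtype=float)
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if vals.size == 0:
        raise ValueError("no strictly positive intensities")
    if percentiles is None:
        lo, hi = vals.min(), vals.max()
    else:
        lo, hi = np.percentile(vals, percentiles)
    return float(np.log10(hi) - np.log10(lo))


def localization_profile(
    fraction_table: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-protein compartment proportions and predominant-localization call.

    Proportions are fraction intensities normalized to the per-protein
    total; the predominant label is assigned when the largest proportion
    reaches ``threshold``, otherwise the protein is called "mixed".
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cols = [c for c in COMPARTMENTS if c in fraction_table.columns]
    if len(cols) != 4:
        raise ValueError(f"fraction table must carry columns {COMPARTMENTS}")
    vals = fraction_table[cols].astype(float).to_numpy()
    if (vals < 0).any():
        raise ValueError("fraction intensities must be nonnegative")
    totals = vals.sum(axis=1)
    ok = totals > 0
    props = np.full_like(vals, np.nan)
    props[ok] = vals[ok] / totals[ok, None]
    out = pd.DataFrame(props, index=fraction_table.index, columns=cols)
    max_prop = np.nanmax(props, axis=1)
    arg = np.nanargmax(np.where(np.isnan(props), -np.inf, props), axis=1)
    labels = np.array(cols, dtype=object)[arg]
    out["predominant"] = np.where(ok & (max_prop >= threshold), labels, "mixed")
    out.loc[~ok, "predominant"] = "undefined"
    return out


def cross_omics_correlation(
    protein_changes: pd.Series, mrna_changes: pd.Series
) -> tuple[float, int]:
    """Pearson r between protein and mRNA changes over matched ids."""
    joined = pd.concat(
        [protein_changes.rename("prot"), mrna_changes.rename("rna")],
        axis=1, join="inner",
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("fewer than 3 matched finite pairs")
    r = float(stats.pearsonr(joined["prot"], joined["rna"]).statistic)
    return r, n
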