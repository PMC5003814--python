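"""Self-defined gene-set distribution-shift analysis.

Compares the distribution of age fold changes of a named gene set (e.g.
insulin/IGF-1 signaling, mTOR) against the full quantified background.
The shift statistic is the difference of medians (set minus background),
with a rank-sum standardized companion; significance comes from a
permutation null built from random same-size sets drawn from the non-set
background. Members whose change deviates strongly from their own set's
distribution are flagged as within-set outliers (the DAF-16-style
exceptions inside an otherwise shifted pathway).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: unique member ids plus provenance."""

    name: str
    members: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (set name, description, member ids...).

    Duplicate members within a row are dropped with a warning; a row with
    no members is an error naming the set. Row order is preserved.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValueError(f"gene set {parts[0]!r} has no members")
            name, description = parts[0], parts[1]
            seen: list[str] = []
            dups = 0
            for m in parts[2:]:
                m = m.strip()
                if not m:
                    continue
                if m in seen:
                    dups += 1
                else:
                    seen.append(m)
            if dups:
                warnings.warn(
                    f"gene set {name!r}: dropped {dups} duplicate member(s)"
                )
            sets.append(GeneSet(name, tuple(seen), provenance=description))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.provenance, *s.members]) + "\n")


@dataclass
class ShiftResult:
    """Outcome of one gene-set density-shift test."""

    name: str
    n_matched: int
    shift: float  # median(set) - median(background)
    rank_sum_z: float
    p_value: float
    member_table: pd.DataFrame = field(repr=False)

    @property
    def outliers(self) -> pd.Index:
        return self.member_table.index[self.member_table["outlier"]]


def density_shift(
    gene_set: GeneSet,
    changes: pd.Series,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> ShiftResult:
    """Permutation test for a gene set's abundance-change shift.

    ``changes`` is the background table of per-protein log2 changes (the
    full quantified proteome, set members included). The observed
    statistic is median(set) - median(background); the null is built from
    ``n_perm`` random same-size sets drawn without replacement from the
    non-set background, and the p value is the smoothed two-sided
    exceedance fraction (1 + #{|null| >= |observed|}) / (n_perm + 1).

    Members farther than 1.96 set-SDs from the set's own mean are flagged
    as within-set outliers.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    background = changes.dropna().astype(float)
    member_ids = [m for m in gene_set.members if m in background.index]
    if len(member_ids) < 3:
        raise ValueError(
            f"gene set {gene_set.name!r}: fewer than 3 members matched"
        )
    non_set = background.drop(index=member_ids)
    if len(non_set) < len(member_ids):
        raise ValueError(
            f"gene set {gene_set.name!r} covers (nearly) the whole background"
        )

    set_vals = background.loc[member_ids]
    bg_median = float(background.median())
    observed = float(set_vals.median()) - bg_median

    rng = np.random.default_rng(seed)
    pool = non_set.to_numpy()
    m = len(member_ids)
    draws = np.empty((n_perm, m))
    for i in range(n_perm):
        draws[i] = pool[rng.choice(len(pool), size=m, replace=False)]
    null_stats = np.median(draws, axis=1) - bg_median
    exceed = int((np.abs(null_stats) >= abs(observed)).sum())
    p = (1 + exceed) / (n_perm + 1)

    u = stats.mannwhitneyu(set_vals, non_set, alternative="two-sided")
    n1, n2 = m, len(non_set)
    mu_u = n1 * n2 / 2.0
    sd_u = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = float((u.statistic - mu_u) / sd_u)

    set_mean = float(set_vals.mean())
    set_sd = float(set_vals.std(ddof=1))
    outlier = (
        (set_vals - set_mean).abs() > 1.96 * set_sd
        if set_sd > 0
        else pd.Series(False, index=set_vals.index)
    )
    member_table = pd.DataFrame(
        {"log2_change": set_vals, "outlier": outlier}
    )
    return ShiftResult(
        name=gene_set.name,
        n_matched=m,
        shift=observed,
        rank_sum_z=z,
        p_value=float(p),
        member_table=member_table,
    )
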