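"""Cross-strain scaling of age-variant proteins.

Given a protein's age direction in wild type (up or down) and its
mutant-vs-wild-type log2 ratio at a chronologically matched age, classify
whether the mutant resembles a younger animal, an older animal, or shows
no appreciable difference, then summarize cohort proportions per strain
and direction stratum (the stacked-bar logic of long-/short-lived mutant
comparisons).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CALLS = ("younger", "unchanged", "older")

#: Default call threshold in log2 units (1.5-fold).
DEFAULT_DELTA = 0.585


def classify_scaling(
    direction: str, mutant_vs_wt_log2: float, delta: float = DEFAULT_DELTA
) -> str:
    """Classify one protein's mutant behaviour.

    For an age-increasing protein, a mutant level at least ``delta``
    below wild type is a younger pattern and at least ``delta`` above is
    an older pattern; for an age-decreasing protein the convention
    inverts (more abundant in the mutant = younger). Anything within the
    band is unchanged.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if direction not in ("up", "down"):
        raise ValueError(
            "direction must be 'up' or 'down'; only age-variant proteins are classifiable"
        )
    x = float(mutant_vs_wt_log2)
    if not np.isfinite(x):
        raise ValueError("mutant_vs_wt_log2 must be finite")
    sign = 1.0 if direction == "up" else -1.0
    v = sign * x
    if v <= -delta:
        return "younger"
    if v >= delta:
        return "older"
    return "unchanged"


def classify_table(
    mutant_table: pd.DataFrame, delta: float = DEFAULT_DELTA
) -> pd.DataFrame:
    """Apply :func:`classify_scaling` to a (protein, strain, wt_direction,
    log2_mutant_vs_wt) table, appending a ``call`` column."""
    required = {"protein", "strain", "wt_direction", "log2_mutant_vs_wt"}
    missing = required - set(mutant_table.columns)
    if missing:
        raise ValueError(f"mutant table is missing columns {sorted(missing)}")
    out = mutant_table.copy()
    out["call"] = [
        classify_scaling(d, x, delta)
        for d, x in zip(out["wt_direction"], out["log2_mutant_vs_wt"])
    ]
    return out


def scaling_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of calls per (strain, direction) stratum.

    Proportions are reported to 3 decimals; counts within a stratum sum
    to the stratum size and proportions to 1.
    """
    required = {"strain", "wt_direction", "call"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table is missing columns {sorted(missing)}")
    rows = []
    for (strain, direction), grp in calls.groupby(["strain", "wt_direction"]):
        n = len(grp)
        counts = grp["call"].value_counts()
        for call in CALLS:
            c = int(counts.get(call, 0))
            rows.append(
                {
                    "strain": strain,
                    "wt_direction": direction,
                    "call": call,
                    "count": c,
                    "proportion": round(c / n, 3),
                    "n_stratum": n,
                }
            )
    return pd.DataFrame(rows)


def intersect_age_variant(
    ours: pd.DataFrame, external: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Inner-join our significant set with an external study's table on
    protein id, keeping only direction-concordant proteins.

    Both inputs need ``protein`` and ``direction`` columns. Returns the
    concordant table and the number of discordant proteins discarded.
    """
    for name, df in (("ours", ours), ("external", external)):
        if not {"protein", "direction"} <= set(df.columns):
            raise ValueError(f"{name} table needs 'protein' and 'direction' columns")
    merged = ours.merge(
        external, on="protein", suffixes=("_ours", "_external")
    )
    if merged.empty:
        warnings.warn("no overlapping proteins between the two studies")
        return merged.assign(direction=pd.Series(dtype=object)), 0
    concordant = merged["direction_ours"] == merged["direction_external"]
    discarded = int((~concordant).sum())
    out = merged[concordant].copy()
    out["direction"] = out["direction_ours"]
    return out, discarded
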