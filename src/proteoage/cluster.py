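"""Trend-profile clustering of age-variant proteins.

Each protein's (M/H, L/M, L/H) log2 fold changes are scaled to [-1, +1]
by dividing by the profile's own maximum absolute entry (-1 = maximum
decrease, +1 = maximum increase, near 0 = no change), then clustered with
Ward's minimum-variance method. The tree is typically cut at k = 2 (up
vs down) and k = 6 (trend archetypes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .simulate import PAIRS


def scale_profiles(changes: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each protein's change profile into [-1, +1].

    Divides every row by its own maximum absolute value; all-zero
    profiles are left unchanged. Returns the scaled table and the scale
    factor used per protein. Scaling preserves sign pattern and the
    within-profile rank order of magnitudes, and is idempotent.
    """
    cols = [c for c in PAIRS if c in changes.columns]
    if len(cols) != len(PAIRS):
        raise ValueError(f"changes must carry columns {PAIRS}")
    vals = changes[list(PAIRS)].astype(float)
    if vals.isna().any().any():
        raise ValueError("profiles must not contain missing values")
    scale = vals.abs().max(axis=1)
    divisor = scale.replace(0.0, 1.0)
    scaled = vals.div(divisor, axis=0)
    return scaled, scale.rename("scale_factor")


@dataclass
class ClusterAssignment:
    """Ward clustering result: labels, linkage tree, and profiles.

    Cluster labels run 1..k, numbered by descending cluster size with
    ties broken by the smallest member protein id. ``linkage_matrix`` is
    the scipy agglomeration encoding (merge heights nondecreasing).
    """

    labels: pd.Series
    linkage_matrix: np.ndarray
    profiles: pd.DataFrame
    k: int

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def ward_cluster(profiles: pd.DataFrame, k: int) -> ClusterAssignment:
    """Agglomerative Ward (squared-Euclidean minimum-variance) clustering.

    Uses the Lance-Williams Ward update (Ward.D2 semantics) and cuts the
    tree at ``k`` clusters.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(profiles)})")
    vals = profiles[list(PAIRS)].astype(float)
    if vals.isna().any().any():
        raise ValueError("profiles must not contain missing values")
    # stable input order regardless of caller's row order
    vals = vals.sort_index(kind="mergesort")
    z = linkage(vals.to_numpy(), method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=vals.index, name="cluster")

    order = sorted(
        labels.unique(),
        key=lambda c: (-int((labels == c).sum()), str(labels.index[labels == c].min())),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = labels.map(remap)
    return ClusterAssignment(
        labels=labels.loc[profiles.index], linkage_matrix=z,
        profiles=vals.loc[profiles.index], k=int(labels.max()),
    )


def _descriptor(mean_mh: float, mean_lm: float, dead_zone: float = 0.1) -> str:
    words = {1: "up", 0: "flat", -1: "down"}
    s1 = 0 if abs(mean_mh) < dead_zone else int(np.sign(mean_mh))
    s2 = 0 if abs(mean_lm) < dead_zone else int(np.sign(mean_lm))
    if s1 == 0 and s2 == 0:
        return "flat"
    if s1 != 0 and s2 != 0 and s1 != s2:
        return f"{words[s1]}-then-{words[s2]}"
    if s2 == 0:
        return f"{words[s1]}-flat" if s1 != 0 else "flat"
    if s1 == 0:
        return f"flat-then-{words[s2]}"
    return f"{words[s1]}-{words[s2]}"


def cluster_trends(assignment: ClusterAssignment, dead_zone: float = 0.1) -> pd.DataFrame:
    """Per-cluster mean scaled profile plus a qualitative trend descriptor.

    The descriptor reads the signs of the cluster-mean M/H and L/M
    components with a dead zone at ``|mean| < dead_zone`` (e.g. a cluster
    mean of (0.8, -0.7, 0.05) reads "up-then-down").
    """
    rows = []
    for c in sorted(assignment.labels.unique()):
        members = assignment.members(c)
        mean = assignment.profiles.loc[members, list(PAIRS)].mean()
        rows.append(
            {
                "cluster": c,
                "n": len(members),
                **{f"mean_{p}": float(mean[p]) for p in PAIRS},
                "archetype": _descriptor(mean["MH"], mean["LM"], dead_zone),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def coarsening_consistency(
    fine: ClusterAssignment, coarse: ClusterAssignment
) -> float:
    """Mean, over fine clusters, of the largest fraction of members that
    land in a single coarse cluster (1.0 when the fine partition refines
    the coarse one exactly, as successive cuts of one tree do)."""
    fracs = []
    for c in fine.labels.unique():
        members = fine.members(c)
        counts = coarse.labels.loc[members].value_counts()
        fracs.append(counts.iloc[0] / len(members))
    return float(np.mean(fracs))
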