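"""Typed synaptic-connectivity analysis.

Operations on cell-type-resolved synapse-count matrices (partner type x
focal type, with a class label per partner type): thresholding counts into a
binary "connected" matrix, fan-in/fan-out statistics over partner types, and
agglomerative clustering of focal types by their class-aggregated
connectivity profiles (complete linkage, cosine affinity).

Input CSVs follow the schema
``partner_type, focal_type, direction, synapse_count, partner_class``
with ``direction`` in {"pre", "post"}; pre- and postsynaptic matrices are
kept separate and analysed independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "TypedConnectivity",
    "load_connectivity_csv",
    "threshold_ticks",
    "fan_statistics",
    "cluster_focal_types",
]


@dataclass
class TypedConnectivity:
    """Synapse counts between partner types (rows) and focal types (columns)."""

    counts: pd.DataFrame            # partner_type x focal_type, int counts
    partner_class: pd.Series        # class label per partner type
    direction: str = "pre"          # "pre" or "post"

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.issubdtype(vals.dtype, np.number):
            raise ValueError("synapse counts must be non-negative numbers")
        self.partner_class = self.partner_class.reindex(self.counts.index)


def load_connectivity_csv(path) -> dict[str, TypedConnectivity]:
    """Load a long-format connectivity CSV into per-direction matrices."""
    df = pd.read_csv(path)
    required = {"partner_type", "focal_type", "direction", "synapse_count", "partner_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"connectivity CSV missing columns: {sorted(missing)}")
    out = {}
    for direction, sub in df.groupby("direction"):
        counts = sub.pivot_table(
            index="partner_type", columns="focal_type",
            values="synapse_count", aggfunc="sum", fill_value=0,
        )
        classes = sub.drop_duplicates("partner_type").set_index("partner_type")["partner_class"]
        out[direction] = TypedConnectivity(counts, classes, direction)
    return out


def threshold_ticks(m: TypedConnectivity, min_synapses: int = 5) -> pd.DataFrame:
    """Binary connection matrix: True iff count >= ``min_synapses``."""
    return m.counts >= min_synapses


def fan_statistics(ticks: pd.DataFrame, k: int = 2):
    """Fraction of partner types connected to at least ``k`` focal types.

    Returns ``(fraction, per_partner)`` where ``per_partner`` is the number
    of connected focal types for every partner type (the "Li32 projects to
    27 out of 28 types" style report).
    """
    if ticks.shape[0] == 0:
        raise ValueError("no partner types")
    per_partner = ticks.sum(axis=1)
    fraction = float((per_partner >= k).mean())
    return fraction, per_partner.sort_values(ascending=False)


def cluster_focal_types(m: TypedConnectivity, n_clusters: int | None = None):
    """Agglomerative clustering of focal types on class-summed connections.

    Features for each focal type are its summed synapse counts per partner
    class; complete linkage on cosine distances. Returns a dict with the
    scipy linkage matrix, the focal-type ordering, and (if ``n_clusters``)
    flat cluster assignments listed in numerical/lexical order within each
    cluster.
    """
    features = (
        m.counts.groupby(m.partner_class, observed=True).sum().T
    )  # focal_type x partner_class
    focal = list(features.index)
    if len(focal) == 1:
        return {"linkage": None, "order": focal, "clusters": {1: focal}}
    X = features.to_numpy(dtype=float)
    # cosine distance undefined for all-zero rows; nudge them to a tiny uniform profile
    zero = X.sum(axis=1) == 0
    X[zero] = 1e-12
    dist = pdist(X, metric="cosine")
    Z = linkage(dist, method="complete")
    from scipy.cluster.hierarchy import leaves_list

    order = [focal[i] for i in leaves_list(Z)]
    clusters = None
    if n_clusters is not None:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
        clusters = {}
        for label in sorted(set(flat)):
            members = sorted([f for f, c in zip(focal, flat) if c == label])
            clusters[int(label)] = members
    return {"linkage": Z, "order": order, "clusters": clusters}
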