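"""Graph construction, hub metrics, parcel aggregation and laterality.

The task-related adjacency is binarized at a fraction of its maximum
positive entry (70% by default); only positive, i.e. task-increased,
coupling forms edges. Hubs are identified with three centrality
measures — degree, eigenvector centrality (EVC) and betweenness — and
summarized per atlas parcel. Hemispheric dominance is quantified by the
laterality index LI = (L − R)/(L + R) of EVC summed over frontal and
temporal parcels, with |LI| > 0.25 defining left/right dominance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy import stats as sps

from .connectivity import AdjacencyMatrix
from .stats import fdr_bh
from .synthetic import ParcelAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryGraph",
    "CentralityMap",
    "LateralityResult",
    "binarize_by_max_fraction",
    "degree_centrality",
    "eigenvector_centrality",
    "betweenness_centrality",
    "centrality_map",
    "parcellate_and_scale",
    "laterality_index",
    "group_contrast",
]


@dataclass
class BinaryGraph:
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    threshold_fraction: float
    source: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class CentralityMap:
    degree: np.ndarray
    evc: np.ndarray
    betweenness: np.ndarray
    scaled: bool = False


@dataclass
class LateralityResult:
    li: float
    category: str  # left / right / bilateral
    L: float
    R: float


def binarize_by_max_fraction(
    adjacency: AdjacencyMatrix, fraction: float = 0.7, edge_sign: str = "positive"
) -> BinaryGraph:
    """Edges where the entry reaches ``fraction`` × the maximum strength.

    With ``edge_sign='positive'`` (default) only positive entries —
    task-related coupling increases — can form edges and the reference
    maximum is the largest positive off-diagonal value. 'absolute' uses
    magnitudes instead. An adjacency without positive entries yields an
    empty graph with a warning.
    """
    V = adjacency.values.copy()
    np.fill_diagonal(V, 0.0)
    if edge_sign == "absolute":
        V = np.abs(V)
    elif edge_sign != "positive":
        raise ValueError("edge_sign must be 'positive' or 'absolute'")
    vmax = V.max()
    if vmax <= 0:
        warnings.warn("adjacency has no positive entries; graph is empty", stacklevel=2)
        A = np.zeros_like(V, dtype=bool)
    else:
        A = (V > 0) & (V >= fraction * vmax)
        np.fill_diagonal(A, False)
        A = A & A.T
    return BinaryGraph(adjacency=A, threshold_fraction=fraction)


def degree_centrality(g: BinaryGraph) -> np.ndarray:
    """Suprathreshold connection count per node (row sums)."""
    return g.adjacency.sum(axis=1).astype(int)


def eigenvector_centrality(g: BinaryGraph) -> np.ndarray:
    """Non-negative leading eigenvector of the adjacency, scaled to max 1.

    Eigenvector centrality is only defined up to component, so it is
    computed on the largest connected component (ties broken toward the
    component containing the lowest-index node) and set to zero
    elsewhere. Deterministic: the dense symmetric eigendecomposition is
    used and the Perron vector's sign fixed to be non-negative.
    """
    n = g.n_nodes
    scores = np.zeros(n)
    if not g.adjacency.any():
        warnings.warn("empty graph: eigenvector centrality all zero", stacklevel=2)
        return scores
    n_comp, labels = connected_components(csr_matrix(g.adjacency), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(range(n_comp), key=lambda c: (sizes[c], -int(np.nonzero(labels == c)[0][0])))
    idx = np.nonzero(labels == best)[0]
    sub = g.adjacency[np.ix_(idx, idx)].astype(float)
    w, v = np.linalg.eigh(sub)
    lead = v[:, -1]
    if lead.sum() < 0:
        lead = -lead
    lead = np.abs(lead)  # Perron vector is sign-constant; abs kills round-off
    scores[idx] = lead
    if scores.max() > 0:
        scores = scores / scores.max()
    return scores


def betweenness_centrality(g: BinaryGraph) -> np.ndarray:
    """Unnormalized shortest-path betweenness (undirected pairs counted once)."""
    G = nx.from_numpy_array(g.adjacency.astype(int))
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(g.n_nodes)], dtype=float)


def centrality_map(g: BinaryGraph) -> CentralityMap:
    return CentralityMap(
        degree=degree_centrality(g),
        evc=eigenvector_centrality(g),
        betweenness=betweenness_centrality(g),
    )


def parcellate_and_scale(
    metrics: CentralityMap, atlas: ParcelAtlas, scale: bool = False
) -> pd.DataFrame:
    """Per-parcel arithmetic mean of each voxel-level metric.

    Returns a table with one row per atlas parcel (parcel id, name,
    hemisphere, lobe, voxel count, mean degree/EVC/betweenness). With
    ``scale=True`` each metric column is rescaled to [0, 1] by its
    maximum, the convention for group-level maps.
    """
    n_vox = len(atlas.labels)
    for arr in (metrics.degree, metrics.evc, metrics.betweenness):
        if len(arr) != n_vox:
            raise ValueError("atlas must cover every voxel of the metric map")
    df = pd.DataFrame(
        {
            "parcel": atlas.labels,
            "degree": metrics.degree,
            "evc": metrics.evc,
            "betweenness": metrics.betweenness,
        }
    )
    agg = df.groupby("parcel").agg(
        n_voxels=("degree", "size"),
        degree=("degree", "mean"),
        evc=("evc", "mean"),
        betweenness=("betweenness", "mean"),
    )
    # every atlas parcel present, NaN marker for empty ones
    agg = agg.reindex(atlas.parcel_ids)
    agg.insert(0, "name", [atlas.names[int(p)] for p in agg.index])
    agg.insert(1, "hemisphere", [atlas.hemisphere[int(p)] for p in agg.index])
    agg.insert(2, "lobe", [atlas.lobe[int(p)] for p in agg.index])
    if scale:
        for col in ("degree", "evc", "betweenness"):
            mx = agg[col].max()
            if mx and np.isfinite(mx) and mx > 0:
                agg[col] = agg[col] / mx
    agg.index.name = "parcel"
    return agg.reset_index()


def laterality_index(
    parcels: pd.DataFrame,
    metric: str = "evc",
    cutoff: float = 0.25,
    agg: str = "sum",
) -> LateralityResult:
    """Hemispheric laterality of a parcel metric over frontotemporal parcels.

    ``LI = (L − R)/(L + R)`` with L, R the per-hemisphere aggregate
    (sum by default; mean selectable — the two agree whenever the
    hemispheres contribute equal parcel counts) of the metric over
    frontal and temporal parcels. Strictly LI > 0.25 classifies left,
    LI < −0.25 right, otherwise bilateral.
    """
    ft = parcels[parcels["lobe"].isin(["frontal", "temporal"])]
    lvals = ft.loc[ft["hemisphere"] == "L", metric].dropna()
    rvals = ft.loc[ft["hemisphere"] == "R", metric].dropna()
    if lvals.empty or rvals.empty:
        raise ValueError("need at least one frontotemporal parcel per hemisphere")
    if agg == "sum":
        L, R = float(lvals.sum()), float(rvals.sum())
    elif agg == "mean":
        L, R = float(lvals.mean()), float(rvals.mean())
    else:
        raise ValueError("agg must be 'sum' or 'mean'")
    if L + R <= 0:
        warnings.warn("L + R = 0: laterality index undefined, reporting bilateral", stacklevel=2)
        return LateralityResult(li=float("nan"), category="bilateral", L=L, R=R)
    li = (L - R) / (L + R)
    if li > cutoff:
        category = "left"
    elif li < -cutoff:
        category = "right"
    else:
        category = "bilateral"
    return LateralityResult(li=li, category=category, L=L, R=R)


def group_contrast(
    parcels_group_a: Sequence[pd.DataFrame],
    parcels_group_b: Sequence[pd.DataFrame],
    metric: str = "evc",
    q: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Independent-samples t-test per parcel between two subject groups.

    Welch's t by default (``equal_var=True`` for the pooled variant),
    direction A − B, BH-FDR across parcels at level ``q``. Parcels with
    zero variance in both groups get NaN and are excluded from the FDR
    family.
    """
    if len(parcels_group_a) < 2 or len(parcels_group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    ref = parcels_group_a[0][["parcel", "name", "hemisphere", "lobe"]]
    A = np.column_stack([df[metric].to_numpy() for df in parcels_group_a])
    B = np.column_stack([df[metric].to_numpy() for df in parcels_group_b])
    t = np.full(A.shape[0], np.nan)
    p = np.full(A.shape[0], np.nan)
    for i in range(A.shape[0]):
        a, b = A[i], B[i]
        if np.nanstd(a) == 0 and np.nanstd(b) == 0:
            continue  # undefined, excluded from FDR
        res = sps.ttest_ind(a, b, equal_var=equal_var, nan_policy="omit")
        t[i], p[i] = res.statistic, res.pvalue
    mask = fdr_bh(p, q=q)
    out = ref.copy()
    out["t"] = t
    out["p"] = p
    out["fdr_significant"] = mask
    out.attrs["direction"] = "A-B"
    out.attrs["group_sizes"] = (len(parcels_group_a), len(parcels_group_b))
    return out
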