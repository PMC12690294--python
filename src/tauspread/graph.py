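"""Weighted connectome graphs and shortest-path distance profiles.

Structural connectomes are dense nonnegative matrices of tractography
connection strengths in [0, 1]. The analysis graph is formed by
symmetrizing, zeroing the diagonal and excluding the weakest fraction of
positive edges (default 10%); edge cost is the inverse of connection
strength, and inter-regional distance is the all-pairs shortest-path
cost (Dijkstra). A group connectome averages the raw matrices of
cognitively unimpaired amyloid-negative subjects before thresholding.

Average distance from a subject's epicenters is computed for each region
under four variants crossing individualized (IE) vs canonical group (GE)
epicenters with individual (IC) vs group (GC) connectomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "DistanceMatrix",
    "VARIANTS",
    "prepare_adjacency",
    "shortest_path_distances",
    "group_connectome",
    "epicenter_distance_profiles",
]

#: The four model variants: individualized/group epicenters x
#: individual/group connectome.
VARIANTS = ("IE-IC", "IE-GC", "GE-IC", "GE-GC")


@dataclass(frozen=True)
class Connectome:
    labels: tuple[str, ...]
    adjacency: np.ndarray
    provenance: str
    exclude_bottom_fraction: float

    @property
    def n_regions(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    distances: np.ndarray  # inf for unreachable pairs
    provenance: str
    n_unreachable_pairs: int


def prepare_adjacency(
    raw: np.ndarray,
    labels,
    exclude_bottom_fraction: float = 0.10,
    provenance: str = "individual",
) -> Connectome:
    """Symmetrize, clean and threshold a raw connectivity matrix.

    The matrix is symmetrized by the arithmetic mean of (i,j) and (j,i),
    the diagonal zeroed, and the weakest ``floor(fraction * n_edges)``
    strictly-positive undirected edges removed (ties broken by row-major
    position). Entries marginally above 1 (float dust, <= 1e-6) are
    clipped; larger values raise.
    """
    a = np.asarray(raw, dtype=float)
    labels = tuple(str(x) for x in labels)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got {a.shape}")
    if a.shape[0] != len(labels):
        raise ValueError("label count does not match matrix size")
    if np.any(a < 0):
        raise ValueError("adjacency contains negative weights")
    if np.any(a > 1.0 + 1e-6):
        raise ValueError("adjacency contains weights > 1")
    if np.any(a > 1.0):
        logger.warning("clipping %d weights marginally above 1",
                       int((a > 1.0).sum()))
        a = np.minimum(a, 1.0)
    if not 0.0 <= exclude_bottom_fraction < 1.0:
        raise ValueError("exclude_bottom_fraction must be in [0, 1)")

    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)

    iu, ju = np.triu_indices_from(a, k=1)
    w = a[iu, ju]
    pos = w > 0
    n_edges = int(pos.sum())
    n_remove = int(np.floor(exclude_bottom_fraction * n_edges))
    if n_remove > 0:
        idx = np.flatnonzero(pos)
        # sort by weight, then row-major (i, j) for deterministic ties
        order = np.lexsort((ju[idx], iu[idx], w[idx]))
        kill = idx[order[:n_remove]]
        a[iu[kill], ju[kill]] = 0.0
        a[ju[kill], iu[kill]] = 0.0
    return Connectome(labels, a, provenance, exclude_bottom_fraction)


def shortest_path_distances(c: Connectome) -> DistanceMatrix:
    """All-pairs shortest-path distances with edge cost = 1 / weight.

    Zero-weight pairs are non-edges. Unreachable pairs are reported as
    inf (counted, not raised).
    """
    a = c.adjacency
    mask = a > 0
    costs = np.zeros_like(a)
    costs[mask] = 1.0 / a[mask]
    d = dijkstra(csr_matrix(costs), directed=False)
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(a.shape[0], dtype=bool)
    n_unreachable = int(np.isinf(d[off]).sum()) // 2
    if n_unreachable:
        logger.warning("%d unreachable region pairs in %s connectome",
                       n_unreachable, c.provenance)
    return DistanceMatrix(c.labels, d, c.provenance, n_unreachable)


def group_connectome(
    adjacencies: dict[str, np.ndarray],
    metadata: pd.DataFrame,
    selector=None,
    exclude_bottom_fraction: float = 0.10,
    labels=None,
) -> Connectome:
    """Element-wise mean of raw matrices over selected subjects, then
    thresholding with the same policy as individual connectomes.

    The default selector keeps cognitively unimpaired amyloid-negative
    subjects (``diagnosis == "CU"`` and ``amyloid_positive`` falsy).
    """
    if selector is None:
        def selector(row):
            return row["diagnosis"] == "CU" and not bool(row["amyloid_positive"])
    selected = [s for s in adjacencies
                if s in metadata.index and selector(metadata.loc[s])]
    if not selected:
        raise ValueError("group connectome selector matched no subjects")
    mean = np.mean([np.asarray(adjacencies[s], dtype=float)
                    for s in selected], axis=0)
    if labels is None:
        labels = [f"r{i}" for i in range(mean.shape[0])]
    logger.info("group connectome averaged over %d subjects", len(selected))
    return prepare_adjacency(mean, labels, exclude_bottom_fraction,
                             provenance=f"group(n={len(selected)})")


def average_epicenter_distance(
    dmat: DistanceMatrix,
    epicenter_regions,
    retained_regions,
) -> pd.Series:
    """Mean shortest-path distance of each retained region from a set of
    epicenters; infinite entries are dropped from the mean (logged), and a
    region unreachable from every epicenter gets NaN."""
    label_ix = {lab: i for i, lab in enumerate(dmat.labels)}
    epi_ix = [label_ix[e] for e in epicenter_regions]
    if not epi_ix:
        raise ValueError("epicenter set is empty")
    reg_ix = [label_ix[r] for r in retained_regions]
    sub = dmat.distances[np.ix_(reg_ix, epi_ix)]
    finite = np.isfinite(sub)
    n_inf = int((~finite).sum())
    if n_inf:
        logger.warning("dropping %d infinite epicenter distances", n_inf)
    with np.errstate(invalid="ignore"):
        vals = np.where(finite, sub, 0.0).sum(axis=1) / finite.sum(axis=1)
    vals[finite.sum(axis=1) == 0] = np.nan
    return pd.Series(vals, index=list(retained_regions))


def epicenter_mean_distances(
    c: Connectome,
    epicenter_regions,
    retained_regions,
) -> pd.Series:
    """Mean shortest-path distance of each retained region from a set of
    epicenters, running Dijkstra from the epicenter sources only.

    Equivalent to ``average_epicenter_distance(shortest_path_distances(c),
    ...)`` but avoids the full all-pairs computation; infinite entries are
    dropped from the mean as there.
    """
    label_ix = {lab: i for i, lab in enumerate(c.labels)}
    sources = [label_ix[e] for e in epicenter_regions]
    if not sources:
        raise ValueError("epicenter set is empty")
    a = c.adjacency
    mask = a > 0
    costs = np.zeros_like(a)
    costs[mask] = 1.0 / a[mask]
    d = dijkstra(csr_matrix(costs), directed=False, indices=sources)
    for k, s in enumerate(sources):
        d[k, s] = 0.0
    reg_ix = [label_ix[r] for r in retained_regions]
    sub = d[:, reg_ix].T
    finite = np.isfinite(sub)
    n_inf = int((~finite).sum())
    if n_inf:
        logger.warning("dropping %d infinite epicenter distances", n_inf)
    with np.errstate(invalid="ignore"):
        vals = np.where(finite, sub, 0.0).sum(axis=1) / finite.sum(axis=1)
    vals[finite.sum(axis=1) == 0] = np.nan
    return pd.Series(vals, index=list(retained_regions))


def epicenter_distance_profiles(
    subject_distances: dict[str, DistanceMatrix],
    group_distance: DistanceMatrix,
    individual_epicenters: dict,
    canonical_epicenters,
    retained_regions,
) -> dict[str, pd.DataFrame]:
    """Per-subject average distance-from-epicenter profiles for the four
    variants.

    Returns ``{variant: subjects x retained-regions DataFrame}``. Subjects
    with an empty individualized epicenter set get NaN rows for the IE
    variants (they are excluded from statistics downstream).
    """
    canonical = list(canonical_epicenters)
    out = {v: {} for v in VARIANTS}
    for subject, dmat in subject_distances.items():
        epi = individual_epicenters.get(subject)
        regions = list(epi.regions) if epi is not None else []
        for variant in VARIANTS:
            d = dmat if variant.endswith("IC") else group_distance
            e = regions if variant.startswith("IE") else canonical
            if not e:
                out[variant][subject] = pd.Series(
                    np.nan, index=list(retained_regions))
            else:
                out[variant][subject] = average_epicenter_distance(
                    d, e, retained_regions)
    return {v: pd.DataFrame(rows).T.loc[list(subject_distances)]
            for v, rows in out.items()}
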