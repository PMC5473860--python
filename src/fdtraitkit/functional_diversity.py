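"""Functional-diversity indices over a trait subset.

Four community-level indices on z-standardized trait space:

* FAD  — sum of pairwise Euclidean distances among the species present.
* FD   — total branch length of the part of a UPGMA (average-linkage)
  dendrogram spanning the species present. The dendrogram is built once
  over the full species pool per trait subset and pruned per community.
* Q    — Rao's quadratic entropy, the abundance-weighted sum of pairwise
  distances: Σ_{i<j} d_ij p_i p_j.
* FDis — functional dispersion, the abundance-weighted mean distance of
  species to the abundance-weighted trait centroid.

Traits are standardized over the full species pool BEFORE subsetting, so
index values for different subsets are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .data_model import CommunityMatrix, TraitMatrix, resolve_subset, standardize_traits

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "species_distance_matrix",
    "functional_dendrogram",
    "fad",
    "fd_branch_length",
    "rao_q",
    "fdis",
    "fd_profile",
    "ALL_INDICES",
]

ALL_INDICES = ("fad", "fd", "q", "fdis")


@dataclass
class DistanceMatrix:
    species_ids: list[str]
    d: np.ndarray
    metric: str = "euclidean"
    trait_subset: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0) or np.any(self.d < 0):
            raise ValueError("distances must be nonnegative with zero diagonal")

    def mask(self, present: Iterable[str] | np.ndarray) -> np.ndarray:
        if isinstance(present, np.ndarray) and present.dtype == bool:
            return present
        pos = {s: i for i, s in enumerate(self.species_ids)}
        m = np.zeros(len(self.species_ids), dtype=bool)
        for s in present:
            if s not in pos:
                raise KeyError(f"unknown species {s!r}")
            m[pos[s]] = True
        return m


@dataclass
class Dendrogram:
    """UPGMA tree over the full species pool.

    Node i < n is tip i; node n + j is the j-th merge. Node heights are
    half the cophenetic merge distances (so two species at distance d meet
    at height d/2 and the path between them has length d). ``tip_sets``
    row j gives the tips below internal node n + j.
    """

    species_ids: list[str]
    Z: np.ndarray
    node_heights: np.ndarray     # length 2n-1
    edge_child: np.ndarray       # 2n-2 child-node ids
    edge_length: np.ndarray      # matching branch lengths
    tip_sets: np.ndarray         # (2n-1, n) boolean membership
    total_branch_length: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_branch_length = float(self.edge_length.sum())


def species_distance_matrix(tm: TraitMatrix, subset: Sequence[int | str] | None = None
                            ) -> DistanceMatrix:
    """Pairwise Euclidean distances on the selected standardized trait
    columns. ``tm`` must already be standardized over the full pool."""
    if not tm.is_standardized():
        raise ValueError("species_distance_matrix requires standardized traits "
                         "(standardize over the full pool, then subset)")
    if subset is None:
        idx = tuple(range(tm.n_traits))
    else:
        idx = resolve_subset(subset, tm.trait_names)
    X = tm.values[:, idx]
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(list(tm.species_ids), d, "euclidean",
                          tuple(tm.trait_names[j] for j in idx))


def functional_dendrogram(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram over the full species pool."""
    n = len(dm.species_ids)
    if n < 2:
        raise ValueError("need at least 2 species for a dendrogram")
    Z = linkage(squareform(dm.d, checks=False), method="average")
    heights = np.zeros(2 * n - 1)
    heights[n:] = Z[:, 2] / 2.0  # tips at half the cophenetic distance
    tip_sets = np.zeros((2 * n - 1, n), dtype=bool)
    tip_sets[:n] = np.eye(n, dtype=bool)
    edge_child = np.empty(2 * n - 2, dtype=int)
    edge_length = np.empty(2 * n - 2)
    e = 0
    for j in range(n - 1):
        parent = n + j
        for child in (int(Z[j, 0]), int(Z[j, 1])):
            tip_sets[parent] |= tip_sets[child]
            edge_child[e] = child
            edge_length[e] = heights[parent] - heights[child]
            e += 1
    return Dendrogram(list(dm.species_ids), Z, heights, edge_child,
                      np.clip(edge_length, 0.0, None), tip_sets)


def fad(present: Iterable[str] | np.ndarray, dm: DistanceMatrix) -> float:
    """Functional attribute diversity: sum of pairwise distances among the
    species present. Zero for a single species."""
    m = dm.mask(present)
    if not m.any():
        raise ValueError("empty community")
    sub = dm.d[np.ix_(m, m)]
    return float(sub.sum() / 2.0)


def fd_branch_length(present: Iterable[str] | np.ndarray, dg: Dendrogram,
                     include_root: bool = False) -> float:
    """Dendrogram FD: branch length of the minimal subtree of the pool
    dendrogram spanning the species present.

    By default no path above the species' last common merge is counted, so
    a monoculture has FD = 0 and the full pool recovers the tree's total
    branch length. ``include_root=True`` adds the path from the spanning
    subtree up to the root (a variant in use elsewhere in the FD
    literature)."""
    n = len(dg.species_ids)
    if isinstance(present, np.ndarray) and present.dtype == bool:
        m = present
    else:
        pos = {s: i for i, s in enumerate(dg.species_ids)}
        m = np.zeros(n, dtype=bool)
        for s in present:
            if s not in pos:
                raise KeyError(f"unknown species {s!r}")
            m[pos[s]] = True
    total = int(m.sum())
    if total == 0:
        raise ValueError("empty community")
    # present tips below each edge (int cast: bool @ bool is a logical OR)
    counts = dg.tip_sets[dg.edge_child].astype(np.int64) @ m.astype(np.int64)
    keep = counts > 0 if include_root else (counts > 0) & (counts < total)
    return float(dg.edge_length[keep].sum())


def rao_q(abund: np.ndarray, dm: DistanceMatrix, ordered: bool = False,
          squared: bool = False) -> float:
    """Rao's quadratic entropy Q = Σ_{i<j} d_ij p_i p_j over the full
    species vector ``abund`` (absent species have abundance 0).

    ``ordered=True`` doubles the sum (the ordered-pair convention);
    ``squared=True`` substitutes d²/2 for d. Unnormalized abundances are
    normalized with a notice."""
    p = np.asarray(abund, dtype=float)
    if p.shape != (len(dm.species_ids),):
        raise ValueError("abundance vector length must match the species pool")
    if np.any(p < 0):
        raise ValueError("negative abundance")
    s = p.sum()
    if s <= 0:
        raise ValueError("empty community")
    if abs(s - 1.0) > 1e-8:
        warnings.warn("abundances not normalized; normalizing to sum 1",
                      RuntimeWarning)
        p = p / s
    d = dm.d ** 2 / 2.0 if squared else dm.d
    q = float(p @ d @ p) / 2.0
    return 2.0 * q if ordered else q


def fdis(abund: np.ndarray, tm: TraitMatrix, subset: Sequence[int | str] | None = None
         ) -> float:
    """Functional dispersion: abundance-weighted mean distance of species
    to the abundance-weighted centroid in (subset) trait space."""
    if not tm.is_standardized():
        raise ValueError("fdis requires standardized traits")
    if subset is None:
        idx = tuple(range(tm.n_traits))
    else:
        idx = resolve_subset(subset, tm.trait_names)
    p = np.asarray(abund, dtype=float)
    if p.shape != (tm.n_species,):
        raise ValueError("abundance vector length must match the species pool")
    if np.any(p < 0):
        raise ValueError("negative abundance")
    s = p.sum()
    if s <= 0:
        raise ValueError("empty community")
    p = p / s
    X = tm.values[:, idx]
    c = p @ X
    dist = np.linalg.norm(X - c, axis=1)
    return float(p @ dist)


# ---------------------------------------------------------------------------
# Vectorized multi-community core (shared with the complete search)
# ---------------------------------------------------------------------------

def community_index_table(X_sub: np.ndarray, presence: np.ndarray,
                          rel_abund: np.ndarray,
                          indices: Sequence[str] = ALL_INDICES,
                          include_root: bool = False) -> dict[str, np.ndarray]:
    """All requested indices for every community at once.

    ``X_sub`` is the standardized pool trait matrix restricted to one
    subset (n × k); ``presence`` (m × n boolean) and ``rel_abund`` (m × n,
    rows summing to 1) describe the communities.
    """
    out: dict[str, np.ndarray] = {}
    need_d = any(i in indices for i in ("fad", "q", "fd"))
    if need_d:
        D = squareform(pdist(X_sub, metric="euclidean"))
    P = presence.astype(float)
    if "fad" in indices:
        out["fad"] = np.einsum("ci,ij,cj->c", P, D, P) / 2.0
    if "q" in indices:
        out["q"] = np.einsum("ci,ij,cj->c", rel_abund, D, rel_abund) / 2.0
    if "fdis" in indices:
        C = rel_abund @ X_sub
        diff = X_sub[None, :, :] - C[:, None, :]
        out["fdis"] = np.einsum("ci,ci->c", rel_abund, np.linalg.norm(diff, axis=2))
    if "fd" in indices:
        n = X_sub.shape[0]
        Z = linkage(squareform(D, checks=False), method="average")
        heights = np.zeros(2 * n - 1)
        heights[n:] = Z[:, 2] / 2.0
        tip_sets = np.zeros((2 * n - 1, n), dtype=bool)
        tip_sets[:n] = np.eye(n, dtype=bool)
        edge_child = np.empty(2 * n - 2, dtype=int)
        edge_length = np.empty(2 * n - 2)
        e = 0
        for j in range(n - 1):
            parent = n + j
            for child in (int(Z[j, 0]), int(Z[j, 1])):
                tip_sets[parent] |= tip_sets[child]
                edge_child[e] = child
                edge_length[e] = heights[parent] - heights[child]
                e += 1
        edge_length = np.clip(edge_length, 0.0, None)
        counts = tip_sets[edge_child].astype(np.int32) @ presence.T.astype(np.int32)
        totals = presence.sum(axis=1).astype(np.int32)
        if include_root:
            keep = counts > 0
        else:
            keep = (counts > 0) & (counts < totals[None, :])
        out["fd"] = edge_length @ keep
    return out


def fd_profile(cm: CommunityMatrix, tm: TraitMatrix,
               subset: Sequence[int | str] | None = None,
               indices: Sequence[str] = ALL_INDICES,
               include_root: bool = False) -> pd.DataFrame:
    """Per-community table of the requested indices plus species richness
    for one trait subset (or for PC pseudo-traits when ``tm`` holds PC
    scores). Traits are standardized internally over the full pool if
    needed."""
    for ix in indices:
        if ix not in ALL_INDICES:
            raise ValueError(f"unknown index {ix!r}")
    cm = cm.reconcile(tm)
    # PC pseudo-traits are used as-is: their per-axis variances (the
    # eigenvalues) carry the rotation isometry and must not be rescaled
    if tm.meta.get("pc_scores") or tm.is_standardized():
        tms = tm
    else:
        tms = standardize_traits(tm)
    if subset is None:
        idx = tuple(range(tms.n_traits))
    else:
        idx = resolve_subset(subset, tms.trait_names)
    presence = cm.presence()
    rel = cm.relative_abundances()
    vals = community_index_table(tms.values[:, idx], presence, rel, indices,
                                 include_root)
    df = pd.DataFrame(index=pd.Index(cm.community_ids, name="community"))
    df["richness"] = presence.sum(axis=1)
    for ix in indices:
        df[ix] = vals[ix]
    df.attrs["trait_subset"] = tuple(tms.trait_names[j] for j in idx)
    return df
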