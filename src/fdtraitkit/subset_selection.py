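"""Trait-subset selection by matrix-correlation criteria.

Three criteria score how well a k-trait subset represents the full
standardized trait matrix X (n species × p traits), all expressed through
principal submatrices of S = (1/n)XᵗX and its square:

* RM  = sqrt( tr([S²]_(κ) S_κ⁻¹) / tr(S) ) — the matrix correlation
  between X and its orthogonal projection onto the subset's span;
  100·RM² is the percentage of total trait variation the subset retains.
* GCD = tr([S_{G}]_(κ) S_κ⁻¹) / sqrt(g·k) — Yanai's generalized
  coefficient of determination between the subset's span and the span of
  the g principal components indexed by G.
* RV  = sqrt( tr( ([S²]_(κ) S_κ⁻¹)² ) ) / sqrt( tr(S²) ) — the
  configuration similarity between XXᵗ and its subset-projected
  counterpart, invariant to rotation and global scaling.

Two further selection routes: the highest-loadings (HL) rule picks, for
each leading principal component, the trait with the largest absolute
loading; the PC route replaces traits with principal-component scores
(pseudo-traits) entirely.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import TraitMatrix, resolve_subset

__all__ = [
    "CriterionWorkspace",
    "SubsetScore",
    "build_workspace",
    "rm_coefficient",
    "gcd_coefficient",
    "rv_coefficient",
    "score_subset_all_criteria",
    "best_subset",
    "highest_loading_subset",
    "pc_scores",
]

EXHAUSTIVE_CAP = 15  # traits; beyond this the annealing search takes over


@dataclass
class CriterionWorkspace:
    """Cached spectral quantities for fast subset scoring."""

    X: np.ndarray
    S: np.ndarray
    S2: np.ndarray
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # columns matched to eigenvalues
    trait_names: list[str]

    @property
    def p(self) -> int:
        return self.S.shape[0]


def build_workspace(tm: TraitMatrix) -> CriterionWorkspace:
    """Precompute S, S² and the eigenstructure of S for a standardized
    trait matrix. Rejects unstandardized input."""
    if not tm.is_standardized():
        raise ValueError("build_workspace requires a z-standardized TraitMatrix")
    X = tm.values
    n = X.shape[0]
    S = (X.T @ X) / n
    ev, vec = np.linalg.eigh(S)
    ev = ev[::-1]
    vec = vec[:, ::-1]
    return CriterionWorkspace(X, S, S @ S, np.clip(ev, 0.0, None), vec,
                              list(tm.trait_names))


@dataclass
class SubsetScore:
    subset: tuple[str, ...]
    criterion: str
    value: float
    pc_set: tuple[int, ...] | None = None  # 0-based PC indices (GCD only)
    pct_variation: float | None = None     # 100·RM² of the subset


def _sub_inv(ws: CriterionWorkspace, idx: tuple[int, ...]) -> np.ndarray:
    """Inverse of the principal submatrix S_κ, falling back to the
    Moore-Penrose pseudo-inverse for collinear subsets."""
    S_k = ws.S[np.ix_(idx, idx)]
    try:
        c = np.linalg.cond(S_k)
    except np.linalg.LinAlgError:
        c = np.inf
    if not np.isfinite(c) or c > 1e12:
        warnings.warn("collinear trait subset; using pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(S_k, rcond=1e-12)
    return np.linalg.inv(S_k)


def _resolve(ws: CriterionWorkspace, subset: Sequence[int | str]) -> tuple[int, ...]:
    return resolve_subset(subset, ws.trait_names)


def rm_coefficient(ws: CriterionWorkspace, subset: Sequence[int | str]) -> float:
    """Variance retained by the subset: matrix correlation between X and
    its projection onto the subset's span, in [0, 1]."""
    idx = _resolve(ws, subset)
    num = float(np.trace(ws.S2[np.ix_(idx, idx)] @ _sub_inv(ws, idx)))
    val = np.sqrt(max(num, 0.0) / np.trace(ws.S))
    return float(np.clip(val, 0.0, 1.0))


def gcd_coefficient(ws: CriterionWorkspace, subset: Sequence[int | str],
                    pc_set: Sequence[int]) -> float:
    """Closeness between the subset's span and the span of the principal
    components indexed by ``pc_set`` (0-based), in [0, 1]."""
    idx = _resolve(ws, subset)
    G = tuple(int(g) for g in pc_set)
    if len(G) == 0:
        raise ValueError("empty PC set")
    if len(set(G)) != len(G):
        raise ValueError("repeated PC index")
    if min(G) < 0 or max(G) >= ws.p:
        raise IndexError("PC index out of range")
    V = ws.eigenvectors[:, G]
    S_G = (V * ws.eigenvalues[list(G)]) @ V.T
    num = float(np.trace(S_G[np.ix_(idx, idx)] @ _sub_inv(ws, idx)))
    val = num / np.sqrt(len(G) * len(idx))
    return float(np.clip(val, 0.0, 1.0))


def rv_coefficient(ws: CriterionWorkspace, subset: Sequence[int | str]) -> float:
    """Similarity of the full and subset-projected species configurations
    (translation/rotation/scale invariant), in [0, 1]."""
    idx = _resolve(ws, subset)
    M = ws.S2[np.ix_(idx, idx)] @ _sub_inv(ws, idx)
    num = np.sqrt(max(float(np.trace(M @ M)), 0.0))
    val = num / np.sqrt(float(np.trace(ws.S2)))
    return float(np.clip(val, 0.0, 1.0))


def score_subset_all_criteria(ws: CriterionWorkspace,
                              subset: Sequence[int | str],
                              pc_set: Sequence[int] | None = None
                              ) -> dict[str, SubsetScore]:
    """RM, GCD and RV for one user-supplied subset (e.g. the HL subset).

    ``pc_set`` defaults to the first k principal components, k the subset
    size."""
    idx = _resolve(ws, subset)
    names = tuple(ws.trait_names[j] for j in idx)
    if pc_set is None:
        pc_set = tuple(range(len(idx)))
    rm = rm_coefficient(ws, idx)
    pct = 100.0 * rm * rm
    return {
        "RM": SubsetScore(names, "RM", rm, None, pct),
        "GCD": SubsetScore(names, "GCD", gcd_coefficient(ws, idx, pc_set),
                           tuple(pc_set), pct),
        "RV": SubsetScore(names, "RV", rv_coefficient(ws, idx), None, pct),
    }


def _criterion_fn(ws, criterion: str, pc_set):
    criterion = criterion.upper()
    if criterion == "RM":
        return lambda idx: rm_coefficient(ws, idx)
    if criterion == "RV":
        return lambda idx: rv_coefficient(ws, idx)
    if criterion == "GCD":
        if pc_set is None:
            raise ValueError("GCD requires a pc_set")
        return lambda idx: gcd_coefficient(ws, idx, pc_set)
    raise ValueError(f"unknown criterion {criterion!r}")


def best_subset(ws: CriterionWorkspace, k: int, criterion: str,
                pc_set: Sequence[int] | None = None,
                search: str = "exhaustive", seed: int | None = None,
                cap: int = EXHAUSTIVE_CAP) -> SubsetScore:
    """Size-k subset maximizing one criterion.

    ``search='exhaustive'`` scans all C(p, k) subsets (requires p <= cap);
    ``search='anneal'`` is a seeded simulated-annealing fallback for large
    p. Ties break to the lexicographically smallest subset.
    """
    if not 1 <= k <= ws.p:
        raise ValueError(f"k={k} infeasible for p={ws.p}")
    if criterion.upper() == "GCD" and pc_set is None:
        pc_set = tuple(range(k))
    fn = _criterion_fn(ws, criterion, pc_set)
    if search == "exhaustive":
        if ws.p > cap:
            raise ValueError(
                f"exhaustive search with p={ws.p} exceeds the cap ({cap}); "
                "use search='anneal'"
            )
        best_idx, best_val = None, -np.inf
        for idx in itertools.combinations(range(ws.p), k):
            v = fn(idx)
            if v > best_val + 1e-12:
                best_idx, best_val = idx, v
    elif search == "anneal":
        best_idx, best_val = _anneal(ws, k, fn, seed)
    else:
        raise ValueError(f"unknown search {search!r}")
    names = tuple(ws.trait_names[j] for j in best_idx)
    rm = rm_coefficient(ws, best_idx)
    return SubsetScore(names, criterion.upper(), float(best_val),
                       tuple(pc_set) if pc_set is not None else None,
                       100.0 * rm * rm)


def _anneal(ws, k: int, fn, seed, n_restarts: int = 5, n_steps: int = 400,
            t0: float = 0.1, cooling: float = 0.99):
    # swap-one-trait neighborhood, geometric cooling, several restarts
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        warnings.warn(f"anneal without seed; generated seed={seed}", RuntimeWarning)
    rng = np.random.default_rng(seed)
    best_idx, best_val = None, -np.inf
    for _ in range(n_restarts):
        cur = tuple(sorted(rng.choice(ws.p, size=k, replace=False).tolist()))
        cur_val = fn(cur)
        if cur_val > best_val:
            best_idx, best_val = cur, cur_val
        t = t0
        for _ in range(n_steps):
            inside = list(cur)
            outside = [j for j in range(ws.p) if j not in cur]
            if not outside:
                break
            i = int(rng.integers(len(inside)))
            o = int(rng.integers(len(outside)))
            cand = tuple(sorted(inside[:i] + inside[i + 1:] + [outside[o]]))
            cand_val = fn(cand)
            if cand_val >= cur_val or rng.random() < np.exp((cand_val - cur_val) / t):
                cur, cur_val = cand, cand_val
                if cur_val > best_val or (cur_val == best_val and cur < best_idx):
                    best_idx, best_val = cur, cur_val
            t *= cooling
    return best_idx, best_val


def highest_loading_subset(tm: TraitMatrix, k: int) -> tuple[str, ...]:
    """For each of the first k principal components, the trait with the
    largest absolute loading. Duplicate picks collapse, so fewer than k
    traits may be returned; within-component ties go to the smaller trait
    index. Loading sign is ignored."""
    if k > tm.n_traits:
        raise ValueError(f"k={k} exceeds p={tm.n_traits}")
    ws = build_workspace(tm if tm.is_standardized() else _std(tm))
    picks: list[int] = []
    for comp in range(k):
        j = int(np.argmax(np.abs(ws.eigenvectors[:, comp])))
        if j not in picks:
            picks.append(j)
    picks.sort()
    return tuple(ws.trait_names[j] for j in picks)


def pc_scores(tm: TraitMatrix, k: int) -> TraitMatrix:
    """First k principal-component scores as a pseudo-trait matrix
    (columns PC1..PCk). Cumulative explained variance is recorded in the
    metadata. Scores are usable anywhere a TraitMatrix is."""
    tms = tm if tm.is_standardized() else _std(tm)
    ws = build_workspace(tms)
    rank = int(np.sum(ws.eigenvalues > 1e-10))
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank of the trait matrix ({rank})")
    V = ws.eigenvectors[:, :k].copy()
    # deterministic sign: largest-|loading| entry of each axis made positive
    for j in range(k):
        a = int(np.argmax(np.abs(V[:, j])))
        if V[a, j] < 0:
            V[:, j] = -V[:, j]
    scores = tms.values @ V
    cumvar = 100.0 * float(ws.eigenvalues[:k].sum()) / float(ws.eigenvalues.sum())
    meta = {"pc_scores": True, "cum_pct_variance": cumvar,
            "loadings": V, "source_traits": list(tms.trait_names)}
    return TraitMatrix(list(tms.species_ids), [f"PC{j + 1}" for j in range(k)],
                       scores, meta)


def _std(tm: TraitMatrix) -> TraitMatrix:
    from .data_model import standardize_traits
    return standardize_traits(tm)
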