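"""Associating functional diversity with an ecosystem property.

Each index is regressed (OLS) on per-community species richness; the
coefficient of determination R² ("closeness of association", COD) is the
figure of merit. The complete search evaluates every nonempty trait
subset, yielding a COD landscape, per-index best subsets, and by-size
summaries. A two-way ANOVA (method × index, datasets as replicates) with
per-index Tukey HSD compact-letter groups compares the selection methods
against the complete-search benchmark.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_model import CommunityMatrix, TraitMatrix, standardize_traits
from .functional_diversity import ALL_INDICES, community_index_table
from .subset_selection import (best_subset, build_workspace,
                               highest_loading_subset, pc_scores)

__all__ = [
    "AssociationResult",
    "SearchResult",
    "MethodComparison",
    "species_richness",
    "linear_cod",
    "p_bin",
    "P_BIN_LABELS",
    "complete_search",
    "run_method",
    "compare_methods",
    "METHODS",
]

METHODS = ("PC", "RM", "GCD", "RV", "HL", "CS")

# six significance classes used to color the COD landscape
P_BIN_LABELS = (
    "P<=1e-20",
    "1e-20<P<=1e-11",
    "1e-11<P<=1e-5",
    "1e-5<P<=0.01",
    "0.01<P<=0.05",
    "P>0.05",
)
_P_EDGES = (1e-20, 1e-11, 1e-5, 0.01, 0.05)


def p_bin(p: float) -> str:
    """Assign a p-value to one of six ordered significance classes."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    for edge, label in zip(_P_EDGES, P_BIN_LABELS):
        if p <= edge:
            return label
    return P_BIN_LABELS[-1]


@dataclass
class AssociationResult:
    index: str
    trait_subset: tuple[str, ...]
    n: int
    slope: float
    intercept: float
    cod: float
    p_value: float
    p_bin: str
    degenerate: bool = False


def species_richness(cm: CommunityMatrix) -> np.ndarray:
    """Species with positive abundance, per community."""
    return cm.presence().sum(axis=1)


def linear_cod(x: np.ndarray, y: np.ndarray, index: str = "",
               trait_subset: tuple[str, ...] = ()) -> AssociationResult:
    """OLS of an index on richness: slope, intercept, R² and the two-sided
    p-value of the slope. A constant index is flagged degenerate (COD
    recorded as 0) rather than failing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x and y with at least 3 communities")
    if np.ptp(x) == 0:
        raise ValueError("richness is constant; association undefined")
    if np.ptp(y) == 0:
        return AssociationResult(index, trait_subset, x.size, 0.0, float(y[0]),
                                 0.0, 1.0, P_BIN_LABELS[-1], degenerate=True)
    res = sps.linregress(x, y)
    cod = float(res.rvalue ** 2)
    p = float(np.clip(res.pvalue, np.finfo(float).tiny, 1.0))
    return AssociationResult(index, trait_subset, x.size, float(res.slope),
                             float(res.intercept), cod, p, p_bin(p))


@dataclass
class SearchResult:
    """Complete-search output: one row per (subset, index)."""

    table: pd.DataFrame          # subset, size, index, cod, slope, p, p_bin
    best: dict[str, pd.Series]   # per-index argmax row
    by_size: pd.DataFrame        # per (size, index): mean/sd/max of cod
    trait_names: tuple[str, ...]


def complete_search(tm: TraitMatrix, cm: CommunityMatrix,
                    indices=ALL_INDICES, k_range=None,
                    max_p: int = 15, include_root: bool = False) -> SearchResult:
    """Evaluate every nonempty trait subset against species richness.

    Enumerates all 2^p − 1 subsets (optionally only sizes in ``k_range``),
    computes the requested indices per community, regresses each on
    richness, and collects the full COD landscape with per-index best
    subsets (ties to the smaller, then lexicographically smallest subset)
    and by-size summaries. Degenerate regressions keep a row but their COD
    is excluded from the summaries.
    """
    if tm.n_traits > max_p:
        raise ValueError(
            f"p={tm.n_traits} exceeds the complete-search cap ({max_p}); "
            "raise max_p explicitly to override"
        )
    cm = cm.reconcile(tm)
    tms = tm if tm.is_standardized() else standardize_traits(tm)
    presence = cm.presence()
    rel = cm.relative_abundances()
    rich = presence.sum(axis=1).astype(float)
    p = tms.n_traits
    sizes = range(1, p + 1) if k_range is None else k_range
    rows = []
    for k in sizes:
        for idx in itertools.combinations(range(p), k):
            names = tuple(tms.trait_names[j] for j in idx)
            vals = community_index_table(tms.values[:, list(idx)], presence, rel,
                                         indices, include_root)
            for ix in indices:
                r = linear_cod(rich, vals[ix], ix, names)
                rows.append((";".join(names), k, ix, np.nan if r.degenerate else r.cod,
                             r.slope, r.p_value, r.p_bin, r.degenerate))
    table = pd.DataFrame(rows, columns=["subset", "size", "index", "cod",
                                        "slope", "p_value", "p_bin", "degenerate"])
    best = {}
    for ix in indices:
        sub = table[(table["index"] == ix) & ~table["degenerate"]]
        if len(sub):
            # max cod; ties -> smaller subset, then lexicographic
            top = sub[np.isclose(sub["cod"], sub["cod"].max(), atol=1e-12)]
            top = top.sort_values(["size", "subset"], kind="stable")
            best[ix] = top.iloc[0]
    by_size = (table.dropna(subset=["cod"])
               .groupby(["size", "index"])["cod"]
               .agg(["mean", "std", "max", "count"])
               .reset_index())
    return SearchResult(table, best, by_size, tuple(tms.trait_names))


def run_method(tm: TraitMatrix, cm: CommunityMatrix, method: str, k: int,
               indices=ALL_INDICES, pc_set=None, search: str = "exhaustive",
               seed: int | None = None, include_root: bool = False
               ) -> dict[str, AssociationResult]:
    """Select a trait subset (or PC scores) by one method, compute the
    indices and regress each on richness.

    Methods: ``PC`` (first k principal-component scores as pseudo-traits),
    ``RM``/``GCD``/``RV`` (best size-k subset by that criterion), ``HL``
    (highest loadings on the first k components).
    """
    method = method.upper()
    cm = cm.reconcile(tm)
    tms = tm if tm.is_standardized() else standardize_traits(tm)
    presence = cm.presence()
    rel = cm.relative_abundances()
    rich = presence.sum(axis=1).astype(float)
    if method == "PC":
        scores = pc_scores(tms, k)
        X_sub = scores.values
        names = tuple(scores.trait_names)
    elif method in ("RM", "GCD", "RV"):
        ws = build_workspace(tms)
        score = best_subset(ws, k, method, pc_set=pc_set, search=search, seed=seed)
        names = score.subset
        X_sub = tms.values[:, [tms.trait_names.index(t) for t in names]]
    elif method == "HL":
        names = highest_loading_subset(tms, k)
        X_sub = tms.values[:, [tms.trait_names.index(t) for t in names]]
    else:
        raise ValueError(f"unknown method {method!r} (CS is run via complete_search)")
    vals = community_index_table(X_sub, presence, rel, indices, include_root)
    return {ix: linear_cod(rich, vals[ix], ix, names) for ix in indices}


@dataclass
class MethodComparison:
    long: pd.DataFrame           # dataset, method, index, cod
    anova: pd.DataFrame          # two-way ANOVA table (type II)
    letters: dict[str, dict[str, str]]  # index -> method -> letter group
    alpha: float


def compare_methods(long: pd.DataFrame, alpha: float = 0.05) -> MethodComparison:
    """Two-way fixed-effects ANOVA of COD on method and index with their
    interaction, datasets as replicates, plus per-index Tukey HSD groups
    rendered as compact letters.

    ``long`` needs columns dataset, method, index, cod with a complete
    method × index grid per dataset. The CS cell should carry each
    dataset's maximum COD over all subsets (the benchmark convention).
    """
    req = {"dataset", "method", "index", "cod"}
    if not req <= set(long.columns):
        raise ValueError(f"long table must have columns {sorted(req)}")
    if long["dataset"].nunique() < 2:
        raise ValueError("need at least 2 datasets as replicates")
    counts = long.groupby(["method", "index"])["cod"].count()
    if counts.nunique() != 1:
        raise ValueError("incomplete method × index grid")
    df = long.copy()
    model = smf.ols("cod ~ C(method) * C(index)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    letters: dict[str, dict[str, str]] = {}
    for ix, grp in df.groupby("index"):
        letters[str(ix)] = _tukey_letters(grp["cod"].to_numpy(),
                                          grp["method"].to_numpy(), alpha)
    return MethodComparison(df, anova, letters, alpha)


def _tukey_letters(values: np.ndarray, groups: np.ndarray, alpha: float
                   ) -> dict[str, str]:
    """Compact letter display from Tukey HSD (insert-and-absorb)."""
    labels = sorted(set(map(str, groups)))
    if len(labels) < 2:
        return {labels[0]: "a"}
    if np.ptp(values) == 0:
        return {g: "a" for g in labels}
    tk = pairwise_tukeyhsd(values, groups.astype(str), alpha=alpha)
    res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    different = {(str(r["group1"]), str(r["group2"])) for _, r in res.iterrows()
                 if bool(r["reject"])}

    def ok(g, members):
        return all((min(g, m), max(g, m)) not in different for m in members)

    # order groups by descending mean so "a" marks the top group
    means = {g: values[groups.astype(str) == g].mean() for g in labels}
    order = sorted(labels, key=lambda g: -means[g])
    sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in sets:
            if ok(g, s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    # absorb subsets
    sets = [s for i, s in enumerate(sets)
            if not any(s < t for j, t in enumerate(sets) if i != j)]
    out = {g: "" for g in labels}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in sorted(s):
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}
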