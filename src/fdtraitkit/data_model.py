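"""Core data containers and delimited-table I/O.

The whole toolkit operates on two tables: a species × trait matrix of
quantitative trait values and a community × species abundance matrix.
Traits are z-standardized over the full species pool before any distance
or criterion computation so that every trait carries the same weight and
measurement units drop out.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitMatrix",
    "CommunityMatrix",
    "CorrelationSummary",
    "read_trait_table",
    "read_community_table",
    "write_trait_table",
    "write_community_table",
    "aggregate_species_means",
    "standardize_traits",
    "trait_correlation_summary",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what}: {lab!r}")
        seen[lab] = 1


@dataclass
class TraitMatrix:
    """Species × quantitative-trait matrix.

    ``values[i, j]`` is the (mean) value of trait ``trait_names[j]`` for
    species ``species_ids[i]``. ``meta`` carries provenance such as
    simulation truth or standardization state.
    """

    species_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trait values must be a 2-D array")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 species, got {n}")
        if p < 1:
            raise ValueError("need at least 1 trait")
        if len(self.species_ids) != n or len(self.trait_names) != p:
            raise ValueError("label lengths do not match the value matrix")
        _check_unique(self.species_ids, "species ID")
        _check_unique(self.trait_names, "trait name")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite trait value for species {self.species_ids[bad[0]]!r}, "
                f"trait {self.trait_names[bad[1]]!r}"
            )

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def is_standardized(self, tol: float = 1e-6) -> bool:
        """True if every trait has mean ~0 and unit variance (either the
        n or the n-1 denominator is accepted)."""
        mu = self.values.mean(axis=0)
        if np.any(np.abs(mu) > tol):
            return False
        v1 = self.values.var(axis=0, ddof=1)
        v0 = self.values.var(axis=0, ddof=0)
        return bool(np.all(np.abs(v1 - 1.0) < tol) or np.all(np.abs(v0 - 1.0) < tol))

    def subset_columns(self, subset: Sequence[int]) -> np.ndarray:
        """Column view of the selected trait indices (0-based)."""
        idx = resolve_subset(subset, self.trait_names)
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.species_ids, name="species"),
            columns=self.trait_names,
        )


def resolve_subset(subset: Sequence[int | str], trait_names: Sequence[str]) -> tuple[int, ...]:
    """Normalize a trait subset given as 0-based indices or names into a
    strictly increasing tuple of 0-based indices."""
    if len(subset) == 0:
        raise ValueError("empty trait subset")
    idx: list[int] = []
    for item in subset:
        if isinstance(item, str):
            try:
                idx.append(trait_names.index(item))
            except ValueError:
                raise KeyError(f"unknown trait {item!r}") from None
        else:
            j = int(item)
            if not 0 <= j < len(trait_names):
                raise IndexError(f"trait index {j} out of range 0..{len(trait_names) - 1}")
            idx.append(j)
    out = tuple(sorted(set(idx)))
    if len(out) != len(idx):
        raise ValueError("repeated trait in subset")
    return out


@dataclass
class CommunityMatrix:
    """Community × species abundance matrix (nonnegative, each community
    contains at least one individual)."""

    community_ids: list[str]
    species_ids: list[str]
    abundances: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 2:
            raise ValueError("abundances must be a 2-D array")
        m, n = self.abundances.shape
        if len(self.community_ids) != m or len(self.species_ids) != n:
            raise ValueError("label lengths do not match the abundance matrix")
        _check_unique(self.community_ids, "community ID")
        _check_unique(self.species_ids, "species ID")
        neg = np.argwhere(self.abundances < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative abundance at community {self.community_ids[i]!r}, "
                f"species {self.species_ids[j]!r}"
            )
        empty = np.where(self.abundances.sum(axis=1) <= 0)[0]
        if empty.size:
            raise ValueError(f"empty community: {self.community_ids[empty[0]]!r}")

    @property
    def n_communities(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundances.shape[1]

    def relative_abundances(self) -> np.ndarray:
        """Rows normalized to sum to one."""
        return self.abundances / self.abundances.sum(axis=1, keepdims=True)

    def presence(self) -> np.ndarray:
        return self.abundances > 0

    def reconcile(self, tm: TraitMatrix) -> "CommunityMatrix":
        """Reorder species columns to match a TraitMatrix; species without
        trait data are an error, species absent from every community are
        padded with zero columns."""
        missing = [s for s in self.species_ids if s not in tm.species_ids]
        if missing:
            raise KeyError(f"species absent from the trait table: {missing}")
        pos = {s: j for j, s in enumerate(self.species_ids)}
        ab = np.zeros((self.n_communities, tm.n_species))
        for j, s in enumerate(tm.species_ids):
            if s in pos:
                ab[:, j] = self.abundances[:, pos[s]]
        return CommunityMatrix(list(self.community_ids), list(tm.species_ids), ab,
                               dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundances, index=pd.Index(self.community_ids, name="community"),
            columns=self.species_ids,
        )


@dataclass
class CorrelationSummary:
    """Pairwise Pearson correlation structure of the trait matrix and the
    share of significant unordered pairs at level ``alpha``."""

    trait_names: list[str]
    r_matrix: np.ndarray
    p_matrix: np.ndarray
    alpha: float
    pct_significant: float | None  # None when p < 2 traits (no pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_matrix, index=self.trait_names, columns=self.trait_names)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_delimited(source, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = _sniff_delimiter(source)
    return pd.read_csv(source, sep=delimiter, index_col=0, dtype=str,
                       skipinitialspace=True)


def _sniff_delimiter(source) -> str:
    if isinstance(source, (str, Path)):
        head = Path(source).read_text(encoding="utf-8").splitlines()[0]
    else:
        pos = source.tell()
        head = source.readline()
        source.seek(pos)
    return "\t" if head.count("\t") >= head.count(",") else ","


def _to_float(cell) -> float:
    # exact correctly-rounded parse (pandas' fast parser loses the last ulp)
    try:
        return float(cell)
    except (TypeError, ValueError):
        return float("nan")


def read_trait_table(source, delimiter: str | None = None,
                     missing: str = "error") -> TraitMatrix:
    """Read a species × trait table (first column species ID, header row).

    ``missing='error'`` (default) rejects any missing/non-numeric cell with
    its location; ``missing='drop'`` drops affected species rows.
    """
    df = _read_delimited(source, delimiter)
    num = df.map(_to_float)
    bad = num.isna()
    if bad.to_numpy().any():
        if missing == "drop":
            num = num.loc[~bad.any(axis=1)]
        else:
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric or missing trait value at species {df.index[i]!r}, "
                f"trait {df.columns[j]!r}"
            )
    return TraitMatrix(list(map(str, num.index)), list(map(str, num.columns)),
                       num.to_numpy(float))


def read_community_table(source, delimiter: str | None = None) -> CommunityMatrix:
    """Read a community × species abundance table (first column community ID)."""
    df = _read_delimited(source, delimiter)
    num = df.map(_to_float)
    bad = num.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric abundance at community {df.index[i]!r}, "
            f"species {df.columns[j]!r}"
        )
    return CommunityMatrix(list(map(str, num.index)), list(map(str, num.columns)),
                           num.to_numpy(float))


def write_trait_table(tm: TraitMatrix, path, delimiter: str = ",") -> None:
    tm.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")


def write_community_table(cm: CommunityMatrix, path, delimiter: str = ",") -> None:
    cm.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def aggregate_species_means(observations: pd.DataFrame,
                            species_col: str = "species",
                            trait_col: str = "trait",
                            value_col: str = "value") -> TraitMatrix:
    """Collapse long-format individual observations to species mean trait
    values. Every (species, trait) pair must be observed at least once."""
    wide = observations.pivot_table(index=species_col, columns=trait_col,
                                    values=value_col, aggfunc="mean")
    if wide.isna().to_numpy().any():
        i, j = np.argwhere(wide.isna().to_numpy())[0]
        raise ValueError(
            f"no observation for species {wide.index[i]!r}, trait {wide.columns[j]!r}"
        )
    return TraitMatrix(list(map(str, wide.index)), list(map(str, wide.columns)),
                       wide.to_numpy(float))


def standardize_traits(tm: TraitMatrix, ddof: int = 1) -> TraitMatrix:
    """z-transform every trait to mean 0 and unit variance.

    ``ddof`` selects the sample (1, default) or population (0) standard
    deviation; downstream subset criteria are invariant to the choice.
    """
    sd = tm.values.std(axis=0, ddof=ddof)
    const = np.where(sd <= 0)[0]
    if const.size:
        raise ValueError(f"constant trait cannot be standardized: "
                         f"{tm.trait_names[const[0]]!r}")
    z = (tm.values - tm.values.mean(axis=0)) / sd
    meta = dict(tm.meta)
    meta["standardized"] = True
    meta["sd_ddof"] = ddof
    return TraitMatrix(list(tm.species_ids), list(tm.trait_names), z, meta)


def trait_correlation_summary(tm: TraitMatrix, alpha: float = 0.05) -> CorrelationSummary:
    """Pearson r and two-sided p for every unordered trait pair, plus the
    percentage of pairs significant at ``alpha``."""
    n, p = tm.values.shape
    if n < 3:
        raise ValueError("need at least 3 species for correlation tests")
    sd = tm.values.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        j = int(np.where(sd <= 0)[0][0])
        raise ValueError(f"constant trait: {tm.trait_names[j]!r}")
    r = np.corrcoef(tm.values, rowvar=False)
    r = np.atleast_2d(r)
    pm = np.ones((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            pm[i, j] = pm[j, i] = stats.pearsonr(tm.values[:, i], tm.values[:, j]).pvalue
    n_pairs = p * (p - 1) // 2
    if n_pairs == 0:
        pct = None
    else:
        iu = np.triu_indices(p, k=1)
        pct = 100.0 * float(np.sum(pm[iu] <= alpha)) / n_pairs
    return CorrelationSummary(list(tm.trait_names), r, pm, alpha, pct)
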