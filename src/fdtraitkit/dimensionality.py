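"""Intrinsic dimensionality of a trait matrix.

Three eigenvalue-based stopping rules applied to the trait correlation
matrix: Kaiser's rule (eigenvalues > 1), Horn's parallel analysis
(eigenvalues exceeding those of matched random normal data), and an
automated scree elbow (advisory). A simple majority consensus combines
them, with ties resolved in favor of parallel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import TraitMatrix

__all__ = [
    "EigenProfile",
    "DimensionalityReport",
    "correlation_eigenvalues",
    "kaiser_count",
    "parallel_analysis",
    "scree_elbow",
    "estimate_dimensionality",
]


@dataclass
class EigenProfile:
    """Descending eigenvalues of the p×p trait correlation matrix."""

    eigenvalues: np.ndarray
    total: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < -1e-10):
            raise ValueError("correlation eigenvalues cannot be negative")
        self.eigenvalues = np.clip(ev, 0.0, None)


@dataclass
class DimensionalityReport:
    kaiser_k: int
    pa_k: int
    pa_thresholds: np.ndarray
    scree_k: int | None
    consensus_k: int
    override_k: int | None
    n_iter: int
    quantile_rule: str
    seed: int


def correlation_eigenvalues(tm: TraitMatrix) -> EigenProfile:
    """Eigenvalues of the Pearson correlation matrix of the traits,
    descending. Their sum equals the number of traits."""
    sd = tm.values.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        j = int(np.where(sd <= 0)[0][0])
        raise ValueError(f"constant trait: {tm.trait_names[j]!r}")
    r = np.atleast_2d(np.corrcoef(tm.values, rowvar=False))
    ev = np.linalg.eigvalsh(r)[::-1]
    ev = np.clip(ev, 0.0, None)
    return EigenProfile(ev, float(ev.sum()))


def kaiser_count(ep: EigenProfile) -> int:
    """Number of correlation eigenvalues strictly greater than 1."""
    return int(np.sum(ep.eigenvalues > 1.0))


def parallel_analysis(tm: TraitMatrix, n_iter: int = 1000, rule: str = "mean",
                      seed: int = 0) -> tuple[int, np.ndarray]:
    """Horn's parallel analysis against uncorrelated standard-normal data.

    For each rank r the threshold is the mean (or 95th percentile, with
    ``rule='p95'``) of the r-th largest correlation eigenvalue over
    ``n_iter`` random n×p matrices. Components are retained from the top
    down while the observed eigenvalue exceeds its threshold; retention
    stops at the first failure.
    """
    if n_iter < 10:
        raise ValueError("parallel analysis needs n_iter >= 10")
    if rule not in ("mean", "p95"):
        raise ValueError(f"unknown rule {rule!r}")
    n, p = tm.values.shape
    if n < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iter, p))
    for b in range(n_iter):
        x = rng.standard_normal((n, p))
        r = np.atleast_2d(np.corrcoef(x, rowvar=False))
        sims[b] = np.linalg.eigvalsh(r)[::-1]
    if rule == "mean":
        thresholds = sims.mean(axis=0)
    else:
        thresholds = np.percentile(sims, 95, axis=0)
    observed = correlation_eigenvalues(tm).eigenvalues
    pa_k = 0
    for r_ in range(p):
        if observed[r_] > thresholds[r_]:
            pa_k = r_ + 1
        else:
            break
    return pa_k, thresholds


def scree_elbow(ep: EigenProfile) -> int | None:
    """Automated scree elbow: the number of components retained before the
    sharpest bend, located by the maximum second difference of the
    eigenvalue profile. Advisory only; ``None`` when p < 3."""
    ev = ep.eigenvalues
    p = ev.size
    if p < 3:
        return None
    # second difference at interior position i (1-based rank i+1)
    accel = ev[:-2] - 2.0 * ev[1:-1] + ev[2:]
    return int(np.argmax(accel)) + 1


def estimate_dimensionality(tm: TraitMatrix, n_iter: int = 1000,
                            rule: str = "mean", seed: int = 0,
                            override_k: int | None = None) -> DimensionalityReport:
    """All three stopping rules plus a majority consensus.

    The consensus is the value shared by at least two of the three rules;
    if all three disagree, parallel analysis decides. A user override is
    recorded alongside the consensus, never silently replacing it.
    """
    ep = correlation_eigenvalues(tm)
    kaiser_k = kaiser_count(ep)
    pa_k, thresholds = parallel_analysis(tm, n_iter=n_iter, rule=rule, seed=seed)
    scree_k = scree_elbow(ep)
    votes = [kaiser_k, pa_k] + ([scree_k] if scree_k is not None else [])
    consensus = pa_k
    for v in votes:
        if votes.count(v) >= 2:
            consensus = v
            break
    if override_k is not None and not 0 <= override_k <= tm.n_traits:
        raise ValueError("override_k out of range")
    return DimensionalityReport(kaiser_k, pa_k, thresholds, scree_k, consensus,
                                override_k, n_iter, rule, seed)
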