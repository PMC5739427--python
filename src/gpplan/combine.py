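"""Combining heterogeneous reference cohorts with selection-index theory.

A reference set often mixes close relatives, distant relatives and unrelated
population samples.  Each cohort k is modeled as its own information source
with an effective number of segments Me(k) (or an effective size Ne(k) it is
derived from), N_k records, a trait model, and a genetic correlation
rG(k,T) with the target.  The GBVs estimated from the separate cohorts are
combined as a selection index: with g the vector of covariances between each
cohort's GBV and the true breeding value and P their variance-covariance
matrix, the combined reliability is g' P^-1 g.

For same-trait cohorts that are random samples of one population (all
genetic correlations 1), the index reliability is identical to plugging the
sample-size-weighted harmonic Me,

    Me(weighted) = 1 / sum_k p_k / Me(k),   p_k = N_k / N_total,

together with N_total into the single-cohort reliability formula; both
routes are provided and agree to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .accuracy import (
    ConfigurationError,
    PredictionSetting,
    TraitModel,
    reliability_binary,
    reliability_gbv,
)
from .theory import GenomeModel, me_theoretical

__all__ = [
    "ReferenceSource",
    "SourceSet",
    "CombinedResult",
    "weighted_me",
    "combined_reliability_index",
    "combined_reliability_general",
    "combined_mixed_traits",
]


@dataclass(frozen=True)
class ReferenceSource:
    """One reference cohort.

    Exactly one of ``me`` / ``ne`` must be given; an ``ne`` is converted to
    Me through an explicit :class:`~gpplan.theory.GenomeModel` (default 30
    chromosomes of 1 Morgan) so the conversion is reproducible.
    ``rg_target`` is the genetic correlation between the cohort and the
    target set.  ``n_markers=None`` models a saturating marker panel (b=1).
    """

    label: str
    n_records: int
    trait: TraitModel
    me: Optional[float] = None
    ne: Optional[float] = None
    rg_target: float = 1.0
    n_markers: Optional[float] = None
    genome: Optional[GenomeModel] = None

    def __post_init__(self) -> None:
        if (self.me is None) == (self.ne is None):
            raise ConfigurationError(f"source {self.label!r}: supply exactly one of me / ne")
        if self.me is not None and not self.me > 0:
            raise ValueError(f"source {self.label!r}: me must be positive")
        if self.n_records < 1:
            raise ValueError(f"source {self.label!r}: n_records must be >= 1")
        if not (-1.0 <= self.rg_target <= 1.0):
            raise ValueError(f"source {self.label!r}: rg_target must be in [-1, 1]")

    @property
    def resolved_me(self) -> float:
        """Me of the cohort, converting from Ne if needed."""
        if self.me is not None:
            return self.me
        genome = self.genome or GenomeModel(effective_size=self.ne)
        if genome.effective_size != self.ne:
            raise ConfigurationError(
                f"source {self.label!r}: genome.effective_size disagrees with ne"
            )
        return me_theoretical(genome).me

    def reliability(self) -> float:
        """Single-cohort GBV reliability, binary-aware."""
        if self.trait.is_binary:
            return reliability_binary(self.resolved_me, self.n_records, self.trait)
        setting = PredictionSetting(
            me=self.resolved_me, n_records=self.n_records, trait=self.trait, n_markers=self.n_markers
        )
        return reliability_gbv(setting)


@dataclass(frozen=True)
class SourceSet:
    """An ordered collection of reference cohorts plus the matrix of genetic
    correlations between them (unit diagonal; default all ones)."""

    sources: Sequence[ReferenceSource]
    rg_between: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.sources) == 0:
            raise ValueError("SourceSet needs at least one source")
        if self.rg_between is not None:
            rg = np.asarray(self.rg_between, dtype=float)
            k = len(self.sources)
            if rg.shape != (k, k):
                raise ValueError(f"rg_between must be {k}x{k}, got {rg.shape}")
            if not np.allclose(rg, rg.T, atol=1e-12):
                raise ValueError("rg_between must be symmetric")
            if not np.allclose(np.diag(rg), 1.0, atol=1e-12):
                raise ValueError("rg_between must have unit diagonal")
            if np.any(np.abs(rg) > 1.0 + 1e-12):
                raise ValueError("rg_between entries must be in [-1, 1]")
            object.__setattr__(self, "rg_between", rg)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sources]

    @property
    def rg_matrix(self) -> np.ndarray:
        if self.rg_between is None:
            return np.ones((len(self.sources), len(self.sources)))
        return self.rg_between

    @property
    def all_unit_correlations(self) -> bool:
        return bool(
            np.allclose(self.rg_matrix, 1.0, atol=1e-12)
            and all(s.rg_target == 1.0 for s in self.sources)
        )


@dataclass(frozen=True)
class CombinedResult:
    """Combined-design outcome: reliability (r^2), its square-root accuracy,
    the weighted Me when the shortcut applies, and per-source reliabilities."""

    reliability: float
    accuracy: float
    per_source_reliability: list[float]
    weighted_me: Optional[float] = None


def weighted_me(source_set: SourceSet) -> float:
    """Sample-size-weighted harmonic Me: 1 / sum_k (p_k / Me(k)).

    Valid only for same-trait cohorts sampled at random from one population
    (all genetic correlations 1); otherwise the full index
    (:func:`combined_reliability_general`) must be used.
    """
    if not source_set.all_unit_correlations:
        raise ConfigurationError(
            "weighted_me assumes all genetic correlations are 1; "
            "use combined_reliability_general for correlated designs"
        )
    traits = {s.trait for s in source_set.sources}
    if len(traits) > 1:
        raise ConfigurationError("weighted_me requires all sources to share one trait model")
    n_total = sum(s.n_records for s in source_set.sources)
    inv = sum((s.n_records / n_total) / s.resolved_me for s in source_set.sources)
    return 1.0 / inv


def _solve_index(g: np.ndarray, p_mat: np.ndarray, labels: Sequence[str]) -> float:
    """g' P^-1 g via a symmetric positive-definite factorization."""
    try:
        cho = linalg.cho_factor(p_mat, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "selection-index matrix P is singular or not positive definite for sources "
            f"{list(labels)}: degenerate design (e.g. duplicated source or reliability 1)"
        ) from exc
    return float(g @ linalg.cho_solve(cho, g))


def combined_reliability_index(source_set: SourceSet) -> CombinedResult:
    """Combined reliability of same-population cohorts via the selection index.

    The index has g_i = r^2(i) (each cohort's own GBV reliability) and
    P_ii = r^2(i), P_ij = r^2(i) r^2(j): GBVs from independent random
    samples of the same population are correlated only through the true
    breeding value.  Identical (to numerical precision) to feeding the
    weighted Me and total N into the single-cohort reliability.
    """
    if not source_set.all_unit_correlations:
        raise ConfigurationError(
            "combined_reliability_index assumes unit genetic correlations; "
            "use combined_reliability_general"
        )
    r2 = np.array([s.reliability() for s in source_set.sources])
    if np.any(r2 <= 0.0) or np.any(r2 >= 1.0):
        raise ValueError("per-source reliabilities must be strictly inside (0, 1)")
    p_mat = np.outer(r2, r2)
    np.fill_diagonal(p_mat, r2)
    rel = _solve_index(r2, p_mat, source_set.labels)
    traits = {s.trait for s in source_set.sources}
    w_me = weighted_me(source_set) if len(traits) == 1 else None
    return CombinedResult(
        reliability=rel,
        accuracy=math.sqrt(rel),
        per_source_reliability=list(r2),
        weighted_me=w_me,
    )


def _general_index(source_set: SourceSet, r2: np.ndarray) -> float:
    """Index with genetic correlations: g_k = rG(k,T)^2 r^2(k);
    P_kk = rG(k,T)^2 r^2(k); P_ij = r^2(i) r^2(j) rG(i,j) rG(i,T) rG(j,T)."""
    rg_t = np.array([s.rg_target for s in source_set.sources])
    rg_between = source_set.rg_matrix
    # A source genetically uncorrelated with the target carries no signal and
    # makes the printed P singular (zero row/column); it is dropped, which
    # leaves the reliability unchanged.
    keep = rg_t != 0.0
    if not np.any(keep):
        return 0.0
    r2 = r2[keep]
    rg_t = rg_t[keep]
    rg_between = rg_between[np.ix_(keep, keep)]
    labels = [lab for lab, k in zip(source_set.labels, keep) if k]
    g = rg_t**2 * r2
    p_mat = np.outer(r2, r2) * rg_between * np.outer(rg_t, rg_t)
    np.fill_diagonal(p_mat, g)
    return _solve_index(g, p_mat, labels)


def combined_reliability_general(source_set: SourceSet) -> CombinedResult:
    """Combined reliability allowing genetic correlations below one.

    Generalizes the same-population index: reduces exactly to
    :func:`combined_reliability_index` when every correlation is 1, and a
    source with rG(k,T) = 0 contributes nothing.  Sources sharing
    individuals violate the independence encoded in the off-diagonals of P;
    no overlap correction is attempted.
    """
    r2 = np.array([s.reliability() for s in source_set.sources])
    if np.any(r2 <= 0.0) or np.any(r2 >= 1.0):
        raise ValueError("per-source reliabilities must be strictly inside (0, 1)")
    rel = _general_index(source_set, r2)
    w_me = weighted_me(source_set) if source_set.all_unit_correlations and len({s.trait for s in source_set.sources}) == 1 else None
    return CombinedResult(
        reliability=rel,
        accuracy=math.sqrt(rel),
        per_source_reliability=list(r2),
        weighted_me=w_me,
    )


def combined_mixed_traits(source_set: SourceSet) -> CombinedResult:
    """Combined reliability for designs mixing quantitative and binary cohorts.

    Binary cohorts enter the index through the liability-threshold profile
    score reliability (prevalence and case fraction required); quantitative
    cohorts through the standard GBV reliability.  With an all-quantitative
    set this is identical to :func:`combined_reliability_general`.
    """
    for s in source_set.sources:
        if s.trait.is_binary and (s.trait.prevalence is None or s.trait.case_fraction is None):
            raise ConfigurationError(
                f"binary source {s.label!r} needs both prevalence (K) and case_fraction (P)"
            )
    return combined_reliability_general(source_set)
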