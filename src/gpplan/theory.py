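"""Closed-form theory for the effective number of chromosome segments (Me).

The accuracy of genomic prediction is governed by how many effectively
independent chromosome segments segregate between a reference cohort and the
target individuals.  At drift-recombination equilibrium in a population of
effective size ``Ne``, the expected variance of the mean genomic relationship
over a single chromosome of length ``L`` Morgans is

    v(Ne, L) = [ln(2 Ne L + 1) + 2 Ne L (ln(2 Ne L + 1) - 1)] / (4 Ne^2 L^2)

which is the mean squared genotype correlation over all SNP pairs on the
chromosome (Sved's expected r^2 integrated over map distance, including
mutation).  Relationships at different chromosomes are correlated through the
shared pedigree, contributing an extra ``(Nchr - 1) / (3 Ne)`` term, so the
whole-genome effective number of segments is

    Me = Nchr / ( v + (Nchr - 1) / (3 Ne) )

and ``1 / Me`` equals the expected variance of whole-genome target-reference
genomic relationships.  For the standard 30-chromosome, 1-Morgan genome the
power law ``Me = 2.938 Ne^0.965`` (inverse ``Ne = 0.327 Me^1.036``) is a
convenient approximation accurate to within 5% for Ne in [10, 10000].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GenomeModel",
    "SegmentCount",
    "FamilyStructureMe",
    "chromosome_segment_variance",
    "me_theoretical",
    "me_powerlaw",
    "ne_from_me",
    "b_captured",
    "me_for_family_structure",
]

# Power-law coefficients fitted for a 30 x 1-Morgan genome.
_POWERLAW_COEF = 2.938
_POWERLAW_EXP = 0.965
_POWERLAW_INV_COEF = 0.327
_POWERLAW_INV_EXP = 1.036


@dataclass(frozen=True)
class GenomeModel:
    """Genome architecture and effective population size.

    Parameters
    ----------
    effective_size
        Effective population size Ne (diploid individuals), > 0.
    n_chromosomes
        Number of chromosomes Nchr, >= 1.  Default 30.
    chromosome_length
        Chromosome length in Morgans.  Either a single value shared by all
        chromosomes (the standard model) or a sequence of per-chromosome
        lengths (an extension; the per-chromosome variances are averaged).
        Default 1.0.
    """

    effective_size: float
    n_chromosomes: int = 30
    chromosome_length: float | Sequence[float] = 1.0

    def __post_init__(self) -> None:
        if not (self.effective_size > 0) or not math.isfinite(self.effective_size):
            raise ValueError(f"effective_size must be positive and finite, got {self.effective_size}")
        if int(self.n_chromosomes) != self.n_chromosomes or self.n_chromosomes < 1:
            raise ValueError(f"n_chromosomes must be a positive integer, got {self.n_chromosomes}")
        lengths = self.lengths
        if lengths.size not in (1, self.n_chromosomes):
            raise ValueError(
                f"chromosome_length has {lengths.size} entries but n_chromosomes={self.n_chromosomes}"
            )
        if np.any(lengths <= 0) or not np.all(np.isfinite(lengths)):
            raise ValueError("chromosome lengths must be positive and finite")

    @property
    def lengths(self) -> np.ndarray:
        """Per-chromosome lengths as an array (length 1 if scalar)."""
        return np.atleast_1d(np.asarray(self.chromosome_length, dtype=float))


@dataclass(frozen=True)
class SegmentCount:
    """Effective number of chromosome segments and its building blocks.

    ``me`` is the whole-genome effective number of segments; ``1/me`` is the
    expected variance of whole-genome target-reference relationships.
    ``per_chromosome_variance`` is the expected variance of the mean
    relationship over a single chromosome (averaged over chromosomes when
    lengths differ), i.e. 1/Me of one chromosome.
    """

    me: float
    per_chromosome_variance: float

    @property
    def relationship_variance(self) -> float:
        """Expected variance of whole-genome genomic relationships (= 1/me)."""
        return 1.0 / self.me


def _segment_variance_scalar(ne: float, length: float) -> float:
    a = 2.0 * ne * length
    log_term = math.log(a + 1.0)
    return (log_term + a * (log_term - 1.0)) / (4.0 * ne * ne * length * length)


def chromosome_segment_variance(genome: GenomeModel) -> float:
    """Expected variance of the mean relationship over one chromosome.

    Returns ``v = [ln(2NeL+1) + 2NeL(ln(2NeL+1) - 1)] / (4 Ne^2 L^2)``, the
    mean squared SNP-genotype correlation on a chromosome of length L at
    drift-recombination equilibrium; its inverse is the per-chromosome
    effective number of segments.  Strictly decreasing in Ne and in L.  With
    unequal chromosome lengths the per-chromosome variances are averaged.
    """
    ne = genome.effective_size
    vs = [_segment_variance_scalar(ne, L) for L in genome.lengths]
    return float(np.mean(vs))


def me_theoretical(genome: GenomeModel) -> SegmentCount:
    """Whole-genome effective number of chromosome segments.

    Me = Nchr / ( v + (Nchr - 1) / (3 Ne) ), where v is the per-chromosome
    relationship variance from :func:`chromosome_segment_variance`.  The
    second term is the cross-chromosome covariance of relationships induced
    by shared pedigree; with a single chromosome Me reduces to 1/v exactly.
    """
    v = chromosome_segment_variance(genome)
    nchr = int(genome.n_chromosomes)
    ne = genome.effective_size
    inv_me = (v + (nchr - 1) / (3.0 * ne)) / nchr
    return SegmentCount(me=1.0 / inv_me, per_chromosome_variance=v)


def me_powerlaw(ne: float) -> float:
    """Power-law approximation Me = 2.938 Ne^0.965 (Nchr=30, L=1 genome)."""
    if not ne > 0:
        raise ValueError(f"ne must be positive, got {ne}")
    return _POWERLAW_COEF * ne**_POWERLAW_EXP


def ne_from_me(me: float) -> float:
    """Effective population size implied by Me: Ne = 0.327 Me^1.036.

    Inverse of :func:`me_powerlaw`; round-trips to within 5% for Ne in
    [10, 10000] on the standard 30 x 1-Morgan genome.
    """
    if not me > 0:
        raise ValueError(f"me must be positive, got {me}")
    return _POWERLAW_INV_COEF * me**_POWERLAW_INV_EXP


def b_captured(n_markers: float, me: float) -> float:
    """Proportion of QTL variance captured by M markers: b = M / (Me + M).

    Tends to 1 as the marker count grows; increasing in M, decreasing in Me.
    ``n_markers`` may be ``math.inf`` to model a saturating panel (b = 1).
    """
    if not me > 0:
        raise ValueError(f"me must be positive, got {me}")
    if math.isinf(n_markers):
        return 1.0
    if n_markers < 1:
        raise ValueError(f"n_markers must be >= 1, got {n_markers}")
    return n_markers / (me + n_markers)


@dataclass(frozen=True)
class FamilyStructureMe:
    """Me and implied Ne for a family-structured reference set."""

    me: float
    ne: float
    relationship_variance: float
    within_family_fraction: float


def me_for_family_structure(
    n_families: int,
    sibs_per_family: int,
    kinship: float = 0.5,
    extra_within_variance: float = 0.0,
) -> FamilyStructureMe:
    """Me implied by a sib-family reference set, for a target inside one family.

    The target's relationship to a random reference member is a two-point
    mixture: ``kinship`` (0.5 full sibs, 0.25 half sibs) with probability
    p = 1 / n_families (the within-family fraction), 0 otherwise, giving
    var(G_Tj) = p (1 - p) kinship^2 and Me = 1 / var.  The implied Ne comes
    from the power-law inverse.  Mendelian sampling scatter around the
    expected kinship is excluded by default; pass ``extra_within_variance``
    (the within-class variance of realized relationships, weighted by p) to
    add it.
    """
    if n_families < 1 or sibs_per_family < 1:
        raise ValueError("need at least one family with at least one sib")
    if n_families * sibs_per_family < 2:
        raise ValueError("total reference size must be >= 2")
    if kinship not in (0.5, 0.25):
        raise ValueError(f"kinship must be 0.5 (full sibs) or 0.25 (half sibs), got {kinship}")
    p = 1.0 / n_families
    var = p * (1.0 - p) * kinship**2 + p * extra_within_variance
    if var <= 0.0:
        raise ValueError("infinite Me: homogeneous relationship (within-family fraction is 0 or 1)")
    me = 1.0 / var
    return FamilyStructureMe(
        me=me, ne=ne_from_me(me), relationship_variance=var, within_family_fraction=p
    )
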