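"""Empirical Me from genotypes or a genomic relationship matrix (GRM).

The GRM on standardized genotypes is G = X X' / M with
x = (dosage - 2f) / sqrt(2 f (1 - f)).  For a target individual T, the
variance of its relationships G_Tj across a reference sample estimates
1/Me of that reference with respect to T; the inverse of the aggregated
(median by default, since the per-target variance distribution is skewed)
variance is the empirical effective number of chromosome segments.  No
assumption of unrelatedness is needed: any random sample from the
population can serve as the reference, however related.

Per-chromosome Me is the inverse of the mean squared genotype correlation
over all SNP pairs on the chromosome (diagonal included), and per-chromosome
variances recombine into a whole-genome Me through the cross-chromosome
pedigree term (Nchr - 1) / (3 Ne).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "MeEstimate",
    "qc_filter",
    "build_grm",
    "cross_relationship_variance",
    "empirical_me",
    "per_chromosome_me",
    "combine_chromosome_variances",
    "split_reference_by_relatedness",
]

MISSING = -1  # sentinel for missing dosage


@dataclass
class GenotypeMatrix:
    """0/1/2-coded SNP dosages with a SNP -> chromosome map.

    ``dosage`` is individuals x SNPs, int8, with -1 marking missing calls.
    ``allele_frequency`` (per SNP, counted allele) is computed from the
    non-missing dosages unless supplied.  ``genetic_position`` is in
    Morgans within chromosome, optional.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    chromosome_of_snp: np.ndarray
    dosage: np.ndarray
    genetic_position: Optional[np.ndarray] = None
    allele_frequency: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.chromosome_of_snp = np.asarray(self.chromosome_of_snp, dtype=np.int32)
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError(f"{len(self.individual_ids)} ids for {n} dosage rows")
        if len(self.snp_ids) != m or self.chromosome_of_snp.size != m:
            raise ValueError("snp_ids / chromosome_of_snp length must match dosage columns")
        valid = (self.dosage == MISSING) | ((self.dosage >= 0) & (self.dosage <= 2))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def frequencies(self) -> np.ndarray:
        """Counted-allele frequency per SNP from non-missing dosages."""
        if self.allele_frequency is not None:
            return np.asarray(self.allele_frequency, dtype=float)
        d = self.dosage
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(obs, d, 0).sum(axis=0) / np.maximum(2 * n_obs, 1)
        f[n_obs == 0] = np.nan
        return f

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            snp_ids=[s for s, k in zip(self.snp_ids, mask) if k],
            chromosome_of_snp=self.chromosome_of_snp[mask],
            dosage=self.dosage[:, mask],
            genetic_position=None if self.genetic_position is None else self.genetic_position[mask],
            allele_frequency=None if self.allele_frequency is None else np.asarray(self.allele_frequency)[mask],
        )


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with individual IDs."""

    individual_ids: list[str]
    values: np.ndarray
    n_snps: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"GRM values must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric (tolerance 1e-8)")
        mean_diag = float(np.mean(np.diag(self.values)))
        if not (0.9 <= mean_diag <= 1.1):
            warnings.warn(
                f"mean GRM diagonal is {mean_diag:.3f}, outside [0.9, 1.1]; "
                "check genotype standardization",
                stacklevel=2,
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def indices_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"ids not present in GRM: {missing[:10]}")
        return np.array([lookup[i] for i in ids], dtype=np.intp)


@dataclass(frozen=True)
class MeEstimate:
    """Empirical Me: inverse of the aggregated per-target relationship variance."""

    me: float
    variance_used: float
    aggregation: str
    n_targets: int
    per_target_variances: np.ndarray


def qc_filter(
    genotypes: GenotypeMatrix,
    maf: float = 0.01,
    snp_call_rate: float = 0.95,
    individual_call_rate: float = 0.95,
    hwe_p: Optional[float] = None,
) -> GenotypeMatrix:
    """Marker/individual quality control.

    Drops individuals below ``individual_call_rate``, then SNPs below
    ``snp_call_rate`` or with minor allele frequency <= ``maf``.  If
    ``hwe_p`` is given, SNPs whose Hardy-Weinberg exact test p-value falls
    below it are also dropped.
    """
    d = genotypes.dosage
    obs = d != MISSING
    ind_keep = obs.mean(axis=1) > individual_call_rate
    g = GenotypeMatrix(
        individual_ids=[i for i, k in zip(genotypes.individual_ids, ind_keep) if k],
        snp_ids=genotypes.snp_ids,
        chromosome_of_snp=genotypes.chromosome_of_snp,
        dosage=d[ind_keep],
        genetic_position=genotypes.genetic_position,
    )
    obs = g.dosage != MISSING
    call = obs.mean(axis=0)
    f = g.frequencies()
    minor = np.minimum(f, 1.0 - f)
    snp_keep = (call > snp_call_rate) & (minor > maf)
    if hwe_p is not None:
        snp_keep &= _hwe_pvalues(g) >= hwe_p
    return g.subset_snps(snp_keep)


def _hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    """Chi-square (1 df) Hardy-Weinberg test p-value per SNP."""
    from scipy import stats

    d = genotypes.dosage
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)
    n_aa = ((d == 2) & obs).sum(axis=0)
    n_ab = ((d == 1) & obs).sum(axis=0)
    n_bb = ((d == 0) & obs).sum(axis=0)
    f = (2 * n_aa + n_ab) / np.maximum(2 * n, 1)
    exp = np.stack([n * (1 - f) ** 2, 2 * n * f * (1 - f), n * f**2])
    obs_counts = np.stack([n_bb, n_ab, n_aa]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((obs_counts - exp) ** 2 / np.where(exp > 0, exp, np.nan), axis=0)
    return stats.chi2.sf(chi2, df=1)


def _standardize_chunk(d: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Standardize a dosage chunk; missing entries contribute 0."""
    x = d.astype(float)
    x[d == MISSING] = np.nan
    x = (x - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    return np.nan_to_num(x, nan=0.0)


def build_grm(genotypes: GenotypeMatrix, chunk_size: int = 4096) -> GRM:
    """G = X X' / M on standardized genotypes, chunked over SNPs.

    Monomorphic SNPs are excluded from M; missing dosages are mean-imputed
    (they contribute 0 after centering).  Allele frequencies come from the
    full sample unless the genotype matrix carries its own.
    """
    f = genotypes.frequencies()
    poly = np.isfinite(f) & (f > 0.0) & (f < 1.0)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic: GRM undefined")
    n = genotypes.n_individuals
    g = np.zeros((n, n))
    cols = np.flatnonzero(poly)
    for lo in range(0, cols.size, chunk_size):
        idx = cols[lo : lo + chunk_size]
        x = _standardize_chunk(genotypes.dosage[:, idx], f[idx])
        g += x @ x.T
    g /= cols.size
    return GRM(individual_ids=list(genotypes.individual_ids), values=g, n_snps=int(cols.size))


def cross_relationship_variance(
    grm: GRM, target_ids: Sequence[str], reference_ids: Sequence[str]
) -> np.ndarray:
    """Per-target sample variance (ddof=1) of relationships to the reference.

    Target and reference id sets must be disjoint (a shared individual would
    contribute its own near-1 diagonal relationship).
    """
    overlap = set(target_ids) & set(reference_ids)
    if overlap:
        raise ValueError(f"target and reference sets overlap: {sorted(overlap)[:10]}")
    if len(reference_ids) < 2:
        raise ValueError("need at least 2 reference individuals")
    t_idx = grm.indices_of(target_ids)
    r_idx = grm.indices_of(reference_ids)
    sub = grm.values[np.ix_(t_idx, r_idx)]
    return sub.var(axis=1, ddof=1)


def empirical_me(
    grm: GRM,
    target_ids: Sequence[str],
    reference_ids: Sequence[str],
    aggregation: str = "median",
) -> MeEstimate:
    """Empirical Me = 1 / aggregate(per-target relationship variances).

    The default aggregation is the median: the per-target variance
    distribution is right-skewed (a handful of close relatives inflate a few
    targets), so the median is the more stable summary.
    """
    if aggregation not in ("median", "mean"):
        raise ValueError(f"aggregation must be 'median' or 'mean', got {aggregation!r}")
    variances = cross_relationship_variance(grm, target_ids, reference_ids)
    agg = float(np.median(variances) if aggregation == "median" else np.mean(variances))
    if agg <= 0.0:
        raise ValueError("infinite Me: aggregated relationship variance is zero")
    return MeEstimate(
        me=1.0 / agg,
        variance_used=agg,
        aggregation=aggregation,
        n_targets=len(target_ids),
        per_target_variances=variances,
    )


def per_chromosome_me(genotypes: GenotypeMatrix, chromosome: int) -> float:
    """Me of one chromosome: M_i^2 / sum over all SNP pairs of r^2.

    r is the empirical correlation between standardized genotype columns;
    the double sum includes the diagonal (r^2 = 1) terms, so a chromosome in
    perfect LD has Me = 1 and fully uncorrelated SNPs give Me = M_i.
    """
    mask = genotypes.chromosome_of_snp == chromosome
    d = genotypes.dosage[:, mask].astype(float)
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    sd = d.std(axis=0)
    poly = sd > 0
    d = d[:, poly]
    m = d.shape[1]
    if m < 2:
        raise ValueError(f"chromosome {chromosome} has fewer than 2 polymorphic SNPs")
    z = (d - d.mean(axis=0)) / d.std(axis=0)
    corr = z.T @ z / d.shape[0]
    return m * m / float(np.sum(corr**2))


def combine_chromosome_variances(per_chr_variances: Sequence[float], ne: float) -> float:
    """Whole-genome Me from per-chromosome relationship variances.

    1/Me = [mean(variances) + (Nchr - 1) / (3 Ne)] / Nchr; the second term is
    the cross-chromosome covariance of relationships through the pedigree.
    """
    variances = np.asarray(per_chr_variances, dtype=float)
    if variances.size < 1:
        raise ValueError("need at least one per-chromosome variance")
    if not ne > 0:
        raise ValueError(f"ne must be positive, got {ne}")
    nchr = variances.size
    inv_me = (variances.mean() + (nchr - 1) / (3.0 * ne)) / nchr
    return 1.0 / inv_me


def split_reference_by_relatedness(
    grm: GRM,
    target_ids: Sequence[str],
    thresholds: Sequence[float],
    fractions: Sequence[float],
    reference_ids: Optional[Sequence[str]] = None,
    seed: int | np.random.Generator = 0,
) -> list[list[str]]:
    """Partition a reference into relatedness tiers around a target set.

    Greedy tiers: tier k draws a random ``fractions[k]`` of the not-yet-
    assigned reference individuals whose *maximum* relationship to any
    target exceeds ``thresholds[k]`` (thresholds strictly descending); the
    remainder forms one final tier.  Deterministic for a given seed.
    Returns ``len(thresholds) + 1`` id lists.
    """
    thresholds = list(thresholds)
    fractions = list(fractions)
    if len(thresholds) != len(fractions):
        raise ValueError("thresholds and fractions must have the same length")
    if any(t1 <= t2 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly descending")
    if any(not (0.0 < f <= 1.0) for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    if reference_ids is None:
        reference_ids = [i for i in grm.individual_ids if i not in set(target_ids)]
    if len(reference_ids) == 0:
        raise ValueError("empty reference set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_idx = grm.indices_of(target_ids)
    r_idx = grm.indices_of(reference_ids)
    max_rel = grm.values[np.ix_(r_idx, t_idx)].max(axis=1)
    remaining = np.arange(len(reference_ids))
    tiers: list[list[str]] = []
    for thr, frac in zip(thresholds, fractions):
        eligible = remaining[max_rel[remaining] > thr]
        n_pick = int(round(frac * eligible.size))
        picked = rng.choice(eligible, size=n_pick, replace=False) if n_pick else np.array([], dtype=int)
        picked_set = set(picked.tolist())
        tiers.append([reference_ids[i] for i in sorted(picked_set)])
        remaining = np.array([i for i in remaining if i not in picked_set], dtype=int)
    tiers.append([reference_ids[i] for i in remaining])
    return tiers
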