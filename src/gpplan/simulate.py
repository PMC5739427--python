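"""Wright-Fisher gene-dropping simulator.

Forward-in-time transmission of founder haplotypes through discrete,
non-overlapping generations of constant effective size Ne.  Each offspring
draws two parents uniformly at random (with replacement) from the previous
generation; each transmitted gamete is built with a Poisson(L) number of
crossovers placed uniformly along the chromosome (Haldane's model, no
interference) and per-site mutation flips at the given rate.  Chromosomes
assort independently.  Founders start at linkage equilibrium with allele
frequencies drawn from Uniform(0.05, 0.95); LD then accrues over the burn-in
generations, so that after ~Ne generations the panel sits near
drift-recombination equilibrium and the variance of off-diagonal genomic
relationships matches 1/Me from the closed-form theory.

The final generation is expanded to ``final_sample_size`` offspring whose
parents are drawn from the last Ne-sized generation; this is the cohort the
relationship-variance analyses sample from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .grm import GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "HaplotypePanel",
    "founder_panel",
    "simulate",
    "simulate_families",
]

try:  # optional: identical semantics, much faster on large panels
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _copy_segments_py(haps, gametes, base_rows, other_rows, cuts, cut_offsets, b0, cb, ns):
    """Patch homologous-haplotype segments between sorted crossover cuts.

    Haplotypes are bit-packed 8 SNPs/byte (most significant bit first); one
    chromosome occupies bytes [b0, b0 + cb).  Gamete g carries the base
    haplotype except on alternating segments between its crossover cuts
    (local SNP indices), which come from the homolog; partial boundary bytes
    are blended with bit masks.
    """
    for g in range(base_rows.size):
        gametes[g, b0 : b0 + cb] = haps[base_rows[g], b0 : b0 + cb]
        c0, c1 = cut_offsets[g], cut_offsets[g + 1]
        orow = other_rows[g]
        for j in range(c0, c1, 2):
            a = cuts[j]
            b = cuts[j + 1] if j + 1 < c1 else ns
            if a >= b:
                continue
            ba, ra = a >> 3, a & 7
            bb, rb = b >> 3, b & 7
            if ba == bb:
                m = (0xFF >> ra) & (0xFF ^ (0xFF >> rb))
                gametes[g, b0 + ba] = (gametes[g, b0 + ba] & (0xFF ^ m)) | (haps[orow, b0 + ba] & m)
            else:
                m = 0xFF >> ra
                gametes[g, b0 + ba] = (gametes[g, b0 + ba] & (0xFF ^ m)) | (haps[orow, b0 + ba] & m)
                gametes[g, b0 + ba + 1 : b0 + bb] = haps[orow, b0 + ba + 1 : b0 + bb]
                if rb:
                    m = 0xFF ^ (0xFF >> rb)
                    gametes[g, b0 + bb] = (gametes[g, b0 + bb] & (0xFF ^ m)) | (haps[orow, b0 + bb] & m)


if _HAVE_NUMBA:
    _copy_segments = _njit(cache=False, nogil=True)(_copy_segments_py)
else:  # pragma: no cover
    _copy_segments = _copy_segments_py


def _bytes_per_chromosome(ns: int) -> int:
    return (ns + 7) // 8


def _pack(unpacked: np.ndarray, nchr: int, ns: int) -> np.ndarray:
    """Pack 0/1 haplotypes chromosome-by-chromosome, padding each
    chromosome to a byte boundary."""
    cb = _bytes_per_chromosome(ns)
    out = np.zeros((unpacked.shape[0], nchr * cb), dtype=np.uint8)
    for c in range(nchr):
        out[:, c * cb : (c + 1) * cb] = np.packbits(unpacked[:, c * ns : (c + 1) * ns], axis=1)
    return out


def _unpack(packed: np.ndarray, nchr: int, ns: int) -> np.ndarray:
    cb = _bytes_per_chromosome(ns)
    out = np.empty((packed.shape[0], nchr * ns), dtype=np.uint8)
    for c in range(nchr):
        out[:, c * ns : (c + 1) * ns] = np.unpackbits(packed[:, c * cb : (c + 1) * cb], axis=1)[:, :ns]
    return out


@dataclass(frozen=True)
class SimulationSpec:
    """Gene-dropping configuration.

    Defaults follow the standard validation setup: 30 chromosomes of 4,000
    equally spaced SNPs each, 1 Morgan per chromosome, mutation rate 1e-8
    per site per generation, and a burn-in of Ne generations (pass
    ``n_generations`` explicitly; Ne generations is the customary choice).
    """

    effective_size: int
    n_generations: int
    n_chromosomes: int = 30
    snps_per_chromosome: int = 4000
    chromosome_length: float = 1.0
    mutation_rate: float = 1e-8
    final_sample_size: int = 1000
    seed: int = 0
    mating: str = "random"  # "random" (union with replacement) or "monogamous"

    def __post_init__(self) -> None:
        if self.effective_size < 1 or self.n_generations < 1:
            raise ValueError("effective_size and n_generations must be positive")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one chromosome with at least one SNP")
        if self.chromosome_length < 0 or self.mutation_rate < 0:
            raise ValueError("chromosome_length and mutation_rate must be non-negative")
        if self.final_sample_size < 2:
            raise ValueError("final_sample_size must be >= 2")
        if self.mating not in ("random", "monogamous"):
            raise ValueError(f"mating must be 'random' or 'monogamous', got {self.mating}")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    def positions(self) -> np.ndarray:
        """Within-chromosome genetic positions (Morgans), equally spaced
        across (0, L) with half-spacing margins; concatenated over
        chromosomes."""
        ns, L = self.snps_per_chromosome, self.chromosome_length
        if L > 0 and ns > 1:
            one = (np.arange(ns) + 0.5) * (L / ns)
        else:
            one = np.zeros(ns)
        return np.tile(one, self.n_chromosomes)

    def chromosome_of_snp(self) -> np.ndarray:
        return np.repeat(np.arange(1, self.n_chromosomes + 1), self.snps_per_chromosome).astype(np.int32)


@dataclass
class HaplotypePanel:
    """Binary haplotypes (2 x individuals rows; individual i owns rows 2i,
    2i+1) with their genetic map."""

    haplotypes: np.ndarray
    genetic_positions: np.ndarray
    chromosome_of_snp: np.ndarray
    generation_index: int

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def dosages(self) -> np.ndarray:
        return (self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2])


def founder_panel(spec: SimulationSpec, rng: Optional[np.random.Generator] = None) -> HaplotypePanel:
    """Founder generation: linkage-equilibrium haplotypes.

    Per-SNP allele frequencies are drawn from Uniform(0.05, 0.95) and the
    2 Ne founder haplotypes are sampled independently at those frequencies,
    so founders carry no LD beyond finite-sample noise (E[r^2] ~ 1/(2 Ne)).
    """
    rng = rng or np.random.default_rng(spec.seed)
    freqs = rng.uniform(0.05, 0.95, spec.n_snps)
    haps = (rng.random((2 * spec.effective_size, spec.n_snps)) < freqs).astype(np.uint8)
    return HaplotypePanel(
        haplotypes=haps,
        genetic_positions=spec.positions(),
        chromosome_of_snp=spec.chromosome_of_snp(),
        generation_index=0,
    )


def _meiosis(
    packed: np.ndarray,
    parents: np.ndarray,
    spec: SimulationSpec,
    positions_one: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One bit-packed gamete per entry of ``parents`` (individual indices)."""
    n_g = parents.size
    ns = spec.snps_per_chromosome
    cb = _bytes_per_chromosome(ns)
    L = spec.chromosome_length
    gametes = np.empty((n_g, spec.n_chromosomes * cb), dtype=np.uint8)
    for c in range(spec.n_chromosomes):
        # Chromosomes assort independently: a fresh random start phase each.
        start = rng.integers(0, 2, size=n_g, dtype=np.int64)
        base_rows = 2 * parents + start
        other_rows = 2 * parents + 1 - start
        offsets = np.zeros(n_g + 1, dtype=np.int64)
        if L > 0:
            k = rng.poisson(L, n_g)
            np.cumsum(k, out=offsets[1:])
        total = int(offsets[-1])
        if total:
            # Crossovers are sparse (Poisson(L) per gamete): record sorted
            # breakpoint SNP indices per gamete and patch alternating
            # segments of the homologous haplotype.
            xo = rng.uniform(0.0, L, total)
            sidx = np.searchsorted(positions_one, xo, side="left").astype(np.int64)
            gidx = np.repeat(np.arange(n_g), k)
            cuts = sidx[np.lexsort((sidx, gidx))]
        else:
            cuts = np.empty(0, dtype=np.int64)
        _copy_segments(packed, gametes, base_rows, other_rows, cuts, offsets, c * cb, cb, ns)
    return gametes


def _mutate_packed(packed: np.ndarray, spec: SimulationSpec, rng: np.random.Generator) -> None:
    """Per-site mutation flips on the packed representation."""
    rate = spec.mutation_rate
    if rate <= 0:
        return
    ns = spec.snps_per_chromosome
    cb = _bytes_per_chromosome(ns)
    n_sites = packed.shape[0] * spec.n_snps
    n_mut = int(rng.binomial(n_sites, rate))
    for flat in rng.integers(0, n_sites, n_mut):
        row, site = divmod(int(flat), spec.n_snps)
        chrom, local = divmod(site, ns)
        packed[row, chrom * cb + (local >> 3)] ^= 0x80 >> (local & 7)


def _offspring(
    packed: np.ndarray,
    n_offspring: int,
    spec: SimulationSpec,
    positions_one: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n_par = packed.shape[0] // 2
    if spec.mating == "random":
        pa = rng.integers(0, n_par, n_offspring)
        pb = rng.integers(0, n_par, n_offspring)
    else:
        # Monogamous pairs: shuffle parents, pair consecutively, each
        # offspring drawn from a random pair.
        order = rng.permutation(n_par)
        n_pairs = n_par // 2
        pair_idx = rng.integers(0, n_pairs, n_offspring)
        pa = order[2 * pair_idx]
        pb = order[2 * pair_idx + 1]
    g1 = _meiosis(packed, pa, spec, positions_one, rng)
    g2 = _meiosis(packed, pb, spec, positions_one, rng)
    out = np.empty((2 * n_offspring, g1.shape[1]), dtype=np.uint8)
    out[0::2] = g1
    out[1::2] = g2
    _mutate_packed(out, spec, rng)
    return out


def _simulate_packed(spec: SimulationSpec, rng: np.random.Generator) -> tuple[np.ndarray, HaplotypePanel]:
    """Run the generations on bit-packed haplotypes; returns the packed
    final cohort plus the founder panel (for its genetic map)."""
    founders = founder_panel(spec, rng)
    positions_one = founders.genetic_positions[: spec.snps_per_chromosome]
    packed = _pack(founders.haplotypes, spec.n_chromosomes, spec.snps_per_chromosome)
    # Generations 1 .. n_generations-1 at size Ne; the final generation is
    # the expanded sampling cohort.
    for _ in range(spec.n_generations - 1):
        packed = _offspring(packed, spec.effective_size, spec, positions_one, rng)
    packed = _offspring(packed, spec.final_sample_size, spec, positions_one, rng)
    return packed, founders


def _simulate_haplotypes(spec: SimulationSpec, rng: Optional[np.random.Generator] = None) -> HaplotypePanel:
    rng = rng or np.random.default_rng(spec.seed)
    packed, founders = _simulate_packed(spec, rng)
    return HaplotypePanel(
        haplotypes=_unpack(packed, spec.n_chromosomes, spec.snps_per_chromosome),
        genetic_positions=founders.genetic_positions,
        chromosome_of_snp=founders.chromosome_of_snp,
        generation_index=spec.n_generations,
    )


def _panel_to_genotypes(panel: HaplotypePanel, id_prefix: str = "sim") -> GenotypeMatrix:
    n = panel.n_individuals
    ns_total = panel.haplotypes.shape[1]
    chrom = panel.chromosome_of_snp
    snp_ids = [f"chr{chrom[j]}_snp{j}" for j in range(ns_total)]
    return GenotypeMatrix(
        individual_ids=[f"{id_prefix}_{i}" for i in range(n)],
        snp_ids=snp_ids,
        chromosome_of_snp=chrom,
        dosage=panel.dosages(),
        genetic_position=panel.genetic_positions,
    )


def simulate(spec: SimulationSpec) -> GenotypeMatrix:
    """Run the gene-dropping simulation and return the sampled final cohort.

    Deterministic for a fixed ``spec.seed``.
    """
    return _panel_to_genotypes(_simulate_haplotypes(spec))


def simulate_families(
    n_families: int,
    sibs_per_family: int,
    structure: str,
    genome: SimulationSpec,
) -> GenotypeMatrix:
    """Simulate sib families whose parents come from a gene-dropped base
    population.

    ``structure`` is ``"full"`` (each family: 2 shared parents, expected
    within-family relationship 0.5) or ``"half"`` (one shared sire, a
    distinct dam per sib, expected 0.25).  Parents are distinct individuals
    sampled from the base population's final generation, so between-family
    relationships are near zero when the base Ne is large.  Individual ids
    are ``fam{f}_sib{s}``.
    """
    if n_families < 1 or sibs_per_family < 1:
        raise ValueError("need at least one family with at least one sib")
    if structure not in ("full", "half"):
        raise ValueError(f"structure must be 'full' or 'half', got {structure}")
    if structure == "full":
        n_parents = 2 * n_families
    else:
        n_parents = n_families * (1 + sibs_per_family)
    base_spec = replace(genome, final_sample_size=max(n_parents, 2))
    rng = np.random.default_rng(genome.seed)
    base_packed, founders = _simulate_packed(base_spec, rng)
    positions_one = founders.genetic_positions[: base_spec.snps_per_chromosome]
    parent_order = rng.permutation(base_packed.shape[0] // 2)[:n_parents]
    sires = np.empty(n_families * sibs_per_family, dtype=np.intp)
    dams = np.empty(n_families * sibs_per_family, dtype=np.intp)
    ids = []
    cursor = 0
    for f in range(n_families):
        if structure == "full":
            sire, dam = parent_order[2 * f], parent_order[2 * f + 1]
            for s in range(sibs_per_family):
                sires[cursor], dams[cursor] = sire, dam
                ids.append(f"fam{f}_sib{s}")
                cursor += 1
        else:
            block = parent_order[f * (1 + sibs_per_family) : (f + 1) * (1 + sibs_per_family)]
            sire = block[0]
            for s in range(sibs_per_family):
                sires[cursor], dams[cursor] = sire, block[1 + s]
                ids.append(f"fam{f}_sib{s}")
                cursor += 1
    g1 = _meiosis(base_packed, sires, base_spec, positions_one, rng)
    g2 = _meiosis(base_packed, dams, base_spec, positions_one, rng)
    packed = np.empty((2 * len(ids), g1.shape[1]), dtype=np.uint8)
    packed[0::2] = g1
    packed[1::2] = g2
    _mutate_packed(packed, base_spec, rng)
    panel = HaplotypePanel(
        haplotypes=_unpack(packed, base_spec.n_chromosomes, base_spec.snps_per_chromosome),
        genetic_positions=founders.genetic_positions,
        chromosome_of_snp=founders.chromosome_of_snp,
        generation_index=base_spec.n_generations + 1,
    )
    geno = _panel_to_genotypes(panel)
    geno.individual_ids = ids
    return geno
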