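"""Forward simulation of a composite population with full-sib families.

The composite is built by crossing two random-mating parental populations
that are each in linkage equilibrium but differ in allele frequency locus
by locus.  F1 individuals (one haplotype sampled from each parental
population) are mated pairwise to produce the composite base generation —
whose haplotype LD is exactly Δ_ab = ((1−2θ)/4)Δp_aΔp_b — followed by
generations of random mating without mutation, selection or migration.
From the advanced generation, full-sib families are sampled (default
20 families × 50 sibs = 1000 individuals), and populations of decreasing
size are obtained by removing individuals proportionally from every family.

Meiosis follows Haldane's model: the inheritance indicator along a
chromosome is a Markov chain whose switch probability between consecutive
loci is the recombination fraction θ(d) = (1 − e^(−2d/100))/2, which is
exactly the marginal law of a Poisson crossover process without
interference; chromosomes assort independently.

Phase (haplotypes) is tracked internally; downstream stages only see
dosages in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeMap


@dataclass(frozen=True)
class ParentalFrequencies:
    """Per-locus allele frequencies of the two parental populations."""

    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self):
        p1 = np.asarray(self.p1, float)
        p2 = np.asarray(self.p2, float)
        if p1.shape != p2.shape:
            raise ValueError("p1 and p2 must have the same length")
        for p in (p1, p2):
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "p1", p1)
        object.__setattr__(self, "p2", p2)

    @property
    def n_loci(self) -> int:
        return self.p1.size


@dataclass
class Population:
    """A cohort of diploid individuals over a :class:`GenomeMap`.

    ``haplotypes`` has shape (n, 2, n_loci) with entries in {0, 1}; the
    dosage matrix is its sum over the ploidy axis.  ``ids`` are stable
    within a sampled cohort so phenotypes simulated on the full cohort can
    be aligned after downsampling.
    """

    haplotypes: np.ndarray
    gmap: GenomeMap
    family_id: np.ndarray
    generation: int = 0
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise ValueError("haplotype locus count does not match the map")
        if self.ids is None:
            self.ids = np.arange(self.n)
        self.family_id = np.asarray(self.family_id)
        if self.family_id.shape[0] != self.n:
            raise ValueError("family_id length mismatch")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def genotypes(self) -> np.ndarray:
        """Dosage matrix (n × n_loci), entries in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    @property
    def marker_dosages(self) -> np.ndarray:
        return self.genotypes[:, self.gmap.marker_locus_idx]

    @property
    def qtl_dosages(self) -> np.ndarray:
        return self.genotypes[:, self.gmap.qtl_locus_idx]

    @property
    def n_families(self) -> int:
        return int(np.unique(self.family_id).size)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# parental populations

def simulate_parental_pops(gmap: GenomeMap, freq_law=None,
                           seed: int | np.random.SeedSequence | None = 0
                           ) -> ParentalFrequencies:
    """Draw per-locus allele frequencies for the two parental populations.

    Each population is in linkage equilibrium, so frequencies are drawn
    independently per locus.  ``freq_law`` is a mapping with a ``name``:

    ``{"name": "divergent", "lo": 0.05, "hi": 0.28}`` (default)
        one population gets p ~ U(1−hi, 1−lo), the other p ~ U(lo, hi),
        with the roles swapped per locus with probability 1/2, so the two
        populations are strongly differentiated at every locus and the
        composite carries strong, heterogeneous LD.
    ``{"name": "uniform", "low": 0.05, "high": 0.95}``
        both populations i.i.d. uniform — weak, mostly sub-threshold LD.
    ``{"name": "fixed", "p1": array, "p2": array}``
        explicit frequencies (used by tests for degenerate designs).
    """
    if freq_law is None:
        freq_law = {"name": "divergent"}
    rng = np.random.default_rng(seed)
    L = gmap.n_loci
    name = freq_law.get("name", "divergent")
    if name == "fixed":
        p1 = np.broadcast_to(np.asarray(freq_law["p1"], float), (L,)).copy()
        p2 = np.broadcast_to(np.asarray(freq_law["p2"], float), (L,)).copy()
    elif name == "uniform":
        low = freq_law.get("low", 0.05)
        high = freq_law.get("high", 0.95)
        p1 = rng.uniform(low, high, size=L)
        p2 = rng.uniform(low, high, size=L)
    elif name == "divergent":
        lo = freq_law.get("lo", 0.05)
        hi = freq_law.get("hi", 0.28)
        p_high = rng.uniform(1.0 - hi, 1.0 - lo, size=L)
        p_low = rng.uniform(lo, hi, size=L)
        swap = rng.random(L) < 0.5
        p1 = np.where(swap, p_low, p_high)
        p2 = np.where(swap, p_high, p_low)
    else:
        raise ValueError(f"unknown frequency law {name!r}")
    return ParentalFrequencies(p1=p1, p2=p2)


# ---------------------------------------------------------------------------
# meiosis

def _gametes(haplotypes: np.ndarray, gmap: GenomeMap,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual (vectorised Haldane meiosis).

    For each chromosome the inheritance indicator starts on a random
    haplotype and switches between consecutive loci with probability equal
    to the adjacent recombination fraction.
    """
    n, _, L = haplotypes.shape
    out = np.empty((n, L), dtype=np.int8)
    offset = 0
    for c in range(gmap.n_chromosomes):
        Lc = gmap.locus_positions[c].size
        theta = gmap.adjacent_theta(c)
        start = rng.integers(0, 2, size=(n, 1), dtype=np.int32)
        if Lc > 1:
            switches = rng.random((n, Lc - 1)) < theta
            ind = np.concatenate(
                [start, (start + np.cumsum(switches, axis=1)) % 2], axis=1)
        else:
            ind = start
        block = haplotypes[:, :, offset:offset + Lc]
        rows = np.arange(n)[:, None]
        out[:, offset:offset + Lc] = block[rows, ind, np.arange(Lc)[None, :]]
        offset += Lc
    return out


def meiosis(parent_haplotypes: np.ndarray, gmap: GenomeMap,
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Produce a single gamete from one phased parent.

    ``parent_haplotypes`` must have shape (2, n_loci) with entries in
    {0, 1}; the gamete contains only parental alleles (no mutation) and
    chromosomes assort independently.
    """
    h = np.asarray(parent_haplotypes)
    if h.ndim != 2 or h.shape[0] != 2:
        raise ValueError("parent must be phased: haplotypes of shape (2, n_loci)")
    if h.shape[1] != gmap.n_loci:
        raise ValueError("haplotype length does not match the map")
    if not np.isin(h, [0, 1]).all():
        raise ValueError("haplotype entries must be 0/1 alleles")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _gametes(h[None], gmap, rng)[0]


def _mate(haps: np.ndarray, mothers: np.ndarray, fathers: np.ndarray,
          gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """Offspring haplotypes from chosen parent indices (one child each)."""
    g1 = _gametes(haps[mothers], gmap, rng)
    g2 = _gametes(haps[fathers], gmap, rng)
    return np.stack([g1, g2], axis=1)


# ---------------------------------------------------------------------------
# composite population

def simulate_composite(gmap: GenomeMap, parental_freqs: ParentalFrequencies,
                       composite_size: int = 5000, n_generations: int = 5,
                       n_families_base: int = 100,
                       seed: int | np.random.SeedSequence | None = 0
                       ) -> Population:
    """Simulate the composite: cross, base families, random mating.

    2·n_families_base F1 parents are created by giving every individual one
    haplotype drawn from each parental population.  Mating the F1 pairwise
    yields the base generation (``n_generations=0``): composite_size
    individuals in n_families_base full-sib families whose haplotype LD
    follows the Δ_ab closed form.  Each later generation is produced by
    random pairing within the whole composite (constant size, discrete
    generations).
    """
    if parental_freqs.n_loci != gmap.n_loci:
        raise ValueError("parental frequencies do not match the map")
    if composite_size % n_families_base:
        raise ValueError("composite_size must divide into base families")
    rng = np.random.default_rng(seed)
    L = gmap.n_loci
    n_f1 = 2 * n_families_base
    f1 = np.empty((n_f1, 2, L), dtype=np.int8)
    f1[:, 0, :] = rng.random((n_f1, L)) < parental_freqs.p1
    f1[:, 1, :] = rng.random((n_f1, L)) < parental_freqs.p2

    fam_size = composite_size // n_families_base
    mothers = np.repeat(np.arange(0, n_f1, 2), fam_size)
    fathers = np.repeat(np.arange(1, n_f1, 2), fam_size)
    haps = _mate(f1, mothers, fathers, gmap, rng)
    family = np.repeat(np.arange(n_families_base), fam_size)

    for _ in range(n_generations):
        mothers = rng.integers(0, composite_size, size=composite_size)
        shift = rng.integers(1, composite_size, size=composite_size)
        fathers = (mothers + shift) % composite_size  # never self-mating
        haps = _mate(haps, mothers, fathers, gmap, rng)
        family = np.full(composite_size, -1)

    return Population(haplotypes=haps, gmap=gmap,
                      family_id=family if n_generations == 0
                      else np.full(composite_size, -1),
                      generation=n_generations)


def sample_fullsib_families(composite: Population, n_families: int = 20,
                            family_size: int = 50,
                            seed: int | np.random.SeedSequence | None = 0
                            ) -> Population:
    """Sample full-sib families from the advanced composite generation.

    Each family is the progeny of one randomly chosen (disjoint) parent
    pair; defaults give 20 × 50 = 1000 individuals.
    """
    if composite.n < 2 * n_families:
        raise ValueError("composite too small to supply distinct parents")
    rng = np.random.default_rng(seed)
    parents = rng.choice(composite.n, size=2 * n_families, replace=False)
    mothers = np.repeat(parents[0::2], family_size)
    fathers = np.repeat(parents[1::2], family_size)
    haps = _mate(composite.haplotypes, mothers, fathers, composite.gmap, rng)
    family = np.repeat(np.arange(n_families), family_size)
    return Population(haplotypes=haps, gmap=composite.gmap, family_id=family,
                      generation=composite.generation + 1)


def downsample(pop: Population, target_n: int,
               seed: int | np.random.SeedSequence | None = 0) -> Population:
    """Remove individuals uniformly at random, equally from every family.

    ``target_n`` must keep family sizes equal (proportional removal), per
    the stepwise 1000 → 900 → … → 200 design.
    """
    if target_n > pop.n:
        raise ValueError("target size exceeds current population size")
    if target_n == pop.n:
        return pop
    fams, counts = np.unique(pop.family_id, return_counts=True)
    if target_n % fams.size:
        raise ValueError("target size must be divisible by the family count")
    keep_per_fam = target_n // fams.size
    if np.any(counts < keep_per_fam):
        raise ValueError("a family is too small for proportional downsampling")
    rng = np.random.default_rng(seed)
    keep = []
    for f in fams:
        members = np.flatnonzero(pop.family_id == f)
        keep.append(rng.choice(members, size=keep_per_fam, replace=False))
    keep = np.sort(np.concatenate(keep))
    return Population(haplotypes=pop.haplotypes[keep], gmap=pop.gmap,
                      family_id=pop.family_id[keep],
                      generation=pop.generation, ids=pop.ids[keep])
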