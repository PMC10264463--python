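import numpy as np
import pytest

from qrgwas.genome import GenomeMap, build_genome_map
from qrgwas.popgen import (Population, sample_fullsib_families,
                           simulate_composite, simulate_parental_pops)
from qrgwas.structure import grm, pca_covariates
from qrgwas.traits import simulate_trait


@pytest.fixture(scope="session")
def small_map():
    """One chromosome, 50 markers at 0.1 cM, a single QTL."""
    return GenomeMap(marker_positions=(np.arange(50) * 0.1,),
                     qtl_positions=(np.array([2.45]),),
                     architecture="infinitesimal_100",
                     chrom_length_cM=200.0)


@pytest.fixture(scope="session")
def small_cohort(small_map):
    """A 10-family, 300-individual cohort over the small map."""
    fr = simulate_parental_pops(small_map, seed=1)
    comp = simulate_composite(small_map, fr, composite_size=600,
                              n_generations=2, n_families_base=30, seed=2)
    return sample_fullsib_families(comp, n_families=10, family_size=30, seed=3)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort: 20 x 50 full sibs, 3-QTL architecture."""
    ss = np.random.SeedSequence(20240915).spawn(5)
    gmap = build_genome_map(architecture="major3_plus97", seed=ss[0])
    fr = simulate_parental_pops(gmap, seed=ss[1])
    comp = simulate_composite(gmap, fr, seed=ss[2])
    cohort = sample_fullsib_families(comp, seed=ss[3])
    trait = simulate_trait(cohort, 0.30, seed=ss[4])
    return gmap, cohort, trait


@pytest.fixture(scope="session")
def default_structure(default_cohort):
    _, cohort, _ = default_cohort
    G = grm(cohort)
    return G, pca_covariates(G, 19)


def random_population(gmap, n, seed=0, p=0.5):
    """Unlinked, unrelated individuals: i.i.d. Bernoulli haplotypes."""
    rng = np.random.default_rng(seed)
    haps = (rng.random((n, 2, gmap.n_loci)) < p).astype(np.int8)
    return Population(haplotypes=haps, gmap=gmap,
                      family_id=np.arange(n), generation=0)
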