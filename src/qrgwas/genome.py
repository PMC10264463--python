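"""Genetic map construction and composite-population LD expectations.

A :class:`GenomeMap` lays markers on a regular genetic grid (positions in
centimorgans) and places QTLs at random inter-marker positions inside the
marker-covered region of each chromosome.  Two architectures are supported:

``infinitesimal_100``
    100 QTLs of small additive effect (infinitesimal-style trait).
``major3_plus97``
    3 major genes jointly explaining half the genetic variance plus 97
    minor loci.

The closed form :func:`expected_composite_ld` gives the signed
disequilibrium created when two random-mating populations in linkage
equilibrium are crossed and the F1 individuals mated: for loci *a*, *b*
with recombination fraction θ and parental allele frequencies p¹, p²,

    Δ_ab = ((1 − 2θ) / 4) (p¹_a − p²_a)(p¹_b − p²_b)

so |Δ| ≤ 0.25, maximised for θ = 0 and fully divergent parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARCHITECTURES = ("infinitesimal_100", "major3_plus97")


def haldane_theta(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance under Haldane's map.

    θ(d) = (1 − e^(−2d/100)) / 2 with *d* in centimorgans; crossovers are
    a Poisson process along the map (no interference).
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def expected_composite_ld(theta, pa1, pa2, pb1, pb2):
    """Signed LD Δ_ab of the composite base generation.

    Parameters
    ----------
    theta : recombination fraction between the two loci, in [0, 0.5].
    pa1, pa2 : allele frequencies of locus *a* in parental populations 1, 2.
    pb1, pb2 : allele frequencies of locus *b* in parental populations 1, 2.
    """
    theta = np.asarray(theta, dtype=float)
    freqs = [np.asarray(p, dtype=float) for p in (pa1, pa2, pb1, pb2)]
    if np.any(theta < 0) or np.any(theta > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    for p in freqs:
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
    pa1, pa2, pb1, pb2 = freqs
    return (1.0 - 2.0 * theta) / 4.0 * (pa1 - pa2) * (pb1 - pb2)


@dataclass(frozen=True)
class GenomeMap:
    """Marker and QTL layout over a set of chromosomes (positions in cM)."""

    marker_positions: tuple  # per-chromosome float arrays, strictly increasing
    qtl_positions: tuple     # per-chromosome float arrays, strictly increasing
    architecture: str
    chrom_length_cM: float = 200.0

    # derived, filled in __post_init__
    locus_positions: tuple = field(init=False, repr=False)
    locus_is_marker: tuple = field(init=False, repr=False)

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        loci, masks = [], []
        for c, (m, q) in enumerate(zip(self.marker_positions, self.qtl_positions)):
            m = np.asarray(m, dtype=float)
            q = np.asarray(q, dtype=float)
            if m.size and np.any(np.diff(m) <= 0):
                raise ValueError(f"marker positions not strictly increasing on chromosome {c}")
            if m.size and (m[0] < 0 or m[-1] > self.chrom_length_cM):
                raise ValueError(f"marker positions outside chromosome {c} span")
            if q.size and (np.min(q) < 0 or np.max(q) > self.chrom_length_cM):
                raise ValueError(f"QTL positions outside chromosome {c} span")
            pos = np.concatenate([m, q])
            mask = np.concatenate([np.ones(m.size, bool), np.zeros(q.size, bool)])
            order = np.argsort(pos, kind="stable")
            loci.append(pos[order])
            masks.append(mask[order])
        object.__setattr__(self, "locus_positions", tuple(loci))
        object.__setattr__(self, "locus_is_marker", tuple(masks))

    # ---- layout queries -------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.marker_positions)

    @property
    def n_markers(self) -> int:
        return int(sum(len(m) for m in self.marker_positions))

    @property
    def n_qtls(self) -> int:
        return int(sum(len(q) for q in self.qtl_positions))

    @property
    def n_loci(self) -> int:
        return self.n_markers + self.n_qtls

    @property
    def locus_chrom(self) -> np.ndarray:
        """Chromosome index of every locus, genome order."""
        return np.repeat(np.arange(self.n_chromosomes),
                         [len(p) for p in self.locus_positions])

    @property
    def locus_pos_flat(self) -> np.ndarray:
        return np.concatenate(self.locus_positions)

    @property
    def locus_is_marker_flat(self) -> np.ndarray:
        return np.concatenate(self.locus_is_marker)

    @property
    def marker_locus_idx(self) -> np.ndarray:
        """Flat locus indices of markers, genome order."""
        return np.flatnonzero(self.locus_is_marker_flat)

    @property
    def qtl_locus_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.locus_is_marker_flat)

    @property
    def marker_chrom(self) -> np.ndarray:
        return self.locus_chrom[self.marker_locus_idx]

    @property
    def marker_pos(self) -> np.ndarray:
        return self.locus_pos_flat[self.marker_locus_idx]

    @property
    def qtl_chrom(self) -> np.ndarray:
        return self.locus_chrom[self.qtl_locus_idx]

    @property
    def qtl_pos(self) -> np.ndarray:
        return self.locus_pos_flat[self.qtl_locus_idx]

    @property
    def marker_ids(self) -> list:
        return [f"chr{c + 1}_M{i + 1}"
                for c in range(self.n_chromosomes)
                for i in range(len(self.marker_positions[c]))]

    def adjacent_theta(self, chrom: int) -> np.ndarray:
        """Recombination fractions between consecutive loci of a chromosome."""
        return haldane_theta(np.diff(self.locus_positions[chrom]))


def build_genome_map(n_chrom: int = 10,
                     chrom_length_cM: float = 200.0,
                     markers_per_chrom: int = 200,
                     spacing_cM: float = 0.1,
                     architecture: str = "infinitesimal_100",
                     n_qtls: int = 100,
                     seed: int | np.random.SeedSequence | None = 0) -> GenomeMap:
    """Build the default genome: a regular marker grid plus random QTLs.

    Markers sit at 0, spacing, 2·spacing, … on each chromosome.  QTLs are
    placed uniformly at random inside the marker-covered span of the genome
    (chromosome chosen with probability proportional to covered length),
    at inter-marker positions.
    """
    span = (markers_per_chrom - 1) * spacing_cM
    if span > chrom_length_cM:
        raise ValueError("markers_per_chrom x spacing_cM exceeds chromosome length")
    markers = tuple(np.arange(markers_per_chrom) * spacing_cM
                    for _ in range(n_chrom))

    rng = np.random.default_rng(seed)
    chrom_of_qtl = rng.integers(0, n_chrom, size=n_qtls)  # equal covered spans
    qtls = []
    for c in range(n_chrom):
        k = int(np.sum(chrom_of_qtl == c))
        pos = np.sort(rng.uniform(0.0, span, size=k))
        # nudge exact marker collisions off the grid (measure-zero, but be safe)
        on_grid = np.isin(np.round(pos / spacing_cM, 9) % 1.0, [0.0])
        pos[on_grid] += spacing_cM * 1e-3
        qtls.append(pos)
    return GenomeMap(marker_positions=markers, qtl_positions=tuple(qtls),
                     architecture=architecture, chrom_length_cM=chrom_length_cM)
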