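"""Scenario orchestration: power and false-positive rate of QR vs GLM scans.

A scenario is one (architecture, heritability, population size) cell; the
default grid is 2 architectures × h² ∈ {0.30, 0.50} × sizes 1000…200 in
steps of 100 = 36 scenarios, each replicated 10 times with fresh
simulations.  Per replicate the pipeline is: simulate the composite and
the 20 × 50 full-sib sample → simulate the trait → downsample stepwise
(nested: the N = 800 set is a subset of the N = 900 set) → calibrate the
LD window at r² = 0.20 → PCA covariates → scans (QR at τ = 0.10, 0.50,
0.90 and GLM) → power and false-positive rate.

Power: fraction of target-QTL windows holding at least one significant
marker.  Target QTLs are the 3 major genes under ``major3_plus97`` and
all 100 loci under ``infinitesimal_100``.  FPR: significant markers
outside every target window divided by all tested markers outside every
target window (monomorphic markers are excluded from both counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import build_genome_map
from .ld import fit_decay_curve, pairwise_r2, qtl_marker_association, window_distance
from .popgen import downsample, sample_fullsib_families, simulate_composite, \
    simulate_parental_pops
from .scan import DEFAULT_TAUS, GWASResults, ScanConfig, scan
from .structure import DEFAULT_K, grm, pca_covariates
from .traits import simulate_trait

POPULATION_SIZES = tuple(range(1000, 100, -100))


def default_methods(alpha: float = 0.01):
    return tuple([ScanConfig(method="QR", tau=t, alpha=alpha)
                  for t in DEFAULT_TAUS] + [ScanConfig(method="GLM", alpha=alpha)])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulator (one source of defaults)."""

    n_chromosomes: int = 10
    chrom_length_cM: float = 200.0
    markers_per_chrom: int = 200
    spacing_cM: float = 0.1
    n_qtls: int = 100
    composite_size: int = 5000
    n_generations: int = 5
    n_families_base: int = 100
    n_families: int = 20
    family_size: int = 50
    freq_law: dict = field(default_factory=lambda: {"name": "divergent"})
    ld_span: float = 0.75
    ld_degree: int = 2
    r2_threshold: float = 0.20
    ld_max_pairs: int | None = None


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario of the grid plus how to scan and replicate it."""

    architecture: str = "major3_plus97"
    h2: float = 0.30
    population_size: int = 1000
    methods: tuple = field(default_factory=default_methods)
    n_replicates: int = 10
    master_seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    K: int | None = None           # PCs; default per architecture
    nested_downsampling: bool = True

    def __post_init__(self):
        full = self.sim.n_families * self.sim.family_size
        if not (0 < self.population_size <= full):
            raise ValueError("population size outside the sampled cohort size")


@dataclass
class ScenarioResult:
    """Replicate-wise power/FPR with scenario-level mean ± SE."""

    spec: ScenarioSpec
    replicates: pd.DataFrame   # replicate, method, power, fpr, window_cM, ...

    def aggregate(self) -> pd.DataFrame:
        def mean_se(g):
            r = len(g)
            return pd.Series({
                "power_mean": g["power"].mean(),
                "power_se": g["power"].std(ddof=1) / np.sqrt(r) if r > 1 else 0.0,
                "fpr_mean": g["fpr"].mean(),
                "fpr_se": g["fpr"].std(ddof=1) / np.sqrt(r) if r > 1 else 0.0,
                "n_replicates": r,
            })
        return (self.replicates.groupby("method", sort=False)
                .apply(mean_se, include_groups=False).reset_index())

    @property
    def mean_window_cM(self) -> float:
        per_rep = self.replicates.drop_duplicates("replicate")["window_cM"]
        return float(per_rep.mean())


# ---------------------------------------------------------------------------
# power / FPR definitions

def detection_power(scan_result: GWASResults, assoc) -> float:
    """Fraction of target-QTL windows containing ≥1 significant marker."""
    if assoc.n_windows == 0:
        raise ValueError("empty window set")
    sig = set(scan_result.significant_marker_idx.tolist())
    hits = sum(1 for w in assoc.windows if sig.intersection(w.tolist()))
    return hits / assoc.n_windows


def false_positive_rate(scan_result: GWASResults, assoc) -> float:
    """Significant non-associated markers over all tested non-associated."""
    tested = scan_result.table["marker_idx"].to_numpy()
    outside = ~assoc.associated[tested]
    denom = int(outside.sum())
    if denom == 0:
        raise ValueError("no non-associated markers")
    sig = scan_result.significant
    return int(np.sum(sig & outside)) / denom


# ---------------------------------------------------------------------------
# one replicate of the pipeline

def run_replicate(spec: ScenarioSpec, seed: np.random.SeedSequence | int
                  ) -> pd.DataFrame:
    """Run the full pipeline once; returns one row per scan method."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_map, s_par, s_comp, s_fam, s_trait, s_down, s_ld = ss.spawn(7)
    sim = spec.sim

    gmap = build_genome_map(
        n_chrom=sim.n_chromosomes, chrom_length_cM=sim.chrom_length_cM,
        markers_per_chrom=sim.markers_per_chrom, spacing_cM=sim.spacing_cM,
        architecture=spec.architecture, n_qtls=sim.n_qtls, seed=s_map)
    freqs = simulate_parental_pops(gmap, sim.freq_law, seed=s_par)
    comp = simulate_composite(gmap, freqs, composite_size=sim.composite_size,
                              n_generations=sim.n_generations,
                              n_families_base=sim.n_families_base, seed=s_comp)
    cohort = sample_fullsib_families(comp, n_families=sim.n_families,
                                     family_size=sim.family_size, seed=s_fam)
    trait = simulate_trait(cohort, spec.h2, spec.architecture, seed=s_trait)

    pop = cohort
    if spec.nested_downsampling:
        steps = [n for n in POPULATION_SIZES
                 if cohort.n > n > spec.population_size]
        if spec.population_size < cohort.n:
            steps.append(spec.population_size)
    else:
        steps = [spec.population_size] if spec.population_size < cohort.n \
            else []
    for target, s in zip(steps, s_down.spawn(max(len(steps), 1))):
        pop = downsample(pop, target, seed=s)
    y = trait.phenotypes[pop.ids]

    pairs = pairwise_r2(pop, gmap, max_pairs=sim.ld_max_pairs, seed=s_ld)
    curve = fit_decay_curve(pairs, span=sim.ld_span, degree=sim.ld_degree)
    w = window_distance(curve, threshold=sim.r2_threshold)

    targets = trait.effects.major_indices \
        if spec.architecture == "major3_plus97" else None
    assoc = qtl_marker_association(gmap, w, targets)

    G = grm(pop)
    K = spec.K if spec.K is not None else DEFAULT_K[spec.architecture]
    cov = pca_covariates(G, K)

    rows = []
    for cfg in spec.methods:
        res = scan(pop, y, cov, cfg)
        rows.append({
            "method": cfg.label,
            "power": detection_power(res, assoc),
            "fpr": false_positive_rate(res, assoc),
            "n_significant": res.n_significant,
            "window_cM": w,
            "pc_variance": cov.cumulative_variance,
            "n": pop.n,
        })
    return pd.DataFrame(rows)


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """All replicates of one scenario, reproducible from the master seed.

    Replicate r uses the r-th child of SeedSequence(master_seed), so
    results are independent of execution order.
    """
    seeds = np.random.SeedSequence(spec.master_seed).spawn(spec.n_replicates)
    frames = []
    for r, s in enumerate(seeds):
        df = run_replicate(spec, s)
        df.insert(0, "replicate", r)
        frames.append(df)
    return ScenarioResult(spec=spec, replicates=pd.concat(frames,
                                                          ignore_index=True))


# ---------------------------------------------------------------------------
# tables

def make_tables(results) -> tuple:
    """Power and FPR tables: rows (architecture, h², method) × size columns.

    Returns (power_table, fpr_table, long_frame); the wide tables hold
    "mean ± SE" strings, the long frame the machine-readable numbers.
    """
    if not results:
        raise ValueError("no scenario results")
    recs = []
    for res in results:
        agg = res.aggregate()
        for _, row in agg.iterrows():
            recs.append({
                "architecture": res.spec.architecture,
                "h2": res.spec.h2,
                "method": row["method"],
                "population_size": res.spec.population_size,
                "power_mean": row["power_mean"], "power_se": row["power_se"],
                "fpr_mean": row["fpr_mean"], "fpr_se": row["fpr_se"],
                "window_cM": res.mean_window_cM,
                "n_replicates": row["n_replicates"],
            })
    long = pd.DataFrame(recs)

    def wide(metric):
        d = long.copy()
        d["cell"] = (d[f"{metric}_mean"].map("{:.2f}".format) + " ± "
                     + d[f"{metric}_se"].map("{:.2f}".format))
        return d.pivot_table(index=["architecture", "h2", "method"],
                             columns="population_size", values="cell",
                             aggfunc="first", sort=False)

    return wide("power"), wide("fpr"), long
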