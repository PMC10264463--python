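"""Additive trait simulation: QTL effects, heritability calibration, phenotypes.

Effects are drawn i.i.d. normal with zero mean.  Under the
``major3_plus97`` architecture three randomly chosen QTLs are rescaled so
that they jointly account for exactly half of the realized genetic
variance in the base population (realized variance includes LD covariance
between QTLs, which makes the split and the later heritability
calibration exact by construction).  The environmental variance is set
from the realized genetic variance as σ²_e = var(g)·(1 − h²)/h², and
phenotypes are Y_i = g_i + e_i with e_i ~ N(0, σ²_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .popgen import Population

N_MAJOR = 3


@dataclass(frozen=True)
class EffectSet:
    """Additive allele-substitution effects for every QTL."""

    effects: np.ndarray      # one effect per QTL, genome order
    is_major: np.ndarray     # bool flag per QTL
    architecture: str

    @property
    def n_qtls(self) -> int:
        return self.effects.size

    @property
    def major_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_major)


@dataclass(frozen=True)
class TraitModel:
    """A simulated trait tied to one population sample."""

    effects: EffectSet
    genetic_values: np.ndarray
    error_variance: float
    h2_target: float
    phenotypes: np.ndarray

    @property
    def realized_h2(self) -> float:
        return float(np.var(self.genetic_values) / np.var(self.phenotypes))


def assign_qtl_effects(gmap: GenomeMap, base_pop: Population,
                       architecture: str | None = None,
                       seed: int | np.random.SeedSequence | None = 0
                       ) -> EffectSet:
    """Draw additive QTL effects and apply the architecture's variance split.

    ``major3_plus97``: 3 QTLs (chosen at random among the polymorphic
    ones) are scaled by the λ > 0 solving
    var(λ·g_major) = ½·var(λ·g_major + g_minor), i.e. the quadratic
    ½λ²v_M − λc − ½v_m = 0 with c = cov(g_M, g_m), so the realized share
    of the major genes is exactly ½.  ``infinitesimal_100``: all effects
    kept as drawn (scale is irrelevant after heritability calibration).
    """
    architecture = architecture or gmap.architecture
    rng = np.random.default_rng(seed)
    nq = gmap.n_qtls
    X = base_pop.qtl_dosages.astype(float)
    poly = X.std(axis=0) > 0
    if not poly.any():
        raise ValueError("all QTLs are monomorphic in the base population")
    effects = rng.standard_normal(nq)
    is_major = np.zeros(nq, dtype=bool)
    if architecture == "major3_plus97":
        candidates = np.flatnonzero(poly)
        if candidates.size < N_MAJOR:
            raise ValueError("fewer than 3 polymorphic QTLs for major genes")
        is_major[rng.choice(candidates, size=N_MAJOR, replace=False)] = True
        g_major = X[:, is_major] @ effects[is_major]
        g_minor = X[:, ~is_major] @ effects[~is_major]
        v_M = np.var(g_major)
        v_m = np.var(g_minor)
        c = np.cov(g_major, g_minor, ddof=0)[0, 1]
        lam = (c + np.sqrt(c * c + v_M * v_m)) / v_M
        effects[is_major] *= lam
    elif architecture != "infinitesimal_100":
        raise ValueError(f"unknown architecture {architecture!r}")
    return EffectSet(effects=effects, is_major=is_major,
                     architecture=architecture)


def genetic_values(pop: Population, effects: EffectSet) -> np.ndarray:
    """Additive genotypic values g_i = Σ_q dosage_iq · effect_q."""
    X = pop.qtl_dosages
    if X.shape[1] != effects.n_qtls:
        raise ValueError("effect count does not match the QTL count")
    return X.astype(float) @ effects.effects


def calibrate_error_variance(genetic_vals: np.ndarray, h2_target: float) -> float:
    """Environmental variance giving the target broad-sense heritability."""
    if not 0.0 < h2_target < 1.0:
        raise ValueError("heritability must lie strictly inside (0, 1)")
    var_g = float(np.var(genetic_vals))
    if var_g <= 0:
        raise ValueError("genetic variance is zero; cannot calibrate")
    return var_g * (1.0 - h2_target) / h2_target


def simulate_phenotypes(genetic_vals: np.ndarray, error_variance: float,
                        seed: int | np.random.SeedSequence | None = 0
                        ) -> np.ndarray:
    """Phenotypes Y = g + e with e ~ N(0, σ²_e) i.i.d."""
    if error_variance < 0:
        raise ValueError("error variance must be nonnegative")
    rng = np.random.default_rng(seed)
    g = np.asarray(genetic_vals, float)
    return g + rng.normal(0.0, np.sqrt(error_variance), size=g.size)


def simulate_trait(pop: Population, h2: float,
                   architecture: str | None = None,
                   seed: int | np.random.SeedSequence | None = 0
                   ) -> TraitModel:
    """Convenience pipeline: effects → genetic values → σ²_e → phenotypes."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_eff, s_env = ss.spawn(2)
    eff = assign_qtl_effects(pop.gmap, pop, architecture, seed=s_eff)
    g = genetic_values(pop, eff)
    s2e = calibrate_error_variance(g, h2)
    y = simulate_phenotypes(g, s2e, seed=s_env)
    return TraitModel(effects=eff, genetic_values=g, error_variance=s2e,
                      h2_target=h2, phenotypes=y)
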