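# qrgwas

Quantile-regression GWAS evaluated against the general linear model on
simulated composite populations — a tested re-implementation of a
simulation study of QTL detection power and false-positive rate as a
function of population size, heritability and genetic architecture.

## The problem

Plant-breeding programs often have far fewer genotyped and phenotyped
individuals than classical GWAS requires. This package asks, by
simulation, how two single-marker association methods behave as the
population shrinks from N = 1000 to N = 200:

* **GLM** — per-marker ordinary least squares with population-structure
  covariates and the usual *t*-test;
* **QR** — per-marker quantile regression at τ = 0.10, 0.50, 0.90 with
  rank-score inference, which makes no assumption on the error
  distribution and targets the tails of the phenotype.

Both fit, marker by marker,

    Y = μ + α_j·SNP_j + Σ_k β_k·CP_k + ε ,

where CP₁…CP_K are the leading principal components of the VanRaden
genomic relationship matrix G = ZZ′/Σ2p_j(1−p_j). QR estimates θ̂_τ =
argmin Σ ρ_τ(y_i − x_i′θ) with the check loss ρ_τ(ε) = τε (ε ≥ 0),
(τ−1)ε (ε < 0), solved as a linear program; marker significance uses the
regression rank-score test built from the LP dual of the covariate-only
fit. All p-values are FDR-adjusted (Benjamini–Hochberg step-up; Storey
optional) and called at q ≤ 0.01.

The simulator produces the study populations: two random-mating founder
populations in linkage equilibrium with divergent allele frequencies are
crossed; the composite base carries LD Δ_ab = ((1−2θ)/4)(p¹_a−p²_a)(p¹_b−p²_b);
five generations of random mating follow (Haldane meiosis, no mutation/
selection/migration); 20 full-sib families × 50 sibs are sampled and
downsampled stepwise 1000 → 200 proportionally to family. Traits are
additive with 100 QTLs — either all small (infinitesimal) or 3 major
genes carrying 50 % of the genetic variance plus 97 minor loci — with
environmental noise calibrated to broad-sense h² ∈ {0.30, 0.50}. A QTL
counts as detected when any marker within *w* cM of it is significant,
where *w* is the distance at which a local-polynomial (LOESS-style) fit
of pairwise marker r² against genetic distance crosses r² = 0.20.

## Worked example

```python
import numpy as np
from qrgwas import *

ss = np.random.SeedSequence(11).spawn(6)
gmap  = build_genome_map(architecture="major3_plus97", seed=ss[0])
freqs = simulate_parental_pops(gmap, seed=ss[1])
composite = simulate_composite(gmap, freqs, seed=ss[2])
cohort    = sample_fullsib_families(composite, seed=ss[3])   # 20 x 50
trait     = simulate_trait(cohort, h2=0.30, seed=ss[4])

curve = fit_decay_curve(pairwise_r2(cohort, gmap))
w = window_distance(curve)                 # LD window at r2 = 0.20
print(f"detection window at r2=0.20: {w:.3f} cM")
cov = pca_covariates(grm(cohort), K=19)
print(f"19 PCs explain {100*cov.cumulative_variance:.1f}% of the genotypic variance")
assoc = qtl_marker_association(gmap, w, targets=trait.effects.major_indices)
for cfg in (ScanConfig(method="QR", tau=0.10), ScanConfig(method="GLM")):
    res = scan(cohort, trait.phenotypes, cov, cfg)
    print(f"{cfg.label}: {res.n_significant} significant markers, "
          f"power={detection_power(res, assoc):.2f}, "
          f"FPR={false_positive_rate(res, assoc):.4f}")
```

prints

```
detection window at r2=0.20: 0.630 cM
19 PCs explain 93.4% of the genotypic variance
QR(0.10): 0 significant markers, power=0.00, FPR=0.0000
GLM: 9 significant markers, power=0.33, FPR=0.0031
```

i.e. on this replicate the decay curve crosses the critical r² at
0.63 cM, the 19 structure PCs carry 93 % of the genotypic-data variance,
and the GLM scan finds one of the three major genes (9 significant
markers clustered around it on chromosome 6) at a false-positive rate of
0.3 %, while the rank-score QR scan at τ = 0.10 calls nothing at
q ≤ 0.01 on this family-structured sample. `res.summary()` gives the
per-marker table. The full scenario grid (36 scenarios × methods ×
replicates) runs via

```bash
qrgwas evaluate --out results/ --seed 1 --replicates 10   # writes
# table1_power.csv, table2_fpr.csv, results_long.csv, resolved_config.yaml
```

and `qrgwas simulate | ld-window | scan | report` expose the individual
stages (TSV/VCF exports, user-supplied genotype/phenotype scans).

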