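"""Plain-text import/export of genotypes, maps, phenotypes and scan results.

Formats: tab-separated dosage matrices with individual/family ID columns,
PLINK-style 4-column map files, optional VCF v4.2 with phased GT taken
from the internal haplotypes, and the result CSVs of the evaluation grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .popgen import Population


def export_genotypes(pop: Population, path) -> None:
    """Dosage TSV: individual ID, family ID, then one column per marker."""
    gmap = pop.gmap
    df = pd.DataFrame(pop.marker_dosages, columns=gmap.marker_ids)
    df.insert(0, "family_id", pop.family_id)
    df.insert(0, "individual_id", [f"ind{int(i)}" for i in pop.ids])
    df.to_csv(path, sep="\t", index=False)


def import_genotypes(path) -> pd.DataFrame:
    """Read a dosage TSV written by :func:`export_genotypes`."""
    df = pd.read_csv(path, sep="\t")
    need = {"individual_id", "family_id"}
    if not need.issubset(df.columns):
        raise ValueError("genotype file lacks individual_id/family_id columns")
    return df

def export_map(gmap: GenomeMap, path) -> None:
    """PLINK .map column semantics: chrom, marker ID, cM, physical (blank)."""
    rows = zip(gmap.marker_chrom + 1, gmap.marker_ids, gmap.marker_pos)
    with open(path, "w") as fh:
        for chrom, mid, pos in rows:
            fh.write(f"{chrom}\t{mid}\t{pos:.6g}\t0\n")


def export_vcf(pop: Population, path) -> None:
    """VCF v4.2 with phased GT fields from the internal haplotypes.

    Marker positions are written in base pairs at 1 cM = 1 Mbp, alleles
    coded REF=A (allele 0), ALT=T (allele 1).
    """
    gmap = pop.gmap
    idx = gmap.marker_locus_idx
    h = pop.haplotypes[:, :, idx]
    names = [f"ind{int(i)}" for i in pop.ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=qrgwas simulated composite population\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j, (chrom, mid, pos) in enumerate(
                zip(gmap.marker_chrom, gmap.marker_ids, gmap.marker_pos)):
            bp = int(round(pos * 1e4)) + 1
            gts = "\t".join(f"{h[i, 0, j]}|{h[i, 1, j]}" for i in range(pop.n))
            fh.write(f"chr{chrom + 1}\t{bp}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def export_phenotypes(pop: Population, phenotypes, path) -> None:
    pd.DataFrame({
        "individual_id": [f"ind{int(i)}" for i in pop.ids],
        "phenotype": np.asarray(phenotypes, float),
    }).to_csv(path, sep="\t", index=False)


def export_effects(gmap: GenomeMap, effect_set, path) -> None:
    pd.DataFrame({
        "qtl_id": [f"Q{k + 1}" for k in range(gmap.n_qtls)],
        "chrom": gmap.qtl_chrom + 1,
        "pos_cM": gmap.qtl_pos,
        "effect": effect_set.effects,
        "major": effect_set.is_major.astype(int),
    }).to_csv(path, sep="\t", index=False)


def export_covariates(pop: Population, covariates, path) -> None:
    scores = getattr(covariates, "scores", np.asarray(covariates))
    df = pd.DataFrame(scores,
                      columns=[f"PC{k + 1}" for k in range(scores.shape[1])])
    df.insert(0, "individual_id", [f"ind{int(i)}" for i in pop.ids])
    df.to_csv(path, sep="\t", index=False)


def export_ld_pairs(pairs: pd.DataFrame, gmap: GenomeMap, path) -> None:
    out = pairs.copy()
    ids = gmap.marker_ids
    out["markerA"] = [ids[i] for i in out.pop("i")]
    out["markerB"] = [ids[j] for j in out.pop("j")]
    out["chrom"] = out["chrom"] + 1
    out[["chrom", "markerA", "markerB", "dist_cM", "r2"]].to_csv(
        path, sep="\t", index=False)


def plot_decay(pairs: pd.DataFrame, curve, path, threshold: float = 0.20,
               window: float | None = None) -> None:
    """Scatter of r² vs distance with the fitted curve and threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    sub = pairs.sample(min(len(pairs), 20000), random_state=0)
    ax.scatter(sub["dist_cM"], sub["r2"], s=2, alpha=0.15, color="gray")
    grid = np.linspace(curve.dmin, curve.dmax, 200)
    ax.plot(grid, curve(grid), color="C0", lw=2, label="local polynomial fit")
    ax.axhline(threshold, color="C3", ls="--", label=f"r² = {threshold}")
    if window is not None:
        ax.axvline(window, color="C2", ls=":", label=f"window = {window:.3g} cM")
    ax.set_xlabel("genetic distance (cM)")
    ax.set_ylabel("r²")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_tables(power, fpr, long, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    power.to_csv(outdir / "table1_power.csv")
    fpr.to_csv(outdir / "table2_fpr.csv")
    long.to_csv(outdir / "results_long.csv", index=False)
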