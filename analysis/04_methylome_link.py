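#!/usr/bin/env python
"""Promoter methylation / protein correlation and the count-rule ORA.

Correlates every promoter CpG (TSS200/TSS1500/5'UTR) with its gene's protein
level across the tumor samples (Spearman, BY-adjusted over all pairs), calls
genes with >= 1 CpG at adjusted p <= .05 methylation-linked, and tests gene
sets with the count rule (>= 2 and > 10% of in-universe members linked) within
the universe of significantly differential proteins.
"""

from pathlib import Path

from rosette_omics import core_io
from rosette_omics.differential import differential_table
from rosette_omics.methylome_link import (
    correlation_table,
    methylation_ora,
    significant_genes,
)
from rosette_omics.preprocess import median_center

FIX = Path("results/fixtures")
OUT = Path("results/methylome")


def main() -> None:
    if not FIX.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    proteome = median_center(core_io.read_matrix(FIX / "proteome.tsv", "proteome"))
    methylome = core_io.read_matrix(FIX / "methylome.tsv", "methylome")
    cpg_ann = core_io.read_cpg_annotation(FIX / "cpg_annotation.tsv")
    ann = core_io.read_sample_table(FIX / "annotations.tsv")
    sets = core_io.read_gmt(FIX / "gene_sets.gmt")

    corr = correlation_table(methylome, proteome, cpg_ann)
    corr.to_csv(OUT / "correlation.tsv", sep="\t", index=False)
    linked = significant_genes(corr)
    print(f"{len(corr)} promoter CpG-protein pairs tested; "
          f"{len(linked)} genes methylation-linked at BY-adjusted p <= .05")

    comp = ann.samples_where(entity="ATRT") + ann.samples_where(entity="MB")
    diff = differential_table(proteome, ann.samples_where(entity="ETMR"), comp)
    universe = set(diff.index[diff["p"] <= 0.05])
    ora = methylation_ora(linked & universe, universe, sets, min_size=5, max_size=150)
    ora.assign(members=ora["members"].map(";".join)).to_csv(OUT / "ora.tsv", sep="\t")
    called = list(ora.index[ora["over_represented"]])
    print(f"methylation ORA universe: {len(universe)} differential proteins; "
          f"over-represented sets: {called}")


if __name__ == "__main__":
    main()
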