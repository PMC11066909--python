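"""End-to-end orchestration: normalize -> integrate -> differential ->
enrichment -> methylome link -> clustering, from a single config.

The pipeline mirrors the study design: per-sample median centering, optional
empirical-Bayes batch adjustment, subgroup-stratified differential ranking
(ETANTR and EBL/MEPL each versus the AT/RT + MB comparators), combined-rank
preranked GSEA, ORA of significant proteins, promoter-methylation correlation
ORA, ontology-term ORA with semantic-redundancy pruning, and consensus
clustering of the most variant proteins.  Every intermediate table is written
to the output directory and a manifest records the seed, parameters and
SHA-256 checksums so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import core_io, simulate
from .clustering import consensus_cluster, select_top_variant
from .core_io import OmicsMatrix, ValidationError
from .differential import (
    combine_subgroup_ranks,
    differential_table,
    morphology_independent_selection,
    rank_statistic,
)
from .enrichment import gsea_preranked, ora_hypergeometric, redundancy_filter
from .methylome_link import (
    correlation_table,
    methylation_ora,
    significant_genes,
    triomics_overlap,
)
from .preprocess import combat_adjust, median_center

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "fc_threshold": 1.0,
    "p_threshold": 0.05,
    "gsea_min_size": 10,
    "gsea_max_size": 250,
    "gsea_rna_max_size": 600,
    "gsea_weight": 1.0,
    "gsea_n_perm": 1000,
    "ora_min_count": 5,
    "methyl_min_size": 5,
    "methyl_max_size": 150,
    "methyl_min_count": 2,
    "methyl_min_fraction": 0.10,
    "similarity_threshold": 0.4,
    "top_variant": 1000,
    "k_range": [2, 3, 4, 5],
    "n_resamples": 250,
    "subsample_frac": 0.8,
    "alpha": 0.05,
}


def validate_params(params: Mapping[str, Any]) -> dict[str, Any]:
    merged = {**DEFAULT_PARAMS, **dict(params)}
    unknown = set(merged) - set(DEFAULT_PARAMS)
    if unknown:
        raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
    for key in ("p_threshold", "alpha", "methyl_min_fraction", "subsample_frac"):
        if not 0 < merged[key] <= 1:
            raise ValidationError(f"{key} must lie in (0, 1]")
    if merged["similarity_threshold"] < 0 or merged["similarity_threshold"] > 1:
        raise ValidationError("similarity_threshold must lie in [0, 1]")
    for key in ("gsea_min_size", "gsea_max_size", "methyl_min_size", "methyl_max_size",
                "top_variant", "gsea_n_perm", "ora_min_count", "n_resamples"):
        if merged[key] < 1:
            raise ValidationError(f"{key} must be >= 1")
    return merged


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _load_inputs(config: Mapping[str, Any]) -> simulate.SimulatedStudy | Any:
    if "simulate" in config:
        sim_cfg = dict(config["simulate"] or {})
        sim_cfg.setdefault("seed", config.get("seed", 0))
        planted = [
            simulate.PlantedSet(**ps) for ps in sim_cfg.pop("planted_sets", [])
        ] or None
        links = [simulate.MethylLink(**ml) for ml in sim_cfg.pop("methyl_link", [])]
        kwargs = dict(sim_cfg)
        if planted is not None:
            kwargs["planted_sets"] = planted
        kwargs["methyl_link"] = links
        return simulate.generate_multiomics(simulate.SimulationConfig(**kwargs))
    inputs = config.get("inputs")
    if not inputs:
        raise ValidationError("config needs either a 'simulate' or an 'inputs' section")
    for key in ("proteome", "annotations", "gene_sets"):
        if key not in inputs:
            raise ValidationError(f"inputs section missing {key!r}")
        if not Path(inputs[key]).exists():
            raise ValidationError(f"input file not found: {inputs[key]}")
    proteome = core_io.read_matrix(inputs["proteome"], "proteome")
    ann = core_io.read_sample_table(inputs["annotations"])
    gene_sets = core_io.read_gmt(inputs["gene_sets"])
    transcriptome = (
        core_io.read_matrix(inputs["transcriptome"], "transcriptome")
        if "transcriptome" in inputs
        else None
    )
    methylome = (
        core_io.read_matrix(inputs["methylome"], "methylome")
        if "methylome" in inputs
        else None
    )
    cpg_ann = (
        core_io.read_cpg_annotation(inputs["cpg_annotation"])
        if "cpg_annotation" in inputs
        else None
    )
    return simulate.SimulatedStudy(
        proteome=proteome,
        transcriptome=transcriptome,
        methylome=methylome,
        annotations=ann,
        cpg_annotation=cpg_ann,
        gene_sets=gene_sets,
        truth={},
    )


def _subgroup_scores(
    matrix: OmicsMatrix, ann, p_clamp_warned: bool = False
) -> tuple[dict[str, float], dict[str, float], pd.DataFrame, pd.DataFrame]:
    comparators = ann.samples_where(is_reference=False, entity="ATRT") + ann.samples_where(
        is_reference=False, entity="MB"
    )
    etantr = ann.samples_where(subgroup="ETANTR", is_reference=False)
    ebl = ann.samples_where(subgroup="EBL_MEPL", is_reference=False)
    diff_a = differential_table(matrix, etantr, comparators, test="welch")
    diff_b = differential_table(matrix, ebl, comparators, test="welch")

    def scores(tab: pd.DataFrame) -> dict[str, float]:
        ok = tab["p"].notna() & tab["fc"].notna()
        return dict(
            zip(
                tab.index[ok],
                rank_statistic(tab.loc[ok, "fc"].to_numpy(), tab.loc[ok, "p"].to_numpy()),
            )
        )

    return scores(diff_a), scores(diff_b), diff_a, diff_b


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, (list, tuple))).any():
            out[col] = out[col].map(lambda v: ";".join(map(str, v)))
    out.to_csv(path, sep="\t")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any], output_dir: str | Path | None = None) -> dict:
    """Run every stage on the configured inputs; return the result bundle.

    Writes all intermediate tables plus ``manifest.json`` under the output
    directory.  Any stage error aborts with the stage name attached.
    """
    params = validate_params(config.get("params", {}))
    seed = int(config.get("seed", 0))
    out_dir = Path(output_dir or config.get("output_dir", "results/pipeline"))
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"params": params, "seed": seed}
    stage = "load_inputs"
    t0 = time.time()
    try:
        study = _load_inputs(config)
        ann = study.annotations

        stage = "normalize"
        proteome = median_center(study.proteome)

        stage = "batch_adjust"
        batches = ann.frame["batch"]
        if batches.nunique() > 1:
            proteome, _ = combat_adjust(proteome, batches)

        stage = "differential"
        sa, sb, diff_a, diff_b = _subgroup_scores(proteome, ann)
        ranked = combine_subgroup_ranks(sa, sb)
        comparators = ann.samples_where(is_reference=False, entity="ATRT") + \
            ann.samples_where(is_reference=False, entity="MB")
        etmr = ann.samples_where(entity="ETMR", is_reference=False)
        diff_all = differential_table(proteome, etmr, comparators, test="welch")
        morph = morphology_independent_selection(
            diff_a, diff_b, params["fc_threshold"], params["p_threshold"]
        )
        _write_tsv(diff_a, out_dir / "differential_etantr.tsv")
        _write_tsv(diff_b, out_dir / "differential_ebl_mepl.tsv")
        _write_tsv(diff_all, out_dir / "differential_etmr.tsv")
        _write_tsv(morph, out_dir / "morphology_independent.tsv")
        ranked.as_series().rename("score").to_csv(out_dir / "ranked_list.tsv", sep="\t")

        stage = "gsea"
        gsea = gsea_preranked(
            ranked,
            study.gene_sets,
            min_size=params["gsea_min_size"],
            max_size=params["gsea_max_size"],
            weight=params["gsea_weight"],
            n_perm=params["gsea_n_perm"],
            seed=seed,
        )
        _write_tsv(gsea, out_dir / "gsea_proteome.tsv")
        bundle["gsea_proteome"] = gsea

        gsea_rna = None
        if study.transcriptome is not None:
            ra, rb, _, _ = _subgroup_scores(study.transcriptome, ann)
            ranked_rna = combine_subgroup_ranks(ra, rb)
            gsea_rna = gsea_preranked(
                ranked_rna,
                study.gene_sets,
                min_size=params["gsea_min_size"],
                max_size=params["gsea_rna_max_size"],
                weight=params["gsea_weight"],
                n_perm=params["gsea_n_perm"],
                seed=seed + 1,
            )
            _write_tsv(gsea_rna, out_dir / "gsea_transcriptome.tsv")
            bundle["gsea_transcriptome"] = gsea_rna

        stage = "ora"
        sig_proteins = set(diff_all.index[diff_all["p"] <= params["p_threshold"]])
        universe = set(proteome.feature_ids)
        ora = ora_hypergeometric(
            sig_proteins,
            universe,
            study.gene_sets,
            min_size=params["gsea_min_size"],
            max_size=params["gsea_max_size"],
            p_threshold=params["p_threshold"],
            min_count=params["ora_min_count"],
        )
        _write_tsv(ora, out_dir / "ora_proteome.tsv")
        bundle["ora_proteome"] = ora

        stage = "methylome_link"
        methyl_terms: set[str] = set()
        if study.methylome is not None and study.cpg_annotation is not None and len(
            study.methylome.feature_ids
        ):
            tumor_samples = [
                s for s in study.methylome.sample_ids
                if s in ann.frame.index and not ann.frame.loc[s, "is_reference"]
            ]
            corr = correlation_table(
                study.methylome, proteome, study.cpg_annotation, tumor_samples
            )
            corr.to_csv(out_dir / "methylation_correlation.tsv", sep="\t", index=False)
            sig_corr = significant_genes(corr, params["alpha"]) & sig_proteins
            if sig_proteins:
                methyl_ora = methylation_ora(
                    sig_corr,
                    sig_proteins,
                    study.gene_sets,
                    min_size=params["methyl_min_size"],
                    max_size=params["methyl_max_size"],
                    min_count=params["methyl_min_count"],
                    min_fraction=params["methyl_min_fraction"],
                )
                _write_tsv(methyl_ora, out_dir / "methylation_ora.tsv")
                bundle["methylation_ora"] = methyl_ora
                methyl_terms = set(methyl_ora.index[methyl_ora["over_represented"]])
            bundle["methylation_correlation"] = corr

        stage = "triomics_overlap"
        prot_terms = set(gsea.index[gsea["significant"]])
        rna_terms = (
            set(gsea_rna.index[gsea_rna["significant"]]) if gsea_rna is not None else set()
        )
        venn = triomics_overlap(prot_terms, rna_terms, methyl_terms)
        (out_dir / "triomics_venn.json").write_text(
            json.dumps({k: v for k, v in venn.items()}, indent=2)
        )
        bundle["triomics_venn"] = venn

        stage = "clustering"
        top = select_top_variant(proteome, params["top_variant"])
        tumor = ann.samples_where(is_reference=False)
        sub = proteome.subset_features(top).subset_samples(tumor)
        consensus = consensus_cluster(
            sub,
            k_range=list(params["k_range"]),
            n_resamples=params["n_resamples"],
            subsample_frac=params["subsample_frac"],
            seed=seed,
        )
        consensus.consensus.to_csv(out_dir / "consensus_matrix.tsv", sep="\t")
        pd.DataFrame(consensus.assignments).to_csv(out_dir / "consensus_assignments.tsv", sep="\t")
        bundle["consensus"] = consensus

        stage = "manifest"
        files = sorted(p for p in out_dir.iterdir() if p.name != "manifest.json")
        manifest = {
            "seed": seed,
            "params": params,
            "outputs": {p.name: _sha256(p) for p in files},
            "truth": study.truth,
            "elapsed_s": round(time.time() - t0, 3),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        bundle["manifest"] = manifest
    except ValidationError as err:
        raise ValidationError(f"stage {stage!r}: {err}") from err
    logger.info("pipeline finished in %.1fs (outputs in %s)", time.time() - t0, out_dir)
    return bundle
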