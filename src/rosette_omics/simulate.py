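"""Synthetic multi-omics generator emulating an embryonal brain tumor case series.

The generator produces matched proteome / transcriptome / methylome matrices with
the statistical structure the downstream analyses assume: a case series of three
tumor entities (ETMR split into the ETANTR and EBL/MEPL histology subgroups,
plus AT/RT and MB comparators), gene sets planted with log2 abundance shifts in
ETMR, promoter CpGs whose beta values co- or anti-vary with their gene's protein
level, batch shift/scale effects with optional shared reference samples, and 4PL
viability curves.  Every planted effect is recorded in a truth record so tests
can check recovery.

Randomness uses ``numpy.random.default_rng`` (PCG64); a fixed seed reproduces
output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CpGAnnotationTable,
    DoseResponseTable,
    GeneSet,
    GeneSetCollection,
    OmicsMatrix,
    OntologyDAG,
    SampleTable,
    ValidationError,
)
from .dose_response import four_pl

__all__ = [
    "PlantedSet",
    "MethylLink",
    "SimulationConfig",
    "SimulatedStudy",
    "generate_multiomics",
    "generate_ontology",
    "generate_viability",
]

SCOPES = ("both", "ETANTR_only", "EBL_MEPL_only")


@dataclass(frozen=True)
class PlantedSet:
    set_id: str
    effect_size: float  # log2 units, added to ETMR samples in scope
    scope: str = "both"
    members: tuple[str, ...] | None = None  # explicit members; default: next free block

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValidationError(f"scope {self.scope!r} not in {SCOPES}")
        if not np.isfinite(self.effect_size):
            raise ValidationError("effect_size must be finite")


@dataclass(frozen=True)
class MethylLink:
    gene: str
    n_promoter_cpgs: int = 3
    sign: int = -1  # -1: promoter methylation anti-correlates with protein
    strength: float = 0.9  # latent correlation in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValidationError("strength must lie in [0, 1]")
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be -1 or +1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic case series.

    Defaults mirror the real series: 16 ETMR (8 ETANTR + 8 EBL/MEPL), 9 AT/RT,
    15 MB; one 20-gene set planted at +1.5 log2 units in all ETMR; residual
    log2 noise of 0.5 SD; a single batch with no shift/scale.
    """

    n_features: int = 200
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "ETMR_ETANTR": 8,
            "ETMR_EBL_MEPL": 8,
            "ATRT": 9,
            "MB": 15,
        }
    )
    planted_sets: Sequence[PlantedSet] = field(
        default_factory=lambda: (PlantedSet("SET_PLANTED", 1.5, "both"),)
    )
    n_background_sets: int = 24
    set_size: int = 20
    noise_sd: float = 0.5
    rna_attenuation: float = 0.7
    rna_noise_sd: float = 0.5
    batch_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"B1": (0.0, 1.0)}
    )
    n_reference_per_batch: int = 0
    reference_noise_sd: float = 0.1
    methyl_link: Sequence[MethylLink] = field(default_factory=tuple)
    n_background_cpgs: int = 50
    n_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group {grp!r} must have >= 2 samples")
        for shift, scale in self.batch_effects.values():
            if scale <= 0:
                raise ValidationError("batch scale factors must be > 0")


@dataclass
class SimulatedStudy:
    proteome: OmicsMatrix
    transcriptome: OmicsMatrix
    methylome: OmicsMatrix
    annotations: SampleTable
    cpg_annotation: CpGAnnotationTable
    gene_sets: GeneSetCollection
    truth: dict


def _sample_layout(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    specs = [
        ("ETMR_ETANTR", "ETANTR", "ETMR", "ETANTR"),
        ("ETMR_EBL_MEPL", "EBL", "ETMR", "EBL_MEPL"),
        ("ATRT", "ATRT", "ATRT", "none"),
        ("MB", "MB", "MB", "none"),
    ]
    for key, prefix, entity, subgroup in specs:
        for i in range(config.group_sizes[key]):
            rows.append(
                {
                    "sample_id": f"{prefix}_{i + 1:02d}",
                    "entity": entity,
                    "subgroup": subgroup,
                    "pair_id": None,
                    "is_reference": False,
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    # microdissection pairs: one ETANTR-like and one EBL/MEPL-like area per tumor
    etantr = [s for s in df.index if s.startswith("ETANTR_")]
    ebl = [s for s in df.index if s.startswith("EBL_")]
    for k in range(min(config.n_pairs, len(etantr), len(ebl))):
        df.loc[etantr[k], "pair_id"] = f"P{k + 1:02d}"
        df.loc[ebl[k], "pair_id"] = f"P{k + 1:02d}"
    batches = list(config.batch_effects)
    df["batch"] = [batches[i % len(batches)] for i in range(len(df))]
    return df


def generate_multiomics(config: SimulationConfig) -> SimulatedStudy:
    """Generate matched proteome, transcriptome and methylome fixtures.

    Baseline per-feature means are N(0, 1); planted sets are shifted by their
    effect size in the ETMR samples their scope covers; the transcriptome
    tracks the proteome with a configurable attenuation; promoter CpG beta
    values are a logistic squash of a latent Gaussian correlated with the
    gene's protein level; batch shift/scale is applied after the signal.
    """
    rng = np.random.default_rng(config.seed)
    layout = _sample_layout(config)
    features = [f"GENE{i + 1:04d}" for i in range(config.n_features)]

    # --- gene sets: planted sets take disjoint leading blocks, background random
    warnings: list[str] = []
    sets: list[GeneSet] = []
    cursor = 0
    planted_members: dict[str, frozenset[str]] = {}
    for ps in config.planted_sets:
        if ps.members is not None:
            unknown = set(ps.members) - set(features)
            if unknown:
                raise ValidationError(
                    f"planted set {ps.set_id!r} has unknown member(s): {sorted(unknown)}"
                )
            members = frozenset(ps.members)
        else:
            block = features[cursor : cursor + config.set_size]
            if len(block) < config.set_size:
                raise ValidationError("n_features too small for the planted sets")
            cursor += config.set_size
            members = frozenset(block)
        planted_members[ps.set_id] = members
        sets.append(GeneSet(ps.set_id, f"planted {ps.scope}", members))
    for a in config.planted_sets:
        for b in config.planted_sets:
            if a.set_id < b.set_id:
                inter = planted_members[a.set_id] & planted_members[b.set_id]
                smaller = min(len(planted_members[a.set_id]), len(planted_members[b.set_id]))
                if len(inter) > 0.5 * smaller:
                    warnings.append(
                        f"planted sets {a.set_id} and {b.set_id} share >50% of members "
                        "(confounded design)"
                    )
    # background sets are genuinely null: drawn from features carrying no
    # planted effect, so downstream false-positive rates are interpretable
    planted_union = set().union(*planted_members.values()) if planted_members else set()
    null_pool = [f for f in features if f not in planted_union]
    if len(null_pool) < config.set_size:
        null_pool = features
    for j in range(config.n_background_sets):
        members = frozenset(
            rng.choice(null_pool, size=config.set_size, replace=False).tolist()
        )
        sets.append(GeneSet(f"SET_BG{j + 1:03d}", "background", members))
    gene_sets = GeneSetCollection(sets)

    # --- proteome signal
    mu = rng.normal(0.0, 1.0, size=config.n_features)
    prot = np.tile(mu[:, None], (1, len(layout)))
    feat_index = {g: i for i, g in enumerate(features)}
    is_etantr = (layout["subgroup"] == "ETANTR").to_numpy()
    is_ebl = (layout["subgroup"] == "EBL_MEPL").to_numpy()
    for ps in config.planted_sets:
        cols = is_etantr | is_ebl if ps.scope == "both" else (
            is_etantr if ps.scope == "ETANTR_only" else is_ebl
        )
        idx = [feat_index[g] for g in sorted(planted_members[ps.set_id])]
        prot[np.ix_(idx, np.flatnonzero(cols))] += ps.effect_size
    signal = prot.copy()
    prot = prot + rng.normal(0.0, config.noise_sd, size=prot.shape)

    # --- transcriptome: attenuated protein signal plus its own noise
    rna = (
        mu[:, None]
        + config.rna_attenuation * (signal - mu[:, None])
        + rng.normal(0.0, config.rna_noise_sd, size=signal.shape)
    )

    # --- methylome: latent Gaussian correlated with protein, logistic squash
    cpg_rows = []
    betas = []
    prot_z = (prot - prot.mean(axis=1, keepdims=True)) / np.where(
        prot.std(axis=1, keepdims=True) == 0, 1.0, prot.std(axis=1, keepdims=True)
    )
    promoter_cycle = ["TSS200", "TSS1500", "UTR5"]
    for link in config.methyl_link:
        if link.gene not in feat_index:
            raise ValidationError(f"methyl_link gene {link.gene!r} not among features")
        z = prot_z[feat_index[link.gene]]
        for c in range(link.n_promoter_cpgs):
            eps = rng.normal(0.0, 1.0, size=len(layout))
            latent = link.sign * link.strength * z + np.sqrt(
                max(0.0, 1.0 - link.strength**2)
            ) * eps
            betas.append(1.0 / (1.0 + np.exp(-latent)))
            cpg_rows.append(
                {
                    "cpg_id": f"cg_{link.gene}_{c + 1:02d}",
                    "gene": link.gene,
                    "region": promoter_cycle[c % 3],
                    "chromosome": "1",
                    "flags": frozenset(),
                }
            )
    bg_genes = rng.choice(features, size=config.n_background_cpgs, replace=True)
    for c, g in enumerate(bg_genes):
        latent = rng.normal(0.0, 1.0, size=len(layout))
        betas.append(1.0 / (1.0 + np.exp(-latent)))
        cpg_rows.append(
            {
                "cpg_id": f"cg_bg_{c + 1:04d}",
                "gene": str(g),
                "region": "body" if c % 2 == 0 else "other",
                "chromosome": "2",
                "flags": frozenset(),
            }
        )
    beta_mat = np.vstack(betas) if betas else np.empty((0, len(layout)))
    cpg_frame = pd.DataFrame(cpg_rows).set_index("cpg_id") if cpg_rows else pd.DataFrame(
        columns=["gene", "region", "chromosome", "flags"]
    )

    # --- reference samples: replicate-like draws shared across batches
    sample_ids = list(layout.index)
    ann = layout.copy()
    if config.n_reference_per_batch > 0:
        ref_mu = rng.normal(0.0, 1.0, size=(config.n_features, config.n_reference_per_batch))
        for batch in config.batch_effects:
            noise = rng.normal(
                0.0, config.reference_noise_sd, size=ref_mu.shape
            )
            prot = np.hstack([prot, ref_mu + noise])
            rna = np.hstack([rna, ref_mu + noise])
            if beta_mat.size:
                beta_mat = np.hstack(
                    [beta_mat, np.full((beta_mat.shape[0], config.n_reference_per_batch), 0.5)]
                )
            for r in range(config.n_reference_per_batch):
                sid = f"REF{r + 1:02d}_{batch}"
                sample_ids.append(sid)
                ann.loc[sid] = {
                    "entity": "MB",
                    "subgroup": "none",
                    "pair_id": None,
                    "is_reference": True,
                    "batch": batch,
                }

    # --- batch shift/scale applied after signal
    for j, sid in enumerate(sample_ids):
        shift, scale = config.batch_effects[ann.loc[sid, "batch"]]
        prot[:, j] = prot[:, j] * scale + shift
        rna[:, j] = rna[:, j] * scale + shift

    proteome = OmicsMatrix(
        pd.DataFrame(prot, index=features, columns=sample_ids), "proteome"
    )
    transcriptome = OmicsMatrix(
        pd.DataFrame(rna, index=features, columns=sample_ids), "transcriptome"
    )
    methylome = OmicsMatrix(
        pd.DataFrame(beta_mat, index=list(cpg_frame.index), columns=sample_ids),
        "methylome",
    )
    truth = {
        "planted_sets": [
            {
                "set_id": ps.set_id,
                "effect_size": ps.effect_size,
                "scope": ps.scope,
                "members": sorted(planted_members[ps.set_id]),
            }
            for ps in config.planted_sets
        ],
        "methyl_links": [
            {
                "gene": l.gene,
                "n_promoter_cpgs": l.n_promoter_cpgs,
                "sign": l.sign,
                "strength": l.strength,
            }
            for l in config.methyl_link
        ],
        "batch_effects": {b: list(e) for b, e in config.batch_effects.items()},
        "group_sizes": dict(config.group_sizes),
        "seed": config.seed,
        "warnings": warnings,
    }
    return SimulatedStudy(
        proteome=proteome,
        transcriptome=transcriptome,
        methylome=methylome,
        annotations=SampleTable(ann),
        cpg_annotation=CpGAnnotationTable(cpg_frame),
        gene_sets=gene_sets,
        truth=truth,
    )


def generate_ontology(
    n_terms: int,
    depth: int,
    seed: int,
    genes: Sequence[str] | None = None,
    genes_per_leaf: int = 8,
) -> OntologyDAG:
    """Generate a rooted is_a DAG with gene annotations and a planted redundant pair.

    Terms are spread over ``depth`` levels below a single root; each term takes
    a random parent one level up.  Childless terms annotate near-disjoint gene
    blocks.  For ``depth >= 2`` two extra sibling terms sharing > 80% of their
    genes are planted under a dedicated parent (recorded in
    ``dag.graph.graph['redundant_pair']``), giving Resnik/Lin similarity above
    the pipeline's 0.4 redundancy threshold.
    """
    import networkx as nx

    if n_terms < 3:
        raise ValidationError("n_terms must be >= 3")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    ns = "biological_process"
    root = "T0001"
    graph.add_node(root, name="root", namespace=ns)
    levels: list[list[str]] = [[root]]
    remaining = n_terms - 1
    per_level = max(1, remaining // depth)
    tid = 2
    for level in range(1, depth + 1):
        count = per_level if level < depth else remaining - per_level * (depth - 1)
        members = []
        for _ in range(max(0, count)):
            term = f"T{tid:04d}"
            tid += 1
            parent = levels[level - 1][rng.integers(0, len(levels[level - 1]))]
            graph.add_node(term, name=f"term {term}", namespace=ns)
            graph.add_edge(term, parent)
            # occasional second parent to exercise the DAG (not a tree)
            if level >= 2 and rng.random() < 0.2:
                alt = levels[level - 1][rng.integers(0, len(levels[level - 1]))]
                if alt != parent:
                    graph.add_edge(term, alt)
            members.append(term)
        levels.append(members)

    leaves = [t for t in graph.nodes if graph.in_degree(t) == 0 and t != root]
    if not leaves:
        leaves = [t for t in graph.nodes if t != root]
    n_needed = len(leaves) * genes_per_leaf + genes_per_leaf + 2
    pool = list(genes) if genes is not None else [f"GENE{i + 1:04d}" for i in range(n_needed)]
    annotations: dict[str, set[str]] = {}
    cursor = 0
    for leaf in sorted(leaves):
        block = [pool[(cursor + k) % len(pool)] for k in range(genes_per_leaf)]
        cursor += genes_per_leaf
        # one random extra gene keeps blocks only disjoint-ish
        block.append(pool[int(rng.integers(0, len(pool)))])
        annotations[leaf] = set(block)

    if depth >= 2:
        parent = "TRED_P"
        a, b = "TRED_A", "TRED_B"
        graph.add_node(parent, name="redundant parent", namespace=ns)
        graph.add_edge(parent, root)
        shared = [pool[(cursor + k) % len(pool)] for k in range(genes_per_leaf + 1)]
        cursor += genes_per_leaf + 1
        for term, extra in ((a, 0), (b, 1)):
            graph.add_node(term, name=f"redundant {term}", namespace=ns)
            graph.add_edge(term, parent)
        annotations[a] = set(shared)
        annotations[b] = set(shared[:-1]) | {pool[(cursor + 1) % len(pool)]}
        graph.graph["redundant_pair"] = (a, b)

    return OntologyDAG(graph, annotations)


def generate_viability(
    true_params: tuple[float, float, float, float],
    concentrations: Sequence[float],
    cv: float,
    n_reps: int,
    seed: int,
    cell_line: str = "SIM",
) -> DoseResponseTable:
    """Simulate a viability assay: 4PL(conc) x (1 + N(0, cv)) per replicate."""
    bottom, top, hill, ic50 = true_params
    if ic50 <= 0:
        raise ValidationError("ic50 must be > 0")
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    rows = []
    for x in conc:
        y = four_pl(x, bottom, top, hill, ic50)
        noise = rng.normal(0.0, cv, size=n_reps) if cv > 0 else np.zeros(n_reps)
        for r in range(n_reps):
            rows.append({"concentration": x, "response": y * (1.0 + noise[r])})
    return DoseResponseTable(pd.DataFrame(rows), cell_line)
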