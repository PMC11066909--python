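"""Domain types shared by all pipeline stages, plus plain-text readers/writers.

The pipeline's common currency is the :class:`OmicsMatrix` — a features x samples
matrix of log2 protein/RNA abundance or methylation beta values — together with a
per-sample annotation table carrying tumor entity (ETMR / AT/RT / MB), the ETMR
histology subgroup (ETANTR vs EBL/MEPL), batch and microdissection-pair labels.
Gene sets travel as GMT collections and the gene ontology as a minimal is_a DAG
with gene annotations from which information content is derived.

All on-disk formats are UTF-8 text: tab-separated matrices ("." decimal, missing
cells empty or "NA"), Broad-dialect GMT, and an OBO subset ([Term] stanzas with
id / name / namespace / is_a only; obsolete terms skipped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ASSAY_KINDS",
    "ENTITIES",
    "SUBGROUPS",
    "REGIONS",
    "PROMOTER_REGIONS",
    "CPG_FLAGS",
    "OmicsMatrix",
    "SampleTable",
    "GeneSet",
    "GeneSetCollection",
    "OntologyDAG",
    "CpGAnnotationTable",
    "DoseResponseTable",
    "read_matrix",
    "write_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
    "read_obo_lite",
    "write_obo_lite",
    "read_cpg_annotation",
    "write_cpg_annotation",
    "read_dose_response",
    "write_dose_response",
]


class ValidationError(ValueError):
    """An input violates a documented type invariant."""


ASSAY_KINDS = frozenset({"proteome", "transcriptome", "methylome"})
ENTITIES = frozenset({"ETMR", "ATRT", "MB", "other"})
SUBGROUPS = frozenset({"ETANTR", "EBL_MEPL", "none"})
REGIONS = frozenset({"TSS200", "TSS1500", "UTR5", "body", "other"})
#: Promoter association per the ChAMP-style region classes.
PROMOTER_REGIONS = frozenset({"TSS200", "TSS1500", "UTR5"})
CPG_FLAGS = frozenset({"sex_chromosome", "snp_at_cpg", "cross_reactive"})

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {sorted(set(dups))}")


@dataclass
class OmicsMatrix:
    """Features x samples numeric matrix with an assay kind.

    ``values`` is a float DataFrame indexed by feature id with sample ids as
    columns.  Missing values are NaN.  Methylome matrices must hold beta values
    in [0, 1].
    """

    values: pd.DataFrame
    assay_kind: str

    def __post_init__(self) -> None:
        if self.assay_kind not in ASSAY_KINDS:
            raise ValidationError(
                f"assay_kind {self.assay_kind!r} not in {sorted(ASSAY_KINDS)}"
            )
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        self.values = self.values.astype(float)
        if self.assay_kind == "methylome":
            arr = self.values.to_numpy()
            with np.errstate(invalid="ignore"):
                bad = (arr < 0) | (arr > 1)
            if np.any(bad & ~np.isnan(arr)):
                i, j = np.argwhere(bad & ~np.isnan(arr))[0]
                raise ValidationError(
                    "methylome beta outside [0,1] at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[:, list(sample_ids)].copy(), self.assay_kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(feature_ids), :].copy(), self.assay_kind)

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values, self.assay_kind)


_SAMPLE_COLUMNS = ["sample_id", "entity", "subgroup", "batch", "pair_id", "is_reference"]


@dataclass
class SampleTable:
    """Per-sample annotations: entity, histology subgroup, batch, pair, reference flag.

    Invariants: the subgroup is only meaningful for ETMR samples; a
    microdissection pair id occurs exactly twice and spans the two histology
    subgroups (a neuropil-rich / ETANTR-like area paired with a primitive
    EBL/MEPL-like area of the same tumor).
    """

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("entity", "subgroup", "batch", "pair_id", "is_reference"):
            if col not in df.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        _check_unique(list(df.index), "sample")
        bad_entity = set(df["entity"]) - ENTITIES
        if bad_entity:
            raise ValidationError(f"unknown entity value(s): {sorted(bad_entity)}")
        bad_sub = set(df["subgroup"]) - SUBGROUPS
        if bad_sub:
            raise ValidationError(f"unknown subgroup value(s): {sorted(bad_sub)}")
        off = df[(df["subgroup"] != "none") & (df["entity"] != "ETMR")]
        if len(off):
            raise ValidationError(
                f"subgroup set for non-ETMR sample(s): {list(off.index)}"
            )
        pairs = df.loc[df["pair_id"].notna() & (df["pair_id"] != ""), "pair_id"]
        for pid, members in df.loc[pairs.index].groupby("pair_id"):
            if len(members) != 2 or len(set(members["subgroup"])) != 2:
                raise ValidationError(
                    f"pair_id {pid!r} must occur exactly twice with distinct subgroups"
                )
        self.frame = df.assign(is_reference=df["is_reference"].astype(bool))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_where(self, **conditions: object) -> list[str]:
        """Sample ids matching all column == value conditions."""
        mask = pd.Series(True, index=self.frame.index)
        for col, val in conditions.items():
            mask &= self.frame[col] == val
        return list(self.frame.index[mask])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.frame.loc[list(sample_ids)].copy())


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")


class GeneSetCollection(Mapping[str, GeneSet]):
    """Named gene sets keyed by set id."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in self._sets:
                raise ValidationError(f"duplicate gene set id {s.set_id!r}")
            self._sets[s.set_id] = s

    def __getitem__(self, key: str) -> GeneSet:
        return self._sets[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {k: v.members for k, v in self._sets.items()} == {
            k: v.members for k, v in other._sets.items()
        }


class OntologyDAG:
    """Rooted is_a DAG over ontology terms with gene annotations.

    Edges run child -> parent.  Gene annotations are propagated upward: the
    annotation of a term is the union of its own genes and those of all its
    descendants, so annotation counts grow monotonically toward the root.
    Information content is IC(t) = -log(n_annotated(t) / n_annotated(root)),
    giving IC(root) = 0.
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        annotations: Mapping[str, Iterable[str]] | None = None,
    ):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValidationError(f"is_a cycle involving term {cycle[0][0]!r}")
        self.graph = graph
        self.raw_annotations: dict[str, frozenset[str]] = {
            t: frozenset(annotations.get(t, ())) if annotations else frozenset()
            for t in graph.nodes
        }
        if annotations:
            unknown = set(annotations) - set(graph.nodes)
            if unknown:
                raise ValidationError(f"annotations for unknown term(s): {sorted(unknown)}")
        self._propagated: dict[str, frozenset[str]] | None = None
        self._roots: dict[str, str] = {}
        for t in graph.nodes:
            if graph.out_degree(t) == 0:
                ns = self.namespace(t)
                if ns in self._roots:
                    raise ValidationError(
                        f"namespace {ns!r} has multiple roots: "
                        f"{self._roots[ns]!r}, {t!r}"
                    )
                self._roots[ns] = t

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "default")

    def root(self, namespace: str = "default") -> str:
        return self._roots[namespace]

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    def children(self, term: str) -> list[str]:
        return list(self.graph.predecessors(term))

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        anc = nx.descendants(self.graph, term)  # reachable via child->parent
        if include_self:
            anc = anc | {term}
        return anc

    def propagated_annotations(self) -> dict[str, frozenset[str]]:
        if self._propagated is None:
            acc: dict[str, set[str]] = {t: set(self.raw_annotations[t]) for t in self.graph}
            for t in nx.topological_sort(self.graph):  # children before parents
                for p in self.graph.successors(t):
                    acc[p] |= acc[t]
            self._propagated = {t: frozenset(g) for t, g in acc.items()}
        return self._propagated

    def annotated_genes(self, term: str) -> frozenset[str]:
        return self.propagated_annotations()[term]

    def ic(self, term: str) -> float:
        """Information content from annotation frequency; IC(root) = 0."""
        ann = self.propagated_annotations()
        n_t = len(ann[term])
        n_root = len(ann[self.root(self.namespace(term))])
        if n_t == 0 or n_root == 0:
            raise ValidationError(f"IC undefined: term {term!r} has no annotated genes")
        return -math.log(n_t / n_root)

    def max_ic(self, namespace: str = "default") -> float:
        ann = self.propagated_annotations()
        ics = [
            self.ic(t)
            for t in self.graph.nodes
            if self.namespace(t) == namespace and len(ann[t]) > 0
        ]
        return max(ics) if ics else 0.0


@dataclass
class CpGAnnotationTable:
    """CpG probe annotations: gene, region class, chromosome, exclusion flags.

    ``frame`` is indexed by cpg_id with columns gene, region, chromosome and
    ``flags`` holding a (possibly empty) frozenset of exclusion flags.
    An optional detection-p matrix (CpG x sample) rides along.
    """

    frame: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("gene", "region", "chromosome", "flags"):
            if col not in self.frame.columns:
                raise ValidationError(f"CpG annotation missing column {col!r}")
        _check_unique(list(self.frame.index), "cpg")
        bad = set(self.frame["region"]) - REGIONS
        if bad:
            raise ValidationError(f"unknown region value(s): {sorted(bad)}")
        for cpg, flags in self.frame["flags"].items():
            unknown = set(flags) - CPG_FLAGS
            if unknown:
                raise ValidationError(f"unknown flag(s) {sorted(unknown)} for {cpg!r}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.frame.index)


@dataclass
class DoseResponseTable:
    """Viability responses per concentration x replicate for one cell line.

    ``frame`` is long-format with columns concentration (molar, > 0) and
    response (luminescence, arbitrary units).
    """

    frame: pd.DataFrame
    cell_line: str

    def __post_init__(self) -> None:
        for col in ("concentration", "response"):
            if col not in self.frame.columns:
                raise ValidationError(f"dose-response table missing column {col!r}")
        conc = self.frame["concentration"].to_numpy(float)
        if np.any(conc <= 0) or np.any(~np.isfinite(conc)):
            raise ValidationError("concentrations must be finite and > 0 (molar)")
        if len(np.unique(conc)) < 4:
            raise ValidationError("need >= 4 distinct concentrations")

    @property
    def concentrations(self) -> np.ndarray:
        return self.frame["concentration"].to_numpy(float)

    @property
    def responses(self) -> np.ndarray:
        return self.frame["response"].to_numpy(float)


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path: str | Path, assay_kind: str) -> OmicsMatrix:
    """Read a features x samples TSV (header = sample ids, first column = feature ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    _check_unique(list(raw.index), "feature")
    _check_unique(list(raw.columns), "sample")
    out = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float)
    for col in raw.columns:
        cell = raw[col].astype(str).str.strip()
        converted = np.full(len(cell), np.nan)
        for i, (feat, sval) in enumerate(cell.items()):
            if sval in _MISSING_TOKENS:
                continue
            try:
                converted[i] = float(sval)  # correctly-rounded parse
            except ValueError:
                raise ValidationError(
                    f"non-numeric cell at feature {feat!r}, sample {col!r}: {sval!r}"
                ) from None
        out[col] = converted
    out.index.name = "feature_id"
    return OmicsMatrix(out, assay_kind)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    # shortest round-trip float repr keeps write -> read -> write bitwise stable
    df = m.values.map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sample table missing column(s): {sorted(missing)}")
    df = df.set_index("sample_id")
    df["pair_id"] = df["pair_id"].replace("", None)
    df["is_reference"] = df["is_reference"].str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if df["is_reference"].isna().any():
        raise ValidationError("is_reference must be true/false")
    return SampleTable(df)


def write_sample_table(t: SampleTable, path: str | Path) -> None:
    df = t.frame.copy()
    df["pair_id"] = df["pair_id"].fillna("")
    df["is_reference"] = df["is_reference"].map({True: "true", False: "false"})
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            set_id, name, *members = fields
            sets.append(GeneSet(set_id, name, frozenset(m for m in members if m)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(collection):
            s = collection[set_id]
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_obo_lite(path: str | Path) -> OntologyDAG:
    """Parse an OBO subset: [Term] stanzas with id, name, namespace, is_a.

    Unknown tags are ignored; obsolete terms are skipped entirely.
    """
    graph = nx.DiGraph()
    edges: list[tuple[str, str]] = []
    current: dict[str, object] | None = None

    def flush() -> None:
        nonlocal current
        if current is None or current.get("obsolete"):
            current = None
            return
        tid = current.get("id")
        if tid is None:
            raise ValidationError("[Term] stanza without an id")
        graph.add_node(
            tid,
            name=current.get("name", tid),
            namespace=current.get("namespace", "default"),
        )
        for parent in current.get("parents", []):  # type: ignore[union-attr]
            edges.append((tid, parent))
        current = None

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                flush()
                current = {"parents": []}
            elif line.startswith("[") and line.endswith("]"):
                flush()  # non-Term stanza: ignore contents
            elif current is not None and ":" in line:
                tag, _, value = line.partition(":")
                value = value.split("!")[0].strip()
                tag = tag.strip()
                if tag == "id":
                    current["id"] = value
                elif tag == "name":
                    current["name"] = value
                elif tag == "namespace":
                    current["namespace"] = value
                elif tag == "is_a":
                    current["parents"].append(value)  # type: ignore[union-attr]
                elif tag == "is_obsolete" and value.lower() == "true":
                    current["obsolete"] = True
    flush()
    for child, parent in edges:
        if parent not in graph:
            raise ValidationError(f"is_a target {parent!r} is not a defined term")
        graph.add_edge(child, parent)
    return OntologyDAG(graph)


def write_obo_lite(dag: OntologyDAG, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(dag.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {dag.name(t)}\n")
            fh.write(f"namespace: {dag.namespace(t)}\n")
            for p in sorted(dag.parents(t)):
                fh.write(f"is_a: {p}\n")


def read_cpg_annotation(
    path: str | Path, detection_p_path: str | Path | None = None
) -> CpGAnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"cpg_id", "gene", "region", "chromosome", "flags"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"CpG annotation missing column(s): {sorted(missing)}")
    df = df.set_index("cpg_id")
    df["flags"] = df["flags"].map(
        lambda s: frozenset(f for f in s.split(";") if f) if s else frozenset()
    )
    det = None
    if detection_p_path is not None:
        det = read_matrix(detection_p_path, "methylome").values
    return CpGAnnotationTable(df, det)


def write_cpg_annotation(t: CpGAnnotationTable, path: str | Path) -> None:
    df = t.frame.copy()
    df["flags"] = df["flags"].map(lambda s: ";".join(sorted(s)))
    df.index.name = "cpg_id"
    df.to_csv(path, sep="\t")


def read_dose_response(path: str | Path) -> list[DoseResponseTable]:
    """Read a long-format TSV (cell_line, concentration, response) into per-line tables."""
    df = pd.read_csv(path, sep="\t")
    needed = {"cell_line", "concentration", "response"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"dose-response TSV missing column(s): {sorted(missing)}")
    return [
        DoseResponseTable(g[["concentration", "response"]].reset_index(drop=True), str(line))
        for line, g in df.groupby("cell_line", sort=True)
    ]


def write_dose_response(tables: Sequence[DoseResponseTable], path: str | Path) -> None:
    frames = []
    for t in tables:
        f = t.frame.copy()
        f.insert(0, "cell_line", t.cell_line)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
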