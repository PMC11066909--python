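"""Preranked GSEA, hypergeometric ORA, ssGSEA, and semantic-redundancy filtering.

GSEA follows the weighted Kolmogorov-Smirnov running sum: walking down the
ranked list, in-set genes add |score|^weight (normalized to the in-set total)
and out-of-set genes subtract 1/(N-K); the enrichment score ES is the maximum
deviation from zero.  The null is gene-label permutation of set membership
(phenotype permutation is impossible for a preranked list); NES divides ES by
the mean of same-sign null scores and the nominal p is the one-sided
permutation tail with a +1 pseudocount.  BH adjustment is applied across the
retained sets of one analysis.

ORA uses the upper hypergeometric tail P(X >= k) within the detection
universe; a term is called over-represented at p < 0.05 with more than 4
overlapping proteins.

GO term redundancy is judged by information-content similarity: IC derives
from propagated gene-annotation frequencies, Resnik similarity (IC of the
most informative common ancestor) is normalized by the namespace's maximum IC
so the shared 0.4 threshold is meaningful, and Lin similarity is
2 IC(MICA) / (IC(t1) + IC(t2)).  A term is dropped when BOTH similarities to
an already-kept, more significant term exceed the threshold.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection, OntologyDAG, ValidationError
from .differential import RankedList

__all__ = [
    "bh_adjust",
    "enrichment_score",
    "gsea_preranked",
    "ora_hypergeometric",
    "ssgsea_score",
    "term_similarity",
    "redundancy_filter",
]

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _es_candidates(positions: np.ndarray, weights: np.ndarray, n: int):
    """ES from sorted hit positions via the piecewise running-sum extrema.

    ``positions`` are 1-based hit positions sorted ascending (last axis),
    ``weights`` the matching |score|^weight values.  The running sum attains
    its local maxima immediately after hits and local minima immediately
    before hits, so only those 2K candidates need inspection.
    """
    k = positions.shape[-1]
    wsum = weights.sum(axis=-1, keepdims=True)
    # degenerate all-zero hit weights fall back to the unweighted statistic
    uniform = np.broadcast_to(wsum <= 0, weights.shape)
    w = np.where(uniform, 1.0, weights)
    wsum = w.sum(axis=-1, keepdims=True)
    cum = np.cumsum(w, axis=-1)
    miss_step = 0.0 if n == k else 1.0 / (n - k)
    j = np.arange(1, k + 1, dtype=float)
    after = cum / wsum - (positions - j) * miss_step
    before = (cum - w) / wsum - (positions - j) * miss_step
    # positive extrema sit just after hits, negative ones just before; on a
    # |tie| (within fp tolerance) the positive extremum wins
    cmax = after.max(axis=-1)
    cmin = before.min(axis=-1)
    es = np.where(cmax + cmin >= -1e-12, cmax, cmin)
    return es, after.argmax(axis=-1), before.argmin(axis=-1)


def enrichment_score(
    ranked: RankedList, members: set[str] | frozenset[str], weight: float = 1.0
) -> tuple[float, list[str]]:
    """Weighted KS enrichment score and leading-edge genes for one set."""
    hit_mask = np.array([g in members for g in ranked.genes])
    k = int(hit_mask.sum())
    n = len(ranked)
    if k == 0:
        raise ValidationError("gene set has no overlap with the ranked list")
    positions = np.flatnonzero(hit_mask) + 1
    weights = np.abs(ranked.scores[hit_mask]) ** weight
    es, argmax_after, argmin_before = _es_candidates(positions.astype(float), weights, n)
    es = float(es)
    # leading edge: hits at/above the extremum for positive ES, at/below for negative
    if es >= 0:
        edge_pos = positions[: int(argmax_after) + 1]
    else:
        edge_pos = positions[int(argmin_before):]
    leading = [ranked.genes[p - 1] for p in edge_pos]
    return es, leading


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 250,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA over a collection, permutation null on set membership.

    Sets are intersected with the ranked genes and kept when the overlap lies
    in [min_size, max_size]; sets with empty overlap are skipped with a log
    entry.  Returns one row per retained set: es, nes, p (permutation tail,
    +1 pseudocount), q (BH across retained sets), size, leading_edge, n_perm.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if seed is None:
        raise ValidationError("a permutation seed is required for reproducibility")
    gene_index = set(ranked.genes)
    n = len(ranked)
    retained: list[tuple[str, frozenset[str]]] = []
    for set_id in sets:
        overlap = sets[set_id].members & gene_index
        if not overlap:
            logger.info("gsea: set %s has no overlap with the ranked list", set_id)
            continue
        if min_size <= len(overlap) <= max_size:
            retained.append((set_id, frozenset(overlap)))
    if not retained:
        raise ValidationError("no gene set passed the size filter")

    rng = np.random.default_rng(seed)
    abs_w = np.abs(ranked.scores) ** weight
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for set_id, members in retained:
        es, leading = enrichment_score(ranked, members, weight)
        k = len(members)
        if k not in null_cache:
            # random K-subsets of positions = gene-label permutation of membership
            perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
            perm_pos.sort(axis=1)
            w = abs_w[perm_pos]
            null_es, _, _ = _es_candidates((perm_pos + 1).astype(float), w, n)
            null_cache[k] = null_es
        null_es = null_cache[k]
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (extreme + 1) / (n_same + 1)
        mean_same = float(np.abs(null_es[same_sign]).mean()) if n_same else np.nan
        nes = es / mean_same if n_same and mean_same > 0 else np.nan
        rows.append(
            {
                "set_id": set_id,
                "es": es,
                "nes": nes,
                "p": p,
                "size": k,
                "leading_edge": leading,
                "n_perm": n_perm,
            }
        )
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= 0.05
    return out.sort_values(["p", "set_id"], kind="mergesort")


def ora_hypergeometric(
    hits: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 250,
    p_threshold: float = 0.05,
    min_count: int = 5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within ``universe``.

    p is the upper tail P(X >= k) for overlap k, set size K within the
    universe, |hits| draws from a universe of size N.  The over-representation
    call requires p < p_threshold AND k >= min_count (the default min_count of
    5 encodes "protein counts higher than 4").
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValidationError("hits must be a subset of the universe")
    n_hits = len(hits)
    n_universe = len(universe)
    rows = []
    for set_id in sets:
        members_u = sets[set_id].members & universe
        if not min_size <= len(members_u) <= max_size:
            continue
        k = len(members_u & hits)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(members_u), n_hits))
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "K": len(members_u),
                "n": n_hits,
                "N": n_universe,
                "p": min(p, 1.0),
                "members": sorted(members_u & hits),
            }
        )
    if not rows:
        raise ValidationError("no gene set passed the size filter")
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["over_represented"] = (out["p"] < p_threshold) & (out["k"] >= min_count)
    return out.sort_values(["p", "set_id"], kind="mergesort")


def ssgsea_score(
    sample_values: Mapping[str, float],
    members: set[str] | frozenset[str],
    alpha: float = 0.25,
) -> float:
    """Single-sample GSEA score: integrated gap between the rank-weighted
    in-set ECDF and the unweighted out-of-set ECDF.

    Genes are ordered by decreasing value (ties broken by gene id); the gene
    at position i from the top carries rank N - i + 1, weighted as
    rank^alpha for the in-set ECDF.
    """
    items = sorted(sample_values.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    n = len(genes)
    in_set = np.array([g in members for g in genes])
    k = int(in_set.sum())
    if k == 0:
        raise ValidationError("gene set has no overlap with the sample's genes")
    if k == n:
        return 0.0
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank N
    w = np.where(in_set, ranks**alpha, 0.0)
    denom = w.sum()
    p_in = np.cumsum(w) / denom
    p_out = np.cumsum(~in_set) / (n - k)
    return float(np.sum(p_in - p_out))


def term_similarity(dag: OntologyDAG, t1: str, t2: str) -> tuple[float, float]:
    """(normalized Resnik, Lin) similarity of two terms in one namespace.

    Resnik = IC of the most informative common ancestor (MICA), normalized by
    the namespace's maximum IC so it lies in [0, 1]; Lin = 2 IC(MICA) /
    (IC(t1) + IC(t2)).  A root MICA gives 0 for both.
    """
    ns1, ns2 = dag.namespace(t1), dag.namespace(t2)
    if ns1 != ns2:
        raise ValidationError(f"terms in different namespaces: {ns1!r} vs {ns2!r}")
    ann = dag.propagated_annotations()
    common = dag.ancestors(t1) & dag.ancestors(t2)
    annotated = [t for t in common if len(ann[t]) > 0]
    if not annotated:
        raise ValidationError("no annotated common ancestor; IC undefined")
    ic1, ic2 = dag.ic(t1), dag.ic(t2)
    mica_ic = max(dag.ic(t) for t in annotated)
    max_ic = dag.max_ic(ns1)
    resnik_norm = mica_ic / max_ic if max_ic > 0 else 0.0
    lin = 2.0 * mica_ic / (ic1 + ic2) if (ic1 + ic2) > 0 else 0.0
    return float(resnik_norm), float(lin)


def redundancy_filter(
    results: pd.DataFrame,
    dag: OntologyDAG,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Drop terms semantically redundant to more significant kept terms.

    ``results`` must be indexed by term id with a 'p' column.  Terms are
    scanned in ascending (p, term id) order; a term is removed when BOTH its
    normalized Resnik and Lin similarities to an already-kept term exceed the
    threshold.  Terms whose similarity cannot be computed (missing from the
    DAG, unannotated, or in another namespace) are kept.
    """
    # ascending p, ties broken by term id (stable sort after an index sort)
    ordered = results.loc[sorted(results.index)].sort_values("p", kind="mergesort")
    kept: list[str] = []
    for term in ordered.index:
        redundant = False
        for other in kept:
            try:
                resnik, lin = term_similarity(dag, term, other)
            except (ValidationError, KeyError):
                continue
            if resnik > threshold and lin > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(term)
    return results.loc[kept]
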