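"""Promoter-CpG / protein correlation analysis and the correlation-based ORA.

Promoter association means a CpG annotated to TSS200, TSS1500 or the 5'UTR of
a measured protein's gene.  Each promoter pair is tested by sample-wise
Spearman correlation across the embryonal tumor samples; p-values are adjusted
with the Benjamini-Yekutieli (BY) step-up over all tested pairs jointly (the
conservative family choice, valid under arbitrary dependence), and a protein
counts as significantly methylation-linked when at least one of its promoter
CpGs reaches BY-adjusted p <= .05.  The ORA of those proteins runs within the
universe of significantly differentially abundant proteins with set sizes
5-150, and calls a term over-represented when at least 2 and more than 10% of
its (in-universe) members are methylation-linked; the hypergeometric p is
still reported for transparency.

For small sample counts (n < 10) the Spearman p comes from exact enumeration
of all n! rank assignments instead of the t approximation.
"""

from __future__ import annotations

from itertools import permutations
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import (
    CpGAnnotationTable,
    GeneSetCollection,
    OmicsMatrix,
    PROMOTER_REGIONS,
    ValidationError,
)
from .enrichment import bh_adjust

__all__ = [
    "SpearmanResult",
    "promoter_pairs",
    "spearman_correlate",
    "by_adjust",
    "correlation_table",
    "significant_genes",
    "methylation_ora",
    "triomics_overlap",
]


def promoter_pairs(
    cpg_annotation: CpGAnnotationTable, proteome_features: Iterable[str]
) -> list[tuple[str, str]]:
    """(cpg, gene) pairs where the CpG is promoter-associated and the gene measured."""
    measured = set(proteome_features)
    frame = cpg_annotation.frame
    mask = frame["region"].isin(PROMOTER_REGIONS) & frame["gene"].isin(measured)
    return [(cpg, frame.loc[cpg, "gene"]) for cpg in frame.index[mask]]


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int
    undefined: bool = False  # constant input: rho has no value


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all n! rank assignments (ties averaged)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    sd = np.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
    perms = np.array(list(permutations(ry)))
    rhos = (perms - ry.mean()) @ rx_c / sd
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_correlate(beta, protein) -> SpearmanResult:
    """Spearman rho on average ranks with a two-sided p.

    Uses the t approximation for n >= 10 and exact permutation enumeration for
    smaller n.  Constant vectors yield an undefined (flagged) result instead
    of an error.
    """
    x = np.asarray(beta, dtype=float)
    y = np.asarray(protein, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must share their length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValidationError("need >= 4 complete sample pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(np.nan, np.nan, n, undefined=True)
    rho, p_t = stats.spearmanr(x, y)
    if n < 10:
        return SpearmanResult(float(rho), _exact_spearman_p(x, y, float(rho)), n)
    return SpearmanResult(float(rho), float(p_t), n)


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up: p_(i) * m * c(m) / i, monotone, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def correlation_table(
    methylome: OmicsMatrix,
    proteome: OmicsMatrix,
    cpg_annotation: CpGAnnotationTable,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every promoter (cpg, gene) pair, BY-adjusted.

    ``sample_ids`` restricts the correlation to a sample subset (defaults to
    the samples shared by both matrices).  Pairs with undefined correlation
    (constant input) are reported with NaN statistics and excluded from the
    BY family.
    """
    if sample_ids is None:
        sample_ids = [s for s in methylome.sample_ids if s in set(proteome.sample_ids)]
    sample_ids = list(sample_ids)
    if len(sample_ids) < 4:
        raise ValidationError("need >= 4 shared samples")
    pairs = promoter_pairs(cpg_annotation, proteome.feature_ids)
    pairs = [(c, g) for c, g in pairs if c in set(methylome.feature_ids)]
    rows = []
    for cpg, gene in pairs:
        res = spearman_correlate(
            methylome.values.loc[cpg, sample_ids].to_numpy(float),
            proteome.values.loc[gene, sample_ids].to_numpy(float),
        )
        rows.append(
            {
                "cpg": cpg,
                "gene": gene,
                "region": cpg_annotation.frame.loc[cpg, "region"],
                "rho": res.rho,
                "p": res.p,
                "n": res.n,
                "undefined": res.undefined,
            }
        )
    out = pd.DataFrame(
        rows, columns=["cpg", "gene", "region", "rho", "p", "n", "undefined"]
    )
    out["q"] = np.nan
    tested = ~out["undefined"] if len(out) else pd.Series(dtype=bool)
    if len(out) and tested.any():
        out.loc[tested, "q"] = by_adjust(out.loc[tested, "p"].to_numpy())
    return out


def significant_genes(corr: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes with at least one promoter CpG at BY-adjusted p <= alpha."""
    hit = corr.loc[corr["q"].notna() & (corr["q"] <= alpha), "gene"]
    return set(hit)


def methylation_ora(
    sig_genes: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 150,
    min_count: int = 2,
    min_fraction: float = 0.10,
) -> pd.DataFrame:
    """ORA of methylation-linked proteins within the differential universe.

    The over-representation call is the count rule: at least ``min_count`` and
    strictly more than ``min_fraction`` of the set's in-universe members must
    be methylation-linked.  The hypergeometric tail p (and its BH adjustment)
    is reported alongside for transparency.
    """
    sig_genes = set(sig_genes)
    universe = set(universe)
    if not sig_genes <= universe:
        raise ValidationError("significantly correlating genes must lie in the universe")
    rows = []
    for set_id in sets:
        members_u = sets[set_id].members & universe
        if not min_size <= len(members_u) <= max_size:
            continue
        k = len(members_u & sig_genes)
        frac = k / len(members_u)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members_u), len(sig_genes)))
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "K": len(members_u),
                "fraction": frac,
                "p": min(p, 1.0),
                "over_represented": (k >= min_count) and (frac > min_fraction),
                "members": sorted(members_u & sig_genes),
            }
        )
    if not rows:
        raise ValidationError("no gene set passed the size filter")
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "set_id"], kind="mergesort")


def triomics_overlap(
    proteome_terms: Iterable[str],
    transcriptome_terms: Iterable[str],
    methylome_terms: Iterable[str],
) -> dict[str, list[str]]:
    """Seven-region Venn partition of term ids across the three omics layers."""
    P, T, M = set(proteome_terms), set(transcriptome_terms), set(methylome_terms)
    return {
        "proteome_only": sorted(P - T - M),
        "transcriptome_only": sorted(T - P - M),
        "methylome_only": sorted(M - P - T),
        "proteome_transcriptome": sorted((P & T) - M),
        "proteome_methylome": sorted((P & M) - T),
        "transcriptome_methylome": sorted((T & M) - P),
        "all_three": sorted(P & T & M),
    }
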