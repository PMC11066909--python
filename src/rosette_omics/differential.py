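"""Group-wise tests, fold changes, rank statistics and selection rules.

Fold change is a difference of group means on the log2 scale (case minus
reference), so the selection threshold |fc| > 1 means a two-fold change.  The
enrichment rank statistic is fc x (-log10 p).  To obtain
histomorphology-independent ranks, scores are computed separately for the
ETANTR and EBL/MEPL subgroups (each versus the comparator tumors) and combined
by the per-gene mean before GSEA.  A protein counts as
histomorphology-independent when it passes |fc| > 1 and p <= .05 in both
subgroup comparisons with a concordant fold-change sign.

Degenerate zero-variance tests return p = 1 with a flag rather than aborting
the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import OmicsMatrix, ValidationError

__all__ = [
    "TestResult",
    "RankedList",
    "welch_test",
    "paired_test",
    "one_way_anova",
    "anova_rank_features",
    "differential_table",
    "rank_statistic",
    "combine_subgroup_ranks",
    "morphology_independent_selection",
]

logger = logging.getLogger(__name__)


class TestResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool = False


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)]


def welch_test(a, b) -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df, two-sided p."""
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("welch_test needs >= 2 non-missing values per group")
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = a.mean() - b.mean()
    if se2 <= 0.0:
        if diff == 0.0:
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, True)
        return TestResult(float(np.sign(diff)) * np.inf, float(n1 + n2 - 2), 1.0, True)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


def paired_test(x, y) -> TestResult:
    """Paired t-test: one-sample t on the differences, two-sided p.

    Zero-variance differences are degenerate; by convention the result carries
    p = 1 with the degenerate flag set instead of failing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired_test needs equal-length vectors")
    ok = ~(np.isnan(x) | np.isnan(y))
    d = (x - y)[ok]
    if len(d) < 2:
        raise ValidationError("paired_test needs >= 2 complete pairs")
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else float(np.sign(d.mean())) * np.inf
        return TestResult(t, float(n - 1), 1.0, True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(min(p, 1.0)))


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float, float, float]:
    """One-way ANOVA from the sum-of-squares decomposition: (F, df1, df2, p)."""
    arrs = [_clean(g) for g in groups]
    if len(arrs) < 2 or any(len(g) < 2 for g in arrs):
        raise ValidationError("one_way_anova needs >= 2 groups with >= 2 values")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    df1 = len(arrs) - 1
    df2 = len(all_vals) - len(arrs)
    # guard against rounding noise masquerading as signal on constant features
    scale = float((all_vals**2).sum()) + 1.0
    if ssw <= 1e-12 * scale:
        if ssb <= 1e-12 * scale:
            return 0.0, float(df1), float(df2), 1.0
        return float(np.inf), float(df1), float(df2), 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(df1), float(df2), float(stats.f.sf(f, df1, df2))


def anova_rank_features(
    m: OmicsMatrix, groups: Mapping[str, str] | pd.Series, top_n: int
) -> list[str]:
    """Rank features by one-way ANOVA p across sample groups; keep the top_n.

    Ties (and NaN p-values, ranked last) are broken by feature id so the
    selection is deterministic.
    """
    labels = pd.Series(groups).reindex(m.sample_ids)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label")
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    X = m.values.to_numpy(float)
    pvals = np.full(X.shape[0], np.nan)
    cols = [np.flatnonzero((labels == g).to_numpy()) for g in names]
    for i in range(X.shape[0]):
        try:
            _, _, _, pvals[i] = one_way_anova([X[i, c] for c in cols])
        except ValidationError:
            pvals[i] = np.nan
    if top_n > X.shape[0]:
        warnings.warn(
            f"top_n={top_n} exceeds {X.shape[0]} features; returning all", stacklevel=2
        )
        top_n = X.shape[0]
    order = sorted(
        range(X.shape[0]),
        key=lambda i: (np.isnan(pvals[i]), pvals[i] if not np.isnan(pvals[i]) else 1.0,
                       m.feature_ids[i]),
    )
    return [m.feature_ids[i] for i in order[:top_n]]


def differential_table(
    m: OmicsMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    test: str = "welch",
    pair_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-feature fold change (case - control, log2) and test statistics.

    ``test`` is 'welch' or 'paired'; for 'paired', ``pair_of`` maps each case
    sample to its control partner.  Features with fewer than two usable values
    per group get NaN statistics but keep their fold change when both groups
    have at least one value.
    """
    case = m.values[list(case_ids)].to_numpy(float)
    ctrl = m.values[list(control_ids)].to_numpy(float)
    rows = []
    for i, feat in enumerate(m.feature_ids):
        a, b = case[i], ctrl[i]
        fc = np.nan
        if (~np.isnan(a)).any() and (~np.isnan(b)).any():
            fc = np.nanmean(a) - np.nanmean(b)
        try:
            if test == "welch":
                res = welch_test(a, b)
            elif test == "paired":
                if pair_of is None:
                    paired_ctrl = b
                else:
                    order = [list(control_ids).index(pair_of[c]) for c in case_ids]
                    paired_ctrl = b[order]
                res = paired_test(a, paired_ctrl)
            else:
                raise ValidationError(f"unknown test {test!r}")
            t, df, p, degen = res
        except ValidationError:
            if test not in ("welch", "paired"):
                raise
            t = df = p = np.nan
            degen = False
        rows.append(
            {
                "feature_id": feat,
                "fc": fc,
                "t": t,
                "df": df,
                "p": p,
                "degenerate": degen,
                "n_case": int((~np.isnan(a)).sum()),
                "n_control": int((~np.isnan(b)).sum()),
                "test": test,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def rank_statistic(fc, p):
    """GSEA rank score: fold change times -log10(p).

    Accepts scalars or arrays; p = 0 is clamped to the smallest positive float
    with a warning so the score stays finite.
    """
    fc_arr = np.asarray(fc, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(fc_arr)):
        raise ValidationError("fold changes must be finite")
    if np.any((p_arr < 0) | (p_arr > 1) | ~np.isfinite(p_arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    if np.any(p_arr == 0):
        warnings.warn("p = 0 clamped to the smallest positive float", stacklevel=2)
        p_arr = np.where(p_arr == 0, np.nextafter(0.0, 1.0), p_arr)
    score = fc_arr * (-np.log10(p_arr))
    return float(score) if np.isscalar(fc) or score.ndim == 0 else score


@dataclass
class RankedList:
    """Genes ordered by descending signed score, ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedList":
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        genes = [g for g, _ in items]
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate genes in ranked list")
        return cls(genes, np.array([s for _, s in items], dtype=float))

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.genes)


def combine_subgroup_ranks(
    scores_etantr: Mapping[str, float],
    scores_ebl_mepl: Mapping[str, float],
    method: str = "mean_score",
) -> RankedList:
    """Combine two subgroup score maps into one ranked list.

    'mean_score' (default) averages the two signed scores per gene;
    'mean_rank' averages the rank positions instead.  Genes present in only
    one map are dropped (count logged).
    """
    if not scores_etantr or not scores_ebl_mepl:
        raise ValidationError("both score maps must be non-empty")
    shared = sorted(set(scores_etantr) & set(scores_ebl_mepl))
    if not shared:
        raise ValidationError("the two score maps share no genes")
    dropped = len(set(scores_etantr) | set(scores_ebl_mepl)) - len(shared)
    if dropped:
        logger.info("combine_subgroup_ranks dropped %d unshared gene(s)", dropped)
    if method == "mean_score":
        combined = {g: 0.5 * (scores_etantr[g] + scores_ebl_mepl[g]) for g in shared}
    elif method == "mean_rank":
        def positions(scores: Mapping[str, float]) -> dict[str, int]:
            ordered = sorted(
                ((g, scores[g]) for g in shared), key=lambda kv: (-kv[1], kv[0])
            )
            return {g: i + 1 for i, (g, _) in enumerate(ordered)}

        pa, pb = positions(scores_etantr), positions(scores_ebl_mepl)
        combined = {g: -0.5 * (pa[g] + pb[g]) for g in shared}
    else:
        raise ValidationError(f"unknown combination method {method!r}")
    return RankedList.from_scores(combined)


def morphology_independent_selection(
    diff_etantr: pd.DataFrame,
    diff_ebl_mepl: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Features significant in BOTH subgroup comparisons with concordant sign.

    A feature is selected when |fc| > fc_threshold and p <= p_threshold hold in
    both tables and the fold changes share a sign; the shared sign is reported
    as the direction ('up' or 'down').
    """
    shared = diff_etantr.index.intersection(diff_ebl_mepl.index)
    a = diff_etantr.loc[shared]
    b = diff_ebl_mepl.loc[shared]
    hit = (
        (a["fc"].abs() > fc_threshold)
        & (b["fc"].abs() > fc_threshold)
        & (a["p"] <= p_threshold)
        & (b["p"] <= p_threshold)
        & (np.sign(a["fc"]) == np.sign(b["fc"]))
        & (a["fc"] != 0)
    )
    selected = shared[hit.fillna(False)]
    direction = np.where(a.loc[selected, "fc"] > 0, "up", "down")
    out = pd.DataFrame({"direction": direction}, index=selected)
    out.index.name = "feature_id"
    return out.sort_index()
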