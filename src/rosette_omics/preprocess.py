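"""Per-sample normalization and batch/cohort integration.

Two normalizations are provided: sample-wise median centering (the proteome
default) and median/MAD standardization (median 0, median absolute deviation 1
per sample, used before cross-dataset integration).  Batch effects are removed
with a parametric empirical-Bayes location/scale adjustment (the ComBat
scheme): features are standardized, per-batch location (gamma) and scale
(delta) estimates are shrunk toward batch-level method-of-moments hyperpriors,
and the pooled scale is restored.  Cross-cohort integration follows the
COCONUT idea: the adjustment is estimated on shared reference samples only and
then applied to every sample of each cohort; references are dropped from the
merged output.

MAD here is the plain median absolute deviation (no consistency constant), so
median/MAD standardization is exactly idempotent.  Per-batch delta estimates
use ddof=0 variances so that statistically identical batches yield delta == 1
and the adjustment reduces to the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OmicsMatrix, ValidationError

__all__ = [
    "BatchModel",
    "median_center",
    "median_mad_standardize",
    "combat_adjust",
    "coconut_integrate",
    "filter_probes",
]

_EPS = 1e-12


def median_center(m: OmicsMatrix) -> OmicsMatrix:
    """Shift each sample so its median over non-missing values is 0."""
    vals = m.values
    med = vals.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValidationError(f"sample(s) with all values missing: {bad}")
    return m.with_values(vals - med)


def median_mad_standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Per sample: shift the median to 0 and scale the MAD to 1."""
    vals = m.values
    med = vals.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValidationError(f"sample(s) with all values missing: {bad}")
    mad = (vals - med).abs().median(axis=0, skipna=True)
    zero = mad <= 0
    if zero.any():
        raise ValidationError(f"sample(s) with zero MAD: {list(mad.index[zero])}")
    return m.with_values((vals - med) / mad)


@dataclass
class BatchModel:
    """Fitted per-batch location (gamma) and scale (delta) adjustments."""

    gamma: pd.DataFrame  # features x batches, post-shrinkage location shift
    delta: pd.DataFrame  # features x batches, post-shrinkage scale (delta > 0)
    grand_mean: pd.Series
    pooled_sd: pd.Series
    mode: str = "parametric_EB"
    reference_only: bool = False


def _eb_batch_params(
    Z: np.ndarray, batch_cols: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Shrink per-batch location/scale toward parametric hyperpriors.

    gamma-hat is shrunk with the normal prior (mean gamma-bar, variance tau^2
    across features); delta^2-hat with the inverse-gamma prior via
    method-of-moments (a, b from the across-feature mean and variance).  The
    two are solved jointly by fixed-point iteration.  Degenerate hyperpriors
    (zero across-feature spread) fall back to the unshrunk estimates.
    """
    gamma_star: dict[str, np.ndarray] = {}
    delta2_star: dict[str, np.ndarray] = {}
    for b, cols in batch_cols.items():
        Zb = Z[:, cols]
        n_b = Zb.shape[1]
        gamma_hat = Zb.mean(axis=1)
        delta2_hat = ((Zb - gamma_hat[:, None]) ** 2).mean(axis=1)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1)) if len(gamma_hat) > 1 else 0.0
        m_d = float(delta2_hat.mean())
        s2_d = float(delta2_hat.var(ddof=1)) if len(delta2_hat) > 1 else 0.0
        if tau2 <= _EPS or s2_d <= _EPS:
            gamma_star[b] = gamma_hat
            delta2_star[b] = np.maximum(delta2_hat, _EPS)
            continue
        a_prior = (2.0 * s2_d + m_d**2) / s2_d
        b_prior = (m_d * s2_d + m_d**3) / s2_d
        g_old = gamma_hat.copy()
        d_old = delta2_hat.copy()
        for _ in range(100):
            g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior + 0.5 * sum2) / (n_b / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(g_new - g_old).max(initial=0.0),
                np.abs(d_new - d_old).max(initial=0.0),
            )
            g_old, d_old = g_new, d_new
            if change < 1e-8:
                break
        gamma_star[b] = g_old
        delta2_star[b] = np.maximum(d_old, _EPS)
    return gamma_star, delta2_star


def combat_adjust(
    m: OmicsMatrix,
    batches: pd.Series | dict[str, str],
    mode: str = "parametric_EB",
) -> tuple[OmicsMatrix, BatchModel]:
    """Empirical-Bayes location/scale batch adjustment (no covariates).

    Features with missing values are mean-imputed for estimation and re-masked
    afterwards; features with zero overall variance are passed through
    unadjusted with a warning.  A single batch returns the input unchanged.
    """
    if mode != "parametric_EB":
        raise ValidationError(f"unsupported mode {mode!r}")
    labels = pd.Series(batches).reindex(m.sample_ids)
    if labels.isna().any():
        raise ValidationError(
            f"samples without batch label: {list(labels.index[labels.isna()])}"
        )
    batch_names = sorted(labels.unique())
    features = m.feature_ids
    empty_model = BatchModel(
        gamma=pd.DataFrame(0.0, index=features, columns=batch_names),
        delta=pd.DataFrame(1.0, index=features, columns=batch_names),
        grand_mean=pd.Series(0.0, index=features),
        pooled_sd=pd.Series(1.0, index=features),
    )
    if len(batch_names) < 2:
        return m.with_values(m.values.copy()), empty_model
    for b in batch_names:
        if (labels == b).sum() < 2:
            raise ValidationError(f"batch {b!r} has fewer than 2 samples")

    X = m.values.to_numpy(float)
    mask = np.isnan(X)
    if mask.any():
        row_mean = np.nanmean(np.where(mask, np.nan, X), axis=1)
        X = np.where(mask, row_mean[:, None], X)

    cols = {b: np.flatnonzero((labels == b).to_numpy()) for b in batch_names}
    n = X.shape[1]
    batch_mean = {b: X[:, c].mean(axis=1) for b, c in cols.items()}
    grand = sum(batch_mean[b] * (len(cols[b]) / n) for b in batch_names)
    fitted = np.empty_like(X)
    for b, c in cols.items():
        fitted[:, c] = batch_mean[b][:, None]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    constant = var_pooled <= _EPS
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance feature(s) passed through unadjusted",
            stacklevel=2,
        )
    ok = ~constant
    sigma = np.sqrt(var_pooled[ok])
    Z = (X[ok] - grand[ok][:, None]) / sigma[:, None]
    gamma_star, delta2_star = _eb_batch_params(Z, cols)

    X_adj = X.copy()
    gamma_full = pd.DataFrame(0.0, index=features, columns=batch_names)
    delta_full = pd.DataFrame(1.0, index=features, columns=batch_names)
    for b, c in cols.items():
        Z_adj = (Z[:, c] - gamma_star[b][:, None]) / np.sqrt(delta2_star[b])[:, None]
        block = Z_adj * sigma[:, None] + grand[ok][:, None]
        sub = X_adj[ok]
        sub[:, c] = block
        X_adj[ok] = sub
        gamma_full.loc[np.array(features)[ok], b] = gamma_star[b]
        delta_full.loc[np.array(features)[ok], b] = np.sqrt(delta2_star[b])
    X_adj[mask] = np.nan
    out = pd.DataFrame(X_adj, index=features, columns=m.sample_ids)
    model = BatchModel(
        gamma=gamma_full,
        delta=delta_full,
        grand_mean=pd.Series(grand, index=features),
        pooled_sd=pd.Series(np.sqrt(np.maximum(var_pooled, _EPS)), index=features),
    )
    return m.with_values(out), model


def coconut_integrate(
    cohort_a: OmicsMatrix,
    cohort_b: OmicsMatrix,
    reference_ids: list[str],
) -> OmicsMatrix:
    """Reference-anchored cohort integration, references dropped from the output.

    The EB batch parameters (cohort as batch) are estimated on the shared
    reference samples only and then applied to every sample of each cohort.
    The merged matrix covers the feature intersection; no reference sample
    survives into the output.
    """
    refs = list(reference_ids)
    if not refs:
        raise ValidationError("no shared reference samples given")
    for name, cohort in (("cohort_a", cohort_a), ("cohort_b", cohort_b)):
        missing = [r for r in refs if r not in cohort.sample_ids]
        if missing:
            raise ValidationError(f"{name} lacks reference sample(s): {missing}")
    if len(refs) < 2:
        raise ValidationError("need >= 2 reference samples per cohort")
    features = [f for f in cohort_a.feature_ids if f in set(cohort_b.feature_ids)]
    if not features:
        raise ValidationError("cohorts share no features")

    A = cohort_a.values.loc[features]
    B = cohort_b.values.loc[features]
    Ra = A[refs].to_numpy(float)
    Rb = B[refs].to_numpy(float)
    n_ref = len(refs)
    mean_a, mean_b = Ra.mean(axis=1), Rb.mean(axis=1)
    grand = 0.5 * (mean_a + mean_b)
    resid = np.hstack([Ra - mean_a[:, None], Rb - mean_b[:, None]])
    var_pooled = (resid**2).mean(axis=1)
    ok = var_pooled > _EPS
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} feature(s) constant across references passed through",
            stacklevel=2,
        )
    sigma = np.sqrt(var_pooled[ok])
    Z_ref = (np.hstack([Ra, Rb])[ok] - grand[ok][:, None]) / sigma[:, None]
    cols = {"a": np.arange(n_ref), "b": np.arange(n_ref, 2 * n_ref)}
    gamma_star, delta2_star = _eb_batch_params(Z_ref, cols)

    def apply(M: pd.DataFrame, key: str) -> pd.DataFrame:
        X = M.to_numpy(float)
        out = X.copy()
        Z = (X[ok] - grand[ok][:, None]) / sigma[:, None]
        out[ok] = (Z - gamma_star[key][:, None]) / np.sqrt(delta2_star[key])[
            :, None
        ] * sigma[:, None] + grand[ok][:, None]
        return pd.DataFrame(out, index=M.index, columns=M.columns)

    A_adj = apply(A, "a").drop(columns=refs)
    B_adj = apply(B, "b").drop(columns=refs)
    overlap = set(A_adj.columns) & set(B_adj.columns)
    if overlap:
        raise ValidationError(f"non-reference sample id(s) present in both cohorts: {sorted(overlap)}")
    merged = pd.concat([A_adj, B_adj], axis=1)
    return OmicsMatrix(merged, cohort_a.assay_kind)


def filter_probes(
    methylome: OmicsMatrix,
    cpg_annotation,
    detection_p_threshold: float = 0.01,
) -> OmicsMatrix:
    """Drop flagged probes and probes failing detection in any sample.

    Exclusions: probes on sex chromosomes, probes with SNPs at the CpG site,
    cross-reactive probes (all carried as annotation flags), and probes with a
    detection p at or above the threshold in any sample (when detection p
    values are provided).  An empty result is allowed, with a warning.
    """
    frame = cpg_annotation.frame
    missing = [c for c in methylome.feature_ids if c not in frame.index]
    if missing:
        raise ValidationError(f"CpG(s) without annotation: {missing[:5]}")
    keep = [c for c in methylome.feature_ids if not frame.loc[c, "flags"]]
    det = cpg_annotation.detection_p
    if det is not None:
        shared = [s for s in methylome.sample_ids if s in det.columns]
        passed = set(
            det.loc[det.index.isin(keep), shared]
            .lt(detection_p_threshold)
            .all(axis=1)
            .pipe(lambda s: s.index[s])
        )
        keep = [c for c in keep if c in passed]
    if not keep:
        warnings.warn("probe filtering removed every CpG", stacklevel=2)
    return methylome.subset_features(keep)
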