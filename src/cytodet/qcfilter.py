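"""Probe quality filtering and simplified covariate-protected batch adjustment.

The detection filter keeps a probe when it is called detected (platform
detection P below a threshold) in at least a given fraction of samples.
The batch adjustment is a deliberately simple location/scale model: per
probe, additive batch and cohort effects are fitted jointly by least
squares, the batch effects are subtracted, and each batch's residual
spread is rescaled to the pooled value.  Fitting the cohort label
alongside batch protects the case/control contrast from being absorbed
into the batch correction; no empirical-Bayes shrinkage of the batch
parameters is performed, and the adjustment notes this in its output
metadata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

#: Free-text note attached to adjusted matrices / run manifests.
BATCH_MODEL_NOTE = (
    "batch adjustment: per-probe additive batch+cohort least-squares fit with "
    "per-batch residual rescaling (no empirical-Bayes shrinkage)"
)


def filter_low_quality_probes(expr: ExpressionMatrix, blacklist) -> ExpressionMatrix:
    """Drop blacklisted probes; order of the remaining probes is preserved."""
    blacklist = set(blacklist)
    keep = [p for p in expr.probe_ids if p not in blacklist]
    if not keep:
        logger.warning("probe blacklist removed every probe; returning empty matrix")
    return expr.subset_probes(keep)


def filter_by_detection(
    expr: ExpressionMatrix, p_threshold: float = 0.01, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep probes detected (detection P < ``p_threshold``, strict) in at
    least ``min_fraction`` of samples.

    A probe detected in exactly ``min_fraction`` of samples is retained.
    """
    if expr.detection_p is None:
        raise ValueError("detection P-values are required for the detection filter "
                         "but are absent from this matrix")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    detected = (expr.detection_p.to_numpy() < p_threshold).mean(axis=1)
    keep = expr.probe_ids[detected >= min_fraction]
    logger.info("detection filter: %d of %d probes retained", len(keep), expr.n_probes)
    return expr.subset_probes(keep)


def _design(meta: SampleMetadata, sample_ids) -> tuple[np.ndarray, list, np.ndarray]:
    """Intercept + cohort dummy + sum-to-zero batch dummies."""
    t = meta.table.loc[sample_ids]
    batches = sorted(t["batch"].unique())
    cohort = (t["cohort"] == "case").to_numpy(float)
    n = len(t)
    X = [np.ones(n), cohort]
    for b in batches[:-1]:  # sum-to-zero coding: last batch = -sum(others)
        col = np.where(t["batch"] == b, 1.0, 0.0) - np.where(t["batch"] == batches[-1], 1.0, 0.0)
        X.append(col)
    return np.column_stack(X), batches, t["batch"].to_numpy(object)


def adjust_batches(expr: ExpressionMatrix, meta: SampleMetadata) -> ExpressionMatrix:
    """Remove additive batch effects while preserving the cohort contrast.

    Raises if any batch has fewer than 2 samples or if batch and cohort
    are fully aliased (every batch contains a single cohort).
    """
    meta = meta.aligned_to(expr)
    t = meta.table
    counts = t["batch"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")
    if len(counts) == 1:
        return expr  # single batch: nothing to remove
    per_batch_cohorts = t.groupby("batch")["cohort"].nunique()
    if (per_batch_cohorts == 1).all():
        raise ValueError(
            "batch is aliased with cohort (every batch contains a single cohort); "
            "the batch effect cannot be separated from the disease effect"
        )

    X, batches, batch_of = _design(meta, expr.sample_ids)
    Y = expr.values.to_numpy()  # probes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # params x probes
    n_b = len(batches)
    # batch part of the fit, per sample (sum-to-zero coding)
    batch_cols = X[:, 2 : 2 + n_b - 1]
    batch_part = batch_cols @ beta[2 : 2 + n_b - 1]  # samples x probes
    resid = Y.T - X @ beta  # samples x probes

    adjusted = Y.T - batch_part  # keep intercept + cohort + residual
    # rescale per-batch residual spread to the pooled residual SD; the
    # scaling is applied to deviations around batch x cohort cell means so
    # neither the zero per-batch mean nor the realized cohort contrast moves
    cohort_of = t["cohort"].to_numpy(object)
    pooled_sd = resid.std(axis=0, ddof=1)
    for b in batches:
        rows = batch_of == b
        bsd = resid[rows].std(axis=0, ddof=1)
        scale = np.divide(pooled_sd, bsd, out=np.ones_like(bsd), where=bsd > 1e-12)
        for c in np.unique(cohort_of[rows]):
            cell = rows & (cohort_of == c)
            cell_mean = resid[cell].mean(axis=0)
            adjusted[cell] += (resid[cell] - cell_mean) * (scale - 1.0)

    out = pd.DataFrame(adjusted.T, index=expr.probe_ids, columns=expr.sample_ids)
    logger.info("%s; batches=%s", BATCH_MODEL_NOTE, batches)
    return ExpressionMatrix(values=out, detection_p=expr.detection_p,
                            gene_symbols=expr.gene_symbols)


def batch_variance_check(
    expr_before: ExpressionMatrix, expr_after: ExpressionMatrix, meta: SampleMetadata
) -> dict:
    """Per-probe fraction of variance explained by batch, before vs after.

    Returns mean and max batch R-squared for each matrix; after adjustment
    the mean should not exceed the before value.
    """
    if not (
        expr_before.probe_ids.equals(expr_after.probe_ids)
        and expr_before.sample_ids.equals(expr_after.sample_ids)
    ):
        raise ValueError("before/after matrices must share probes and samples")
    meta = meta.aligned_to(expr_before)
    batch_of = meta.table["batch"].to_numpy(object)

    def r2(expr: ExpressionMatrix) -> np.ndarray:
        Y = expr.values.to_numpy()
        grand = Y.mean(axis=1, keepdims=True)
        total = ((Y - grand) ** 2).sum(axis=1)
        between = np.zeros(Y.shape[0])
        for b in np.unique(batch_of):
            cols = batch_of == b
            between += cols.sum() * (Y[:, cols].mean(axis=1) - grand[:, 0]) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, between / total, 0.0)
        return out

    before, after = r2(expr_before), r2(expr_after)
    return {
        "mean_r2_before": float(before.mean()),
        "max_r2_before": float(before.max()),
        "mean_r2_after": float(after.mean()),
        "max_r2_after": float(after.max()),
    }
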