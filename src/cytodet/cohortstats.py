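"""Cohort-level statistics: differential expression, paired induction
testing, Benjamini-Hochberg adjustment and qPCR relative quantification.

Differential expression is a per-probe pooled-variance Student t-test on
the log2 matrix with BH adjustment across all retained probes.  No
variance moderation across probes is applied: with ~40-60 samples per
cohort the per-probe variance estimates are stable and a plain t is
transparent; the deviation from moderated-t pipelines is noted in the
result metadata.  Fold change is reported as case - control on the log2
scale.

Relative qPCR quantification uses the classic comparative-Ct method with
amplification efficiency exactly 2: dCt = target - endogenous control per
record (triplicates averaged upstream), ddCt = dCt(test) - dCt(calibrator),
relative quantity 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SampleMetadata

DE_MODEL_NOTE = "per-probe pooled-variance Student t (no cross-probe variance moderation)"


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance Student t; two-sided p on n_a + n_b - 2 df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ValueError("pooled variance is zero; t-statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def paired_t(before, after) -> tuple[float, float]:
    """One-sample t on paired differences (after - before), two-sided."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired vectors must have equal length")
    if before.size < 2:
        raise ValueError("at least 2 pairs are required")
    if (after - before).var(ddof=1) == 0:
        raise ValueError("paired differences have zero variance; t undefined")
    t, p = stats.ttest_rel(after, before)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(expr: ExpressionMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Per-probe case-vs-control t-test, BH-adjusted, ranked by raw p.

    Returns a DataFrame with columns probe_id, gene, mean_control,
    mean_case, fold_change (case - control, log2), t, p, adjp.
    """
    meta = meta.aligned_to(expr)
    controls, cases = meta.control_samples, meta.case_samples
    if len(controls) < 2 or len(cases) < 2:
        raise ValueError("each cohort needs at least 2 samples for differential expression")
    A = expr.values[list(controls)].to_numpy()
    B = expr.values[list(cases)].to_numpy()
    t, p = stats.ttest_ind(B, A, axis=1, equal_var=True)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    genes = (
        expr.gene_symbols.reindex(expr.probe_ids)
        if expr.gene_symbols is not None
        else pd.Series("", index=expr.probe_ids)
    )
    out = pd.DataFrame(
        {
            "probe_id": expr.probe_ids,
            "gene": genes.to_numpy(),
            "mean_control": mean_a,
            "mean_case": mean_b,
            "fold_change": mean_b - mean_a,
            "t": t,
            "p": p,
            "adjp": bh_adjust(p),
        }
    ).sort_values("p", kind="mergesort", ignore_index=True)
    out.attrs["model"] = DE_MODEL_NOTE
    return out


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: triplicate-mean Ct for target and endogenous control."""

    sample_id: str
    target_ct: float
    reference_ct: float
    group: str = "test"

    def __post_init__(self) -> None:
        for name in ("target_ct", "reference_ct"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def dct(self) -> float:
        return self.target_ct - self.reference_ct


def ddct_relative_expression(test: QpcrRecord, calibrator: QpcrRecord) -> float:
    """Comparative-Ct relative quantity 2^-(dCt_test - dCt_calibrator)."""
    ddct = test.dct - calibrator.dct
    return float(2.0 ** (-ddct))


def mean_ct_of_triplicates(ct_values) -> float:
    """Average replicate Ct readings (normally a triplicate) into one value."""
    ct = np.asarray(ct_values, dtype=float)
    if ct.size == 0 or not np.isfinite(ct).all():
        raise ValueError("Ct replicates must be non-empty and finite")
    return float(ct.mean())
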