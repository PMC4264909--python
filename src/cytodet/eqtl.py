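"""Single-SNP additive eQTL regression.

Expression of one probe is regressed on minor-allele dosage (0/1/2) by
ordinary least squares, per cohort: beta is the log2 expression change
per minor allele, r-squared the squared dosage-expression correlation,
and p the two-sided t-test on the slope (n-2 df).  Genotypes may be given
directly as dosages or as biallelic calls such as ``T/G``, which are
converted by counting the declared minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, SampleMetadata


@dataclass(frozen=True)
class EqtlResult:
    probe_id: str
    snp_id: str
    cohort: str
    beta: float
    intercept: float
    r_squared: float
    p: float
    n_by_genotype: tuple[int, int, int]  # counts for dosage 0, 1, 2

    @property
    def n(self) -> int:
        return sum(self.n_by_genotype)


def additive_regression(
    expression,
    dosage,
    probe_id: str = "",
    snp_id: str = "",
    cohort: str = "",
) -> EqtlResult:
    """OLS fit of expression on minor-allele dosage."""
    y = np.asarray(expression, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if y.size != d.size:
        raise ValueError("expression and dosage vectors must have equal length")
    if y.size < 3:
        raise ValueError("at least 3 samples are required")
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    counts = tuple(int((d == k).sum()) for k in (0, 1, 2))
    if sum(c > 0 for c in counts) < 2:
        raise ValueError(
            f"monomorphic genotype distribution (counts 0/1/2 = {counts}); "
            "the additive slope is undefined"
        )
    if np.ptp(y) == 0:
        # flat expression: slope 0, no association
        return EqtlResult(probe_id, snp_id, cohort, 0.0, float(y[0]), 0.0, 1.0, counts)
    fit = stats.linregress(d, y)
    return EqtlResult(
        probe_id=probe_id,
        snp_id=snp_id,
        cohort=cohort,
        beta=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n_by_genotype=counts,
    )


def genotype_from_calls(allele_pairs, minor_allele: str) -> np.ndarray:
    """Count the minor allele in biallelic calls like ``G/G`` or ``T/G``."""
    alleles_seen = set()
    dosages = []
    for call in allele_pairs:
        pair = str(call).replace("|", "/").split("/")
        if len(pair) != 2:
            raise ValueError(f"malformed biallelic call {call!r}")
        alleles_seen.update(pair)
        dosages.append(sum(1 for a in pair if a == minor_allele))
    if len(alleles_seen) > 2:
        raise ValueError(f"more than two alleles observed: {sorted(alleles_seen)}")
    if len(alleles_seen) == 2 and minor_allele not in alleles_seen:
        raise ValueError(
            f"minor allele {minor_allele!r} never observed among alleles "
            f"{sorted(alleles_seen)}"
        )
    return np.asarray(dosages, dtype=int)


def cohort_eqtl(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    probe_id: str,
    snp_id: str = "",
) -> dict[str, EqtlResult]:
    """Fit the additive model separately in each cohort.

    Dosages are read from the metadata ``genotype_dosage`` column;
    samples without a genotype are dropped.
    """
    meta = meta.aligned_to(expr)
    if "genotype_dosage" not in meta.table.columns:
        raise ValueError("metadata has no genotype_dosage column")
    if probe_id not in expr.probe_ids:
        raise ValueError(f"probe {probe_id!r} not in expression matrix")
    out: dict[str, EqtlResult] = {}
    for cohort in ("control", "case"):
        samples = meta.cohort_samples(cohort)
        dos = meta.table.loc[samples, "genotype_dosage"]
        keep = dos.notna()
        samples = samples[keep.to_numpy()]
        if len(samples) < 3:
            continue
        y = expr.values.loc[probe_id, samples].to_numpy(dtype=float)
        out[cohort] = additive_regression(
            y, dos[keep].to_numpy(dtype=float), probe_id=probe_id,
            snp_id=snp_id, cohort=cohort,
        )
    return out
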