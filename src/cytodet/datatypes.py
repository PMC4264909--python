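"""Core in-memory containers shared across the pipeline.

An :class:`ExpressionMatrix` holds log2 intensities as a pandas DataFrame
(probes x samples) with an optional matched matrix of platform detection
P-values and optional probe -> gene-symbol annotation.  A
:class:`SampleMetadata` holds one row per sample with the cohort label
(``control`` / ``case``), batch, stimulation state and, optionally, a
minor-allele dosage for an eQTL SNP.

Sample identifiers are the join key everywhere; column/row order never
carries meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COHORTS = ("control", "case")
STIMULATION_STATES = ("unstimulated", "stimulated")

#: Common aliases accepted on input and mapped to the canonical labels.
COHORT_ALIASES = {
    "hc": "control",
    "control": "control",
    "healthy": "control",
    "cd": "case",
    "case": "case",
}


def canonical_cohort(label: str) -> str:
    """Map a cohort label (e.g. ``HC``/``CD``) to ``control``/``case``."""
    try:
        return COHORT_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unrecognized cohort label {label!r}; expected one of "
            f"{sorted(set(COHORT_ALIASES))}"
        ) from None


@dataclass
class ExpressionMatrix:
    """Log2 expression values for probes x samples.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample; must be
        numeric with no missing cells.
    detection_p
        Optional DataFrame of per-cell detection P-values in [0, 1] with
        the same index and columns as ``values``.
    gene_symbols
        Optional Series mapping probe id -> gene symbol.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dupes[:5])}")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.values = self.values.astype(float)
        if self.detection_p is not None:
            dp = self.detection_p
            if not (dp.index.equals(self.values.index) and dp.columns.equals(self.values.columns)):
                raise ValueError(
                    "detection P-value matrix does not match expression matrix "
                    "probes/samples (order must match exactly)"
                )
            arr = dp.to_numpy(dtype=float)
            if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
                raise ValueError("detection P-values must lie in [0, 1]")
            self.detection_p = dp.astype(float)
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``probe_ids`` (order preserved)."""
        return ExpressionMatrix(
            values=self.values.loc[probe_ids],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probe_ids],
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[list(sample_ids)],
            detection_p=None if self.detection_p is None else self.detection_p[list(sample_ids)],
            gene_symbols=self.gene_symbols,
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations keyed by sample id.

    ``table`` is indexed by sample id and carries at least ``cohort`` and
    ``batch`` columns; ``stimulation`` defaults to ``unstimulated`` and
    ``genotype_dosage`` (minor-allele count 0/1/2) is optional.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            raise ValueError("duplicate sample ids in metadata")
        for col in ("cohort", "batch"):
            if col not in t.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
        t = t.copy()
        t["cohort"] = [canonical_cohort(c) for c in t["cohort"]]
        if "stimulation" not in t.columns:
            t["stimulation"] = "unstimulated"
        bad = set(t["stimulation"]) - set(STIMULATION_STATES)
        if bad:
            raise ValueError(f"unrecognized stimulation states: {sorted(bad)}")
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def cohort_samples(self, cohort: str) -> pd.Index:
        cohort = canonical_cohort(cohort)
        return self.table.index[self.table["cohort"] == cohort]

    @property
    def control_samples(self) -> pd.Index:
        return self.cohort_samples("control")

    @property
    def case_samples(self) -> pd.Index:
        return self.cohort_samples("case")

    def check_matches(self, expr: ExpressionMatrix) -> None:
        """Require exactly one metadata row per expression sample."""
        missing = expr.sample_ids.difference(self.table.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing[:5])}")

    def aligned_to(self, expr: ExpressionMatrix) -> "SampleMetadata":
        """Metadata restricted to, and ordered as, the matrix samples."""
        self.check_matches(expr)
        return SampleMetadata(self.table.loc[expr.sample_ids])
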