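"""Cytokine secretion analysis: viability normalization, cohort
comparison, and pairwise co-secretion correlation networks.

Secretion is measured as pg/ml per sample for a five-cytokine panel
(TNF, IFN-g, IL-6, IL-8, IL-10), with a per-well viability absorbance
(MTT, A570) as a viable-cell proxy.  Concentrations are first rescaled
to a reference absorbance, then log2(x + 1)-transformed for correlation
and cohort comparison.  Within each cohort all 10 unordered cytokine
pairs are Pearson-correlated; an edge is significant at two-sided
p < 0.05.  Networks from two cohorts are compared edge-wise with the
Fisher z difference test — a quantitative extension of the usual
qualitative network comparison, and labelled as such in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import canonical_cohort
from .synthgen import CYTOKINES

EDGE_ALPHA_DEFAULT = 0.05

REQUIRED_COLUMNS = ("sample_id", "cohort", "cytokine", "concentration_pg_ml")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cytokine table is missing column {col!r}")
    if (table["concentration_pg_ml"] < 0).any():
        raise ValueError("cytokine concentrations must be non-negative")
    dup = table.duplicated(["sample_id", "cytokine"])
    if dup.any():
        raise ValueError("more than one concentration per (sample, cytokine)")
    t = table.copy()
    t["cohort"] = [canonical_cohort(c) for c in t["cohort"]]
    return t


def normalize_by_viability(table: pd.DataFrame, reference: float | None = None) -> pd.DataFrame:
    """Rescale concentrations to a common viable-cell level.

    concentration' = concentration * (reference / viability_a570); the
    reference defaults to the mean absorbance over all wells, so a well
    with fewer viable cells (lower A570) is scaled up.
    """
    t = _validate_table(table)
    if "viability_a570" not in t.columns:
        raise ValueError("viability_a570 column required for viability normalization")
    if (t["viability_a570"] <= 0).any() or t["viability_a570"].isna().any():
        raise ValueError("viability absorbance must be positive")
    if reference is None:
        reference = float(t["viability_a570"].mean())
    t["concentration_pg_ml"] = t["concentration_pg_ml"] * (reference / t["viability_a570"])
    return t


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 paired observations are required")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)


@dataclass
class CorrelationNetwork:
    """All 10 pairwise cytokine correlations within one cohort."""

    cohort: str
    edges: pd.DataFrame  # columns cytokine_a, cytokine_b, r, p, n, significant
    alpha: float = EDGE_ALPHA_DEFAULT

    def edge(self, a: str, b: str) -> pd.Series:
        e = self.edges
        m = ((e["cytokine_a"] == a) & (e["cytokine_b"] == b)) | (
            (e["cytokine_a"] == b) & (e["cytokine_b"] == a)
        )
        if not m.any():
            raise KeyError(f"no edge {a}-{b}")
        return e[m].iloc[0]

    @property
    def significant_pairs(self) -> set[frozenset]:
        sig = self.edges[self.edges["significant"]]
        return {frozenset((a, b)) for a, b in zip(sig["cytokine_a"], sig["cytokine_b"])}


def _wide_log2(table: pd.DataFrame, cohort: str) -> pd.DataFrame:
    t = _validate_table(table)
    cohort = canonical_cohort(cohort)
    sub = t[t["cohort"] == cohort]
    wide = sub.pivot(index="sample_id", columns="cytokine", values="concentration_pg_ml")
    missing = [c for c in CYTOKINES if c not in wide.columns]
    present = [c for c in CYTOKINES if c in wide.columns]
    if missing:
        wide = wide[present]
    wide = wide.dropna()
    return np.log2(wide + 1.0)


def build_network(
    table: pd.DataFrame, cohort: str, alpha: float = EDGE_ALPHA_DEFAULT
) -> CorrelationNetwork:
    """Pairwise Pearson network on log2(pg/ml + 1) values for one cohort."""
    wide = _wide_log2(table, cohort)
    if wide.shape[0] < 3:
        raise ValueError(
            f"cohort {cohort!r} has only {wide.shape[0]} complete cytokine profiles; "
            "at least 3 are required"
        )
    rows = []
    for a, b in combinations(wide.columns, 2):
        r, p, n = pearson(wide[a], wide[b])
        rows.append(
            {"cytokine_a": a, "cytokine_b": b, "r": r, "p": p, "n": n,
             "significant": bool(p < alpha), "sign": "+" if r >= 0 else "-"}
        )
    return CorrelationNetwork(cohort=canonical_cohort(cohort),
                              edges=pd.DataFrame(rows), alpha=alpha)


def compare_networks(net_a: CorrelationNetwork, net_b: CorrelationNetwork) -> pd.DataFrame:
    """Edge-wise Fisher z comparison of two cohort networks.

    For each shared pair: z_diff = (atanh r_a - atanh r_b) /
    sqrt(1/(n_a-3) + 1/(n_b-3)), two-sided normal p, plus which network
    (if either) holds the edge as significant.  Quantitative extension of
    the qualitative edge-set comparison; |r| = 1 is rejected because the
    Fisher transform diverges there.
    """
    ea = net_a.edges.set_index(["cytokine_a", "cytokine_b"])
    eb = net_b.edges.set_index(["cytokine_a", "cytokine_b"])
    if set(ea.index) != set(eb.index):
        raise ValueError("networks were built on different cytokine sets")
    rows = []
    for pair in ea.index:
        ra, rb = float(ea.loc[pair, "r"]), float(eb.loc[pair, "r"])
        na, nb = int(ea.loc[pair, "n"]), int(eb.loc[pair, "n"])
        if na <= 3 or nb <= 3:
            raise ValueError("Fisher comparison requires n > 3 in both networks")
        if abs(ra) >= 1.0 or abs(rb) >= 1.0:
            raise ValueError("|r| = 1 encountered; Fisher transform diverges")
        se = np.sqrt(1.0 / (na - 3) + 1.0 / (nb - 3))
        zdiff = (np.arctanh(ra) - np.arctanh(rb)) / se
        sig_a = bool(ea.loc[pair, "significant"])
        sig_b = bool(eb.loc[pair, "significant"])
        rows.append(
            {
                "cytokine_a": pair[0],
                "cytokine_b": pair[1],
                "r_a": ra,
                "r_b": rb,
                "n_a": na,
                "n_b": nb,
                "z_diff": float(zdiff),
                "p_diff": float(2.0 * stats.norm.sf(abs(zdiff))),
                "edge_in_a_only": sig_a and not sig_b,
                "edge_in_b_only": sig_b and not sig_a,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["note"] = "Fisher-z edge comparison (quantitative extension)"
    return out


def compare_secretion(table: pd.DataFrame, log2_scale: bool = True) -> pd.DataFrame:
    """Per-cytokine control-vs-case Student t-test on secretion levels.

    ``log2_scale`` (default) compares log2(pg/ml + 1) values, matching
    the scale of the correlation analysis; set False for raw pg/ml.
    """
    from .cohortstats import two_sample_t

    t = _validate_table(table)
    cohorts = set(t["cohort"])
    if cohorts != {"control", "case"}:
        raise ValueError(f"both cohorts are required, found {sorted(cohorts)}")
    rows = []
    for cyt, grp in t.groupby("cytokine", sort=False):
        a = grp.loc[grp["cohort"] == "control", "concentration_pg_ml"].to_numpy()
        b = grp.loc[grp["cohort"] == "case", "concentration_pg_ml"].to_numpy()
        if log2_scale:
            a, b = np.log2(a + 1.0), np.log2(b + 1.0)
        if a.size == b.size and np.array_equal(a, b):
            tstat, p = 0.0, 1.0  # identical groups, even when both are constant
        else:
            tstat, p = two_sample_t(a, b)
        rows.append(
            {"cytokine": cyt, "mean_control": float(a.mean()), "mean_case": float(b.mean()),
             "n_control": a.size, "n_case": b.size, "t": tstat, "p": p}
        )
    return pd.DataFrame(rows)
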