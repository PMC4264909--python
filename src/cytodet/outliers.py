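"""Per-individual z-score outlier detection and subgroup recurrence.

For each retained probe and each case sample, the test value is compared
with the healthy-control reference distribution for that probe: the
standardized deviation z = (test - mean(controls)) / sd(controls) (sample
SD, n-1 denominator) is referred to the standard normal, giving a
two-sided tail probability.  A call passes when both thresholds are met
strictly: P < 0.005 and |log2 difference| > 1.  Case samples never enter
the reference mean/SD, so a single grossly aberrant case cannot mask
itself.

Passing calls are aggregated per probe into carrier counts by direction;
probes recurrently aberrant in several cases define candidate patient
subgroups.  The normal reference makes the per-test level approximate:
with a finite control group the plug-in mean/SD inflate the tail rate
above the nominal level (quantified in the test-suite against a
Monte-Carlo oracle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

P_THRESHOLD_DEFAULT = 0.005
FC_THRESHOLD_DEFAULT = 1.0

#: Column order of the calls table returned by :func:`call_outliers`.
CALL_COLUMNS = ("probe_id", "sample_id", "z", "p", "delta", "direction", "passes")


@dataclass(frozen=True)
class OutlierCall:
    """A single probe x case-sample outlier test."""

    probe_id: str
    sample_id: str
    z: float
    p: float
    delta: float
    direction: str
    passes: bool


def zscore_outlier(
    test_value: float,
    control_values,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    probe_id: str = "",
    sample_id: str = "",
) -> OutlierCall:
    """Standardized-deviation outlier test of one value against a control group."""
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size < 3:
        raise ValueError("at least 3 control values are required")
    sd = control_values.std(ddof=1)
    if sd == 0:
        raise ValueError("control SD is zero; the standardized deviation is undefined")
    delta = float(test_value - control_values.mean())
    z = delta / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    passes = bool(p < p_threshold and abs(delta) > fc_threshold)
    return OutlierCall(
        probe_id=probe_id,
        sample_id=sample_id,
        z=float(z),
        p=p,
        delta=delta,
        direction="under" if delta < 0 else "over",
        passes=passes,
    )


def call_outliers(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Run the outlier test for every (probe, case sample).

    Returns one row per test with columns :data:`CALL_COLUMNS`.  Control
    statistics are computed once per probe from control samples only.
    """
    meta = meta.aligned_to(expr)
    controls = meta.control_samples
    cases = meta.case_samples
    if len(controls) < 3:
        raise ValueError("at least 3 control samples are required")
    if len(cases) == 0:
        raise ValueError("no case samples to test")
    if (meta.table["stimulation"] != "unstimulated").any():
        logger.warning(
            "outlier calling expects unstimulated samples only; "
            "stimulated samples are present in the input"
        )

    C = expr.values[list(controls)].to_numpy()  # probes x n_ctrl
    T = expr.values[list(cases)].to_numpy()  # probes x n_case
    mean = C.mean(axis=1)
    sd = C.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = expr.probe_ids[sd == 0]
        raise ValueError(f"control SD is zero for probes: {list(bad[:5])}")

    delta = T - mean[:, None]
    z = delta / sd[:, None]
    p = 2.0 * stats.norm.sf(np.abs(z))
    passes = (p < p_threshold) & (np.abs(delta) > fc_threshold)

    n_probes, n_cases = delta.shape
    calls = pd.DataFrame(
        {
            "probe_id": np.repeat(expr.probe_ids.to_numpy(), n_cases),
            "sample_id": np.tile(np.asarray(list(cases), dtype=object), n_probes),
            "z": z.ravel(),
            "p": p.ravel(),
            "delta": delta.ravel(),
            "direction": np.where(delta.ravel() < 0, "under", "over"),
            "passes": passes.ravel(),
        }
    )
    logger.info(
        "outlier calling: %d probes x %d cases, %d passing calls",
        n_probes, n_cases, int(passes.sum()),
    )
    return calls


def calls_from_records(records) -> pd.DataFrame:
    """Build a calls table from an iterable of :class:`OutlierCall`."""
    return pd.DataFrame([vars(r) for r in records], columns=list(CALL_COLUMNS))


def aggregate_recurrence(calls: pd.DataFrame, min_carriers: int = 1) -> pd.DataFrame:
    """Per-probe carrier counts of passing calls, by direction.

    Returns a table indexed by probe id with columns ``count_under``,
    ``count_over``, ``carriers_under``, ``carriers_over`` and
    ``both_directions``, restricted to probes whose larger directional
    count reaches ``min_carriers``.  A probe with carriers on both sides
    is counted in both directions.
    """
    passing = calls[calls["passes"]]
    if passing.empty:
        return pd.DataFrame(
            columns=["count_under", "count_over", "carriers_under", "carriers_over",
                     "both_directions"]
        )
    rows = {}
    for (probe, direction), grp in passing.groupby(["probe_id", "direction"], sort=True):
        rec = rows.setdefault(
            probe,
            {"count_under": 0, "count_over": 0, "carriers_under": [], "carriers_over": []},
        )
        ids = sorted(grp["sample_id"])
        rec[f"count_{direction}"] = len(ids)
        rec[f"carriers_{direction}"] = ids
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "probe_id"
    table["both_directions"] = (table["count_under"] > 0) & (table["count_over"] > 0)
    keep = table[["count_under", "count_over"]].max(axis=1) >= min_carriers
    table = table[keep].sort_values(
        ["count_under", "count_over"], ascending=False, kind="mergesort"
    )
    return table


def summarize_outlier_burden(calls: pd.DataFrame, expr: ExpressionMatrix) -> dict:
    """Cohort-level accounting of how many probes carry any passing call.

    ``percent_flagged`` is reported to one decimal, as a percentage of the
    expressed (retained) probes.  Under- and over-expressed counts are
    reported independently; a probe aberrant in both directions in
    different individuals contributes to both counts and once to
    ``n_probes_flagged_any``.
    """
    passing = calls[calls["passes"]]
    under = set(passing.loc[passing["direction"] == "under", "probe_id"])
    over = set(passing.loc[passing["direction"] == "over", "probe_id"])
    flagged = under | over
    n_expressed = expr.n_probes
    percent = round(100.0 * len(flagged) / n_expressed, 1) if n_expressed else 0.0
    return {
        "n_probes_expressed": int(n_expressed),
        "n_probes_flagged_any": len(flagged),
        "n_under": len(under),
        "n_over": len(over),
        "n_both": len(under & over),
        "percent_flagged": percent,
    }
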