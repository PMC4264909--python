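"""Synthetic case/control cohort generator.

Emulates the statistical structure of a two-cohort macrophage microarray
study: ~10k expressed probes on the log2 scale over 42 controls and 58
cases, optional batch location/scale structure, planted outlier subgroups
(a handful of cases shifted on one probe), an additive eQTL SNP sampled at
Hardy-Weinberg proportions, and a five-cytokine secretion panel whose
within-cohort correlation structure differs between cohorts.

Every random draw flows from the scenario seed, so identical scenarios
give byte-identical cohorts.  The planted truth (carrier ids, eQTL
dosages, target correlations) is recorded alongside the data so that
downstream detection stages can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import ExpressionMatrix, SampleMetadata

CYTOKINES = ("TNF", "IFN-g", "IL-6", "IL-8", "IL-10")


def _corr_from_pairs(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    m = np.eye(len(CYTOKINES))
    for (a, b), r in pairs.items():
        i, j = CYTOKINES.index(a), CYTOKINES.index(b)
        m[i, j] = m[j, i] = r
    return m


#: Within-cohort Pearson correlation targets on log2 secretion values.
#: Pairs not listed default to 0 (independence).
HC_CORR_PAIRS = {
    ("TNF", "IFN-g"): 0.64,
    ("TNF", "IL-6"): 0.67,
    ("IFN-g", "IL-6"): 0.60,
    ("IL-6", "IL-10"): -0.39,
}
CD_CORR_PAIRS = {
    ("TNF", "IFN-g"): 0.15,
    ("TNF", "IL-6"): 0.47,
    ("IFN-g", "IL-6"): 0.33,
    ("IL-6", "IL-10"): 0.02,
}


@dataclass
class PlantedOutlier:
    """A probe on which a subgroup of case samples is shifted.

    ``effect`` is the log2 shift applied to each carrier (negative =
    under-expression); ``probe_sd`` optionally overrides the probe's
    within-cohort noise SD so the planted signal-to-noise is controlled.
    """

    probe_id: str
    n_carriers: int
    effect: float
    direction: str = "under"
    probe_sd: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("under", "over"):
            raise ValueError("direction must be 'under' or 'over'")
        if self.direction == "under" and self.effect > 0:
            self.effect = -self.effect
        if self.direction == "over" and self.effect < 0:
            self.effect = -self.effect


@dataclass
class EqtlSpec:
    """An additive expression QTL: dosage d in {0,1,2} shifts one probe by beta*d."""

    probe_id: str
    maf: float
    beta: float
    probe_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("minor allele frequency must lie in [0, 1]")


@dataclass
class BatchSpec:
    label: str
    size: int
    shift: float = 0.0
    scale: float = 1.0


@dataclass
class SimScenario:
    """Full description of a synthetic two-cohort study."""

    n_control: int = 42
    n_case: int = 58
    n_probes: int = 10_468
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    probe_sd_range: tuple[float, float] = (0.1, 0.35)
    batches: list[BatchSpec] = field(default_factory=list)
    planted_outliers: list[PlantedOutlier] = field(default_factory=list)
    eqtl: EqtlSpec | None = None
    cytokine_corr_control: np.ndarray = field(
        default_factory=lambda: _corr_from_pairs(HC_CORR_PAIRS)
    )
    cytokine_corr_case: np.ndarray = field(
        default_factory=lambda: _corr_from_pairs(CD_CORR_PAIRS)
    )
    #: log2 pg/ml means of the secreted cytokines in controls.
    cytokine_log2_means: tuple[float, ...] = (10.0, 5.5, 12.0, 14.0, 7.5)
    cytokine_log2_sds: tuple[float, ...] = (1.2, 1.2, 1.0, 0.9, 1.1)
    #: additive log2 shift applied to case cytokine means (TNF and IFN-g
    #: secretion is attenuated in cases).
    cytokine_case_log2_shift: tuple[float, ...] = (-0.8, -1.2, 0.0, 0.0, 0.0)
    n_cytokine_control: int = 39
    n_cytokine_case: int = 43
    detection_dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_case", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for po in self.planted_outliers:
            if po.n_carriers > self.n_case:
                raise ValueError(
                    f"planted outlier {po.probe_id!r}: carrier count "
                    f"{po.n_carriers} exceeds n_case {self.n_case}"
                )
        for label, m in (
            ("cytokine_corr_control", self.cytokine_corr_control),
            ("cytokine_corr_case", self.cytokine_corr_case),
        ):
            m = np.asarray(m, dtype=float)
            if m.shape != (5, 5):
                raise ValueError(f"{label} must be 5x5")
            if not np.allclose(m, m.T):
                raise ValueError(f"{label} must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError(f"{label} must have unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{label} is not positive semi-definite")
        if not 0.0 <= self.detection_dropout_rate <= 1.0:
            raise ValueError("detection_dropout_rate must lie in [0, 1]")
        if self.batches and sum(b.size for b in self.batches) != self.n_control + self.n_case:
            raise ValueError("batch sizes must sum to the total number of samples")


@dataclass
class SimTruth:
    """Ground truth planted into a simulated cohort."""

    carriers: dict[str, list[str]]  # probe id -> carrier sample ids
    carrier_effects: dict[str, float]  # probe id -> log2 effect
    eqtl_probe: str | None
    eqtl_beta: float | None
    dosages: dict[str, int]  # sample id -> minor-allele dosage
    corr_targets: dict[str, dict[str, float]]  # cohort -> "A|B" -> r
    probe_means: dict[str, float]
    probe_sds: dict[str, float]


@dataclass
class SimCohort:
    expression: ExpressionMatrix
    metadata: SampleMetadata
    cytokines: pd.DataFrame
    truth: SimTruth

    def __post_init__(self) -> None:
        probes = set(self.expression.probe_ids)
        samples = set(self.expression.sample_ids)
        for pid, carr in self.truth.carriers.items():
            if pid not in probes or not set(carr) <= samples:
                raise ValueError("truth record references unknown probes/samples")


def default_paper_scenario(seed: int = 0) -> SimScenario:
    """The study-sized scenario: 42 controls vs 58 cases over 10 468 probes.

    Plants one under-expressed probe carried by 7 of the 58 cases
    (log2 effect -1.5 at probe SD 0.25) and one additive eQTL probe
    (MAF 0.183, beta -0.78 log2 per minor allele, residual SD chosen so
    the population dosage-expression r-squared is 0.74).  Cytokine
    correlation targets are the cohort-specific values the analysis is
    meant to recover; unlisted pairs are independent.
    """
    maf, beta, r2 = 0.183, -0.78, 0.74
    explained = beta**2 * 2 * maf * (1 - maf)
    resid_sd = float(np.sqrt(explained * (1 - r2) / r2))
    return SimScenario(
        n_control=42,
        n_case=58,
        n_probes=10_468,
        planted_outliers=[
            PlantedOutlier(probe_id="PROBE_000000", n_carriers=7, effect=-1.5, probe_sd=0.25)
        ],
        eqtl=EqtlSpec(probe_id="PROBE_000001", maf=maf, beta=beta, probe_sd=resid_sd),
        seed=seed,
    )


def _sample_ids(scenario: SimScenario) -> tuple[list[str], list[str]]:
    controls = [f"HC{i + 1:03d}" for i in range(scenario.n_control)]
    cases = [f"CD{i + 1:03d}" for i in range(scenario.n_case)]
    return controls, cases


def simulate_expression(scenario: SimScenario) -> SimCohort:
    """Draw a full cohort (expression + metadata + cytokines + truth).

    Per probe, values are normal(baseline, sd) on the log2 scale; batch
    location/scale effects, planted carrier shifts and the eQTL dosage
    effect are then applied.  Detection P-values are < 0.01 for expressed
    cells except for a ``detection_dropout_rate`` fraction drawn >= 0.01.
    """
    rng = np.random.default_rng(scenario.seed)
    controls, cases = _sample_ids(scenario)
    samples = controls + cases
    n_samples = len(samples)

    probe_ids = [f"PROBE_{i:06d}" for i in range(scenario.n_probes)]
    lo, hi = scenario.baseline_mean_range
    means = rng.uniform(lo, hi, scenario.n_probes)
    slo, shi = scenario.probe_sd_range
    sds = rng.uniform(slo, shi, scenario.n_probes)

    probe_pos = {pid: i for i, pid in enumerate(probe_ids)}
    for po in scenario.planted_outliers:
        if po.probe_id not in probe_pos:
            raise ValueError(f"planted outlier probe {po.probe_id!r} not in matrix")
        if po.probe_sd is not None:
            sds[probe_pos[po.probe_id]] = po.probe_sd
    if scenario.eqtl is not None:
        if scenario.eqtl.probe_id not in probe_pos:
            raise ValueError(f"eQTL probe {scenario.eqtl.probe_id!r} not in matrix")
        if scenario.eqtl.probe_sd is not None:
            sds[probe_pos[scenario.eqtl.probe_id]] = scenario.eqtl.probe_sd

    values = rng.normal(means[:, None], sds[:, None], (scenario.n_probes, n_samples))

    # planted outlier subgroups; carriers drawn at random among cases so
    # that sample order never carries meaning
    carriers: dict[str, list[str]] = {}
    carrier_effects: dict[str, float] = {}
    case_offset = scenario.n_control
    for po in scenario.planted_outliers:
        picked = rng.choice(scenario.n_case, size=po.n_carriers, replace=False)
        cols = case_offset + np.sort(picked)
        values[probe_pos[po.probe_id], cols] += po.effect
        carriers[po.probe_id] = [samples[c] for c in cols]
        carrier_effects[po.probe_id] = po.effect

    # eQTL: Hardy-Weinberg dosages at the scenario MAF, additive shift.
    dosages: dict[str, int] = {}
    eqtl_probe = eqtl_beta = None
    if scenario.eqtl is not None:
        p = scenario.eqtl.maf
        dos = rng.choice(3, size=n_samples, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
        values[probe_pos[scenario.eqtl.probe_id]] += scenario.eqtl.beta * dos
        dosages = {s: int(d) for s, d in zip(samples, dos)}
        eqtl_probe, eqtl_beta = scenario.eqtl.probe_id, scenario.eqtl.beta

    # batch location/scale structure
    batch_labels = np.array(["B1"] * n_samples, dtype=object)
    if scenario.batches:
        order = rng.permutation(n_samples)
        start = 0
        for b in scenario.batches:
            idx = order[start : start + b.size]
            start += b.size
            batch_labels[idx] = b.label
            values[:, idx] = means[:, None] + (values[:, idx] - means[:, None]) * b.scale + b.shift

    # detection P-values: expressed cells detected (< 0.01) except dropouts
    detected = rng.random((scenario.n_probes, n_samples)) >= scenario.detection_dropout_rate
    det_p = np.where(
        detected,
        rng.uniform(0.0, 0.01, (scenario.n_probes, n_samples)),
        rng.uniform(0.01, 1.0, (scenario.n_probes, n_samples)),
    )

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=samples),
        detection_p=pd.DataFrame(det_p, index=probe_ids, columns=samples),
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "cohort": ["control"] * scenario.n_control + ["case"] * scenario.n_case,
                "batch": batch_labels,
                "stimulation": "unstimulated",
                "genotype_dosage": [dosages.get(s) for s in samples],
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    cytokines = simulate_cytokines(scenario, rng=rng)
    truth = SimTruth(
        carriers=carriers,
        carrier_effects=carrier_effects,
        eqtl_probe=eqtl_probe,
        eqtl_beta=eqtl_beta,
        dosages=dosages,
        corr_targets={
            "control": _pairs_dict(scenario.cytokine_corr_control),
            "case": _pairs_dict(scenario.cytokine_corr_case),
        },
        probe_means={pid: float(means[i]) for pid, i in probe_pos.items()},
        probe_sds={pid: float(sds[i]) for pid, i in probe_pos.items()},
    )
    return SimCohort(expression=expr, metadata=meta, cytokines=cytokines, truth=truth)


def _pairs_dict(corr: np.ndarray) -> dict[str, float]:
    corr = np.asarray(corr)
    out = {}
    for i in range(5):
        for j in range(i + 1, 5):
            out[f"{CYTOKINES[i]}|{CYTOKINES[j]}"] = float(corr[i, j])
    return out


def simulate_cytokines(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Secretion panel: per cohort, 5 log2-scale cytokines from a
    multivariate normal with the cohort's target correlation matrix,
    exponentiated to pg/ml.  Viability absorbance ~ normal(1.0, 0.05)
    truncated positive.

    Returns a long-format DataFrame with columns sample_id, cohort,
    cytokine, concentration_pg_ml, viability_a570.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    rows = []
    means = np.asarray(scenario.cytokine_log2_means, dtype=float)
    sds = np.asarray(scenario.cytokine_log2_sds, dtype=float)
    shift = np.asarray(scenario.cytokine_case_log2_shift, dtype=float)
    for cohort, n, corr, mu in (
        ("control", scenario.n_cytokine_control, scenario.cytokine_corr_control, means),
        ("case", scenario.n_cytokine_case, scenario.cytokine_corr_case, means + shift),
    ):
        cov = np.asarray(corr, dtype=float) * np.outer(sds, sds)
        log2_vals = rng.multivariate_normal(mu, cov, size=n, method="svd")
        viability = np.abs(rng.normal(1.0, 0.05, size=n))
        prefix = "HCc" if cohort == "control" else "CDc"
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            for k, cyt in enumerate(CYTOKINES):
                rows.append(
                    {
                        "sample_id": sid,
                        "cohort": cohort,
                        "cytokine": cyt,
                        "concentration_pg_ml": float(2.0 ** log2_vals[i, k]),
                        "viability_a570": float(viability[i]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text scenario round-trip


def scenario_to_yaml(scenario: SimScenario, path) -> None:
    d = asdict(scenario)
    d["cytokine_corr_control"] = np.asarray(scenario.cytokine_corr_control).tolist()
    d["cytokine_corr_case"] = np.asarray(scenario.cytokine_corr_case).tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def scenario_from_yaml(path) -> SimScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["cytokine_corr_control"] = np.asarray(d["cytokine_corr_control"], dtype=float)
    d["cytokine_corr_case"] = np.asarray(d["cytokine_corr_case"], dtype=float)
    d["batches"] = [BatchSpec(**b) for b in d.get("batches", [])]
    d["planted_outliers"] = [PlantedOutlier(**p) for p in d.get("planted_outliers", [])]
    if d.get("eqtl"):
        d["eqtl"] = EqtlSpec(**d["eqtl"])
    for key in (
        "baseline_mean_range",
        "probe_sd_range",
        "cytokine_log2_means",
        "cytokine_log2_sds",
        "cytokine_case_log2_shift",
    ):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimScenario(**d)
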