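"""End-to-end pipeline driver and run manifest.

Stages: detection filter -> batch adjustment -> differential expression
-> per-individual outlier calling -> recurrence aggregation, with
optional secretion-network and eQTL stages when their inputs are
configured.  Every output table is written tab-delimited (summaries as
JSON) and listed in a manifest with its SHA-256 digest, so a rerun with
the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as cio
from . import outliers as out_mod
from . import qcfilter, cohortstats, secretion, eqtl as eqtl_mod
from .qcfilter import BATCH_MODEL_NOTE
from .cohortstats import DE_MODEL_NOTE

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    expression_path: str
    metadata_path: str
    output_dir: str
    detection_path: str | None = None
    cytokine_path: str | None = None
    genotype_path: str | None = None
    eqtl_probe: str | None = None
    eqtl_snp_id: str = ""
    detection_p: float = 0.01
    detection_fraction: float = 0.5
    outlier_p: float = 0.005
    fc_threshold: float = 1.0
    min_carriers: int = 3
    alpha: float = 0.05
    normalize_viability: bool = True
    skip_batch_adjust: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("detection_p", 0.0, 1.0),
            ("outlier_p", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}), got {v}")
        if not 0.0 < self.detection_fraction <= 1.0:
            raise ValueError("detection_fraction must lie in (0, 1]")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be non-negative")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be at least 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest (also
    written to ``manifest.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
        "outputs": {},
        "deviations": [BATCH_MODEL_NOTE, DE_MODEL_NOTE],
    }
    for key in ("expression_path", "metadata_path", "detection_path",
                "cytokine_path", "genotype_path"):
        p = getattr(config, key)
        if p is not None:
            manifest["inputs"][key] = _digest(Path(p))

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    expr = stage("load", lambda: cio.read_expression(
        config.expression_path, detection_path=config.detection_path))
    meta = stage("load", lambda: cio.read_metadata(config.metadata_path)).aligned_to(expr)

    if expr.detection_p is not None:
        expr = stage("detection-filter", lambda: qcfilter.filter_by_detection(
            expr, config.detection_p, config.detection_fraction))
    manifest["stages"]["detection_filter"] = {"probes_retained": expr.n_probes}

    if not config.skip_batch_adjust and meta.table["batch"].nunique() > 1:
        expr = stage("batch-adjust", lambda: qcfilter.adjust_batches(expr, meta))
        manifest["stages"]["batch_adjust"] = {"batches": int(meta.table["batch"].nunique())}

    de = stage("differential-expression",
               lambda: cohortstats.differential_expression(expr, meta))
    cio.write_calls(de, outdir / "differential_expression.tsv")
    manifest["stages"]["differential_expression"] = {
        "n_probes": len(de),
        "n_adjp_lt_alpha": int((de["adjp"] < config.alpha).sum()),
    }

    calls = stage("outliers", lambda: out_mod.call_outliers(
        expr, meta, config.outlier_p, config.fc_threshold))
    passing = calls[calls["passes"]]
    cio.write_calls(passing, outdir / "outlier_calls.tsv")
    burden = out_mod.summarize_outlier_burden(calls, expr)
    cio.write_json(burden, outdir / "outlier_burden.json")
    recurrence = stage("recurrence", lambda: out_mod.aggregate_recurrence(
        calls, config.min_carriers))
    cio.write_recurrence(recurrence, outdir / "recurrence.tsv")
    manifest["stages"]["outliers"] = {
        "n_calls": len(calls),
        "n_passing": int(len(passing)),
        "n_recurrent_probes": int(len(recurrence)),
        **burden,
    }

    if config.cytokine_path is not None:
        def run_secretion():
            table = cio.read_cytokines(config.cytokine_path)
            if config.normalize_viability and "viability_a570" in table.columns:
                table = secretion.normalize_by_viability(table)
            nets = {c: secretion.build_network(table, c, config.alpha)
                    for c in ("control", "case")}
            comparison = secretion.compare_networks(nets["control"], nets["case"])
            levels = secretion.compare_secretion(table)
            return nets, comparison, levels

        nets, comparison, levels = stage("secretion", run_secretion)
        for cohort, net in nets.items():
            cio.write_calls(net.edges, outdir / f"network_{cohort}.tsv")
        cio.write_calls(comparison, outdir / "network_comparison.tsv")
        cio.write_calls(levels, outdir / "secretion_comparison.tsv")
        manifest["stages"]["secretion"] = {
            "significant_edges_control": int(nets["control"].edges["significant"].sum()),
            "significant_edges_case": int(nets["case"].edges["significant"].sum()),
        }

    if config.eqtl_probe is not None:
        def run_eqtl():
            m = meta
            if config.genotype_path is not None:
                dos = cio.read_genotypes(config.genotype_path)
                t = m.table.copy()
                t["genotype_dosage"] = dos.reindex(t.index)
                from .datatypes import SampleMetadata
                m = SampleMetadata(t)
            return eqtl_mod.cohort_eqtl(expr, m, config.eqtl_probe, config.eqtl_snp_id)

        results = stage("eqtl", run_eqtl)
        cio.write_json({c: asdict(r) for c, r in results.items()}, outdir / "eqtl.json")
        manifest["stages"]["eqtl"] = {
            c: {"beta": r.beta, "r_squared": r.r_squared, "p": r.p}
            for c, r in results.items()
        }

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _digest(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
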