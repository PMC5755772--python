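"""One-command orchestration of the full analysis.

generate/read cohort → complementary encoding → Auto-CM → whole-cohort
MST + MRG → fracture-subgroup MRGs → triage summary, with every artifact
written to an output directory together with the run configuration and a
stage-by-stage log.  Fixed (config, seed) reproduces every artifact
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .autocm import AutoCMConfig, train_autocm, weights_to_distances
from .clinical import TriageThresholds, triage_risk
from .cohort import CohortTable, default_schema, read_cohort_csv, write_cohort_csv
from .graphs import (
    SemanticGraph,
    find_hubs,
    maximally_regular_graph,
    minimum_spanning_tree,
    plot_semantic_graph,
    subgroup_maps,
    write_dot,
    write_edgelist_csv,
    write_graphml,
)
from .scaling import expand_complementary
from .simulate import GeneratorConfig, sample_cohort

logger = logging.getLogger("osteomap")


class PipelineError(RuntimeError):
    """Wraps any stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input: str = "synthetic"          # path to a cohort CSV, or "synthetic"
    n_records: int = 125
    seed: int = 0
    autocm: AutoCMConfig = field(default_factory=AutoCMConfig)
    triage: TriageThresholds = field(default_factory=TriageThresholds)
    outdir: str = "osteomap_run"
    verbosity: str = "info"           # quiet | info | debug
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "autocm" in d and isinstance(d["autocm"], dict):
            d["autocm"] = AutoCMConfig(**d["autocm"])
        if "triage" in d and isinstance(d["triage"], dict):
            d["triage"] = TriageThresholds(**d["triage"])
        return cls(**d)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_pipeline_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    n_records: int
    subgroup_sizes: dict[str, int]
    converged: bool
    epochs_run: int
    hubs_mst: list[str]
    hubs_mrg: list[str]
    triage_counts: dict[str, int]
    manifest: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


_LEVELS = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}


def _setup_logging(outdir: Path, verbosity: str) -> logging.FileHandler:
    level = _LEVELS.get(verbosity, logging.INFO)
    logger.setLevel(level)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        console = logging.StreamHandler()
        console.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(console)
    return handler


def _write_graph(g: SemanticGraph, stem: Path, manifest: list[str]) -> None:
    for ext, writer in ((".graphml", write_graphml), (".dot", write_dot), (".csv", write_edgelist_csv)):
        path = stem.with_suffix(ext)
        writer(g, path)
        manifest.append(str(path))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the end-to-end analysis; see module docstring for the stages."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir, config.verbosity)
    manifest: list[str] = [str(outdir / "run.log")]
    t0 = time.time()

    def stage(name: str):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    try:
        save_pipeline_config(config, outdir / "config.yaml")
        manifest.append(str(outdir / "config.yaml"))

        if config.input == "synthetic":
            with stage("sample_cohort"):
                gen = GeneratorConfig(n_records=config.n_records, seed=config.seed)
                table = sample_cohort(gen)
                write_cohort_csv(table, outdir / "cohort.csv")
                manifest.append(str(outdir / "cohort.csv"))
                logger.info("synthetic cohort: %d records", len(table))
        else:
            with stage("read_cohort_csv"):
                table = read_cohort_csv(config.input, default_schema())
                logger.info("read cohort %s: %d records", config.input, len(table))

        with stage("expand_complementary"):
            scaled = expand_complementary(table)
            scaled.to_csv(outdir / "scaled_matrix.csv")
            manifest.append(str(outdir / "scaled_matrix.csv"))
            logger.info(
                "scaled matrix: %d records x %d nodes", scaled.n_records, scaled.n_nodes
            )

        with stage("train_autocm"):
            wm = train_autocm(scaled, config.autocm)
            wm.to_csv(outdir / "weights.csv")
            manifest.append(str(outdir / "weights.csv"))
            logger.info(
                "Auto-CM: %d epochs, converged=%s", wm.epochs_run, wm.converged
            )

        with stage("weights_to_distances"):
            dm = weights_to_distances(wm)
            dm.to_csv(outdir / "distances.csv")
            manifest.append(str(outdir / "distances.csv"))

        with stage("minimum_spanning_tree"):
            mst = minimum_spanning_tree(dm)
            _write_graph(mst, outdir / "mst", manifest)
            logger.info("MST: %d nodes, %d edges", len(mst.nodes), mst.n_edges)

        with stage("maximally_regular_graph"):
            mrg = maximally_regular_graph(dm, mst)
            _write_graph(mrg, outdir / "mrg", manifest)
            logger.info("MRG: %d edges", mrg.n_edges)

        with stage("subgroup_maps"):
            subs = subgroup_maps(table, config.autocm)
            sizes = {}
            for label, g in subs.items():
                _write_graph(g, outdir / f"mrg_{label.lower()}", manifest)
            from .clinical import assign_fracture_group

            groups = [assign_fracture_group(s) for s in table.values("SDI")]
            sizes = {lab: groups.count(lab) for lab in set(groups)}
            logger.info("subgroups: %s", sizes)

        with stage("triage"):
            cats = [
                triage_risk(row, config.triage)
                for _, row in table.data.iterrows()
            ]
            triage_df = pd.DataFrame(
                {
                    table.schema.id_field: table.ids,
                    "risk_level": [c.level for c in cats],
                    "reasons": ["; ".join(c.reasons) for c in cats],
                }
            )
            triage_df.to_csv(outdir / "triage_summary.csv", index=False)
            manifest.append(str(outdir / "triage_summary.csv"))
            counts = triage_df["risk_level"].value_counts().to_dict()
            logger.info("triage: %s", counts)

        with stage("hubs"):
            hubs_df = pd.DataFrame(
                {
                    "node": find_hubs(mst),
                    "degree": [mst.degree(n) for n in find_hubs(mst)],
                }
            )
            hubs_df.to_csv(outdir / "hubs.csv", index=False)
            manifest.append(str(outdir / "hubs.csv"))

        if config.make_plots:
            with stage("plots"):
                plot_semantic_graph(mst, outdir / "mst.png", seed=config.seed)
                plot_semantic_graph(mrg, outdir / "mrg.png", seed=config.seed)
                manifest += [str(outdir / "mst.png"), str(outdir / "mrg.png")]

        report = RunReport(
            n_records=len(table),
            subgroup_sizes=sizes,
            converged=wm.converged,
            epochs_run=wm.epochs_run,
            hubs_mst=find_hubs(mst)[:5],
            hubs_mrg=find_hubs(mrg)[:5],
            triage_counts={str(k): int(v) for k, v in counts.items()},
            manifest=manifest + [str(outdir / "report.json")],
        )
        report.to_json(outdir / "report.json")
        logger.info("done in %.1f s; %d artifacts", time.time() - t0, len(report.manifest))
        return report
    finally:
        handler.close()
        logger.removeHandler(handler)
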