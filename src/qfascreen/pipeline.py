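"""End-to-end pipeline: simulate/read → fit → interactions → profiles → files.

The pipeline is deterministic: re-running with an identical configuration
and seed reproduces every output table byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from . import io as qio
from .errors import ConfigurationError, PipelineError
from .growth import DEFAULT_DEAD_THRESHOLD, summarize_screen
from .interactions import compute_interactions, estimate_independence_slope
from .plots import fitness_plot, profile_plot, read_highlight_sets
from .profiles import build_profile_matrix, normalize_profiles, rank_similar_profiles
from .simulate import SimulationConfig, simulate_screen_pair

logger = logging.getLogger("qfascreen")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_paths`` (raw time-series TSVs) or ``simulation``
    must be supplied.
    """

    outdir: str
    input_paths: list[str] | None = None
    simulation: SimulationConfig | None = None
    dead_threshold: float = DEFAULT_DEAD_THRESHOLD
    slope_method: str = "robust"
    q_threshold: float = 0.05
    profile_metric: str = "pearson"
    min_overlap: int = 4
    profile_query: str | None = None
    highlight_file: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        v = []
        if (self.input_paths is None) == (self.simulation is None):
            v.append("exactly one of input_paths or simulation must be supplied")
        if not (0 < self.q_threshold < 1):
            v.append(f"q_threshold must be in (0, 1), got {self.q_threshold}")
        if self.slope_method not in ("robust", "lsq_origin"):
            v.append(f"unknown slope_method {self.slope_method!r}")
        if self.profile_metric not in ("pearson", "euclidean"):
            v.append(f"unknown profile_metric {self.profile_metric!r}")
        if self.dead_threshold <= 1:
            v.append(f"dead_threshold must exceed 1, got {self.dead_threshold}")
        if v:
            raise ConfigurationError(v)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "timepoints" in sim:
                sim["timepoints"] = tuple(float(t) for t in sim["timepoints"])
            for key in ("plate_geometry", "K_dist", "r_dist", "G0_dist"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name, fn, counts, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(name, str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all products under ``config.outdir``.

    Returns a report dict (also written as ``run_log.json``) with per-stage
    counts, the config hash and ``complete`` status.  On a stage failure the
    log is written with ``complete: false`` before the error propagates.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    qio.ensure_writable(config.outdir)

    report = {
        "versions": {"qfascreen": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "complete": False,
    }

    def finish(error=None):
        if error is not None:
            report["error"] = str(error)
        with open(os.path.join(config.outdir, "run_log.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    try:
        # --- acquire raw curves -------------------------------------------
        if config.simulation is not None:
            sim = config.simulation
            logger.info("simulating screen pair: %d genes x %d replicates",
                        sim.n_genes, sim.n_replicates)
            control_curves, query_curves, truth = _stage(
                "simulate", simulate_screen_pair, report, sim)
            qio.write_raw_timeseries(
                control_curves + query_curves,
                os.path.join(config.outdir, "raw_timeseries.tsv"))
            qio.write_ground_truth(truth, config.outdir)
            screens = {"control": control_curves, "query": query_curves}
        else:
            curves = []
            for path in config.input_paths:
                curves.extend(_stage("read", qio.read_raw_timeseries, report, path))
            screens = {}
            for c in curves:
                screens.setdefault(c.background, []).append(c)
        report["stages"]["curves"] = {b: len(cs) for b, cs in screens.items()}

        # --- fit and summarize --------------------------------------------
        tables = {}
        for background, curves in screens.items():
            logger.info("fitting %d %s cultures", len(curves), background)
            tables[background] = _stage(
                "fit", summarize_screen, report, curves, config.dead_threshold)
        report["stages"]["fitness_tables"] = {
            b: len(t.data) for b, t in tables.items()}

        # --- interactions -------------------------------------------------
        interactions = None
        m = None
        if "control" in tables and "query" in tables:
            m = _stage("slope", estimate_independence_slope, report,
                       tables["control"], tables["query"], config.slope_method)
            interactions = _stage("interactions", compute_interactions, report,
                                  tables["control"], tables["query"], m,
                                  config.q_threshold)
            report["stages"]["interactions"] = {
                "m": m,
                "n_scored": len(interactions),
                "n_suppressor": int((interactions["call"] == "suppressor").sum()),
                "n_enhancer": int((interactions["call"] == "enhancer").sum()),
            }

        # --- profiles -----------------------------------------------------
        rankings = []
        matrix = None
        if len(tables) >= 2:
            matrix = _stage("profiles", build_profile_matrix, report,
                            list(tables.values()), "fitness")
            qio.write_profile_matrix(
                matrix, os.path.join(config.outdir, "profile_matrix.tsv"))
            if config.profile_query and len(matrix.screens) >= config.min_overlap:
                rankings.append(_stage(
                    "profiles", rank_similar_profiles, report, matrix,
                    config.profile_query, config.profile_metric,
                    config.min_overlap))
            report["stages"]["profiles"] = {
                "n_genes": len(matrix.genes), "n_screens": len(matrix.screens)}

        # --- tables and plots ---------------------------------------------
        written = _stage("write", qio.write_results_tables, report,
                         list(tables.values()), interactions, rankings,
                         config.outdir)
        report["stages"]["files"] = sorted(written)

        if interactions is not None:
            highlights = None
            if config.highlight_file:
                highlights = read_highlight_sets(config.highlight_file)
            else:
                top = interactions.loc[interactions["call"] != "none"]
                top = top.reindex(top["gis"].abs().sort_values(ascending=False).index)
                if len(top):
                    highlights = {"strongest interactions": list(top["orf"].head(10))}
            _stage("plot", fitness_plot, report, tables["control"],
                   tables["query"], m,
                   os.path.join(config.outdir, "fitness_plot.png"), highlights)
        if matrix is not None:
            show = (list((interactions.loc[interactions["call"] != "none", "orf"]).head(4))
                    if interactions is not None else []) or matrix.genes[:4]
            _stage("plot", profile_plot, report, matrix, show,
                   os.path.join(config.outdir, "profile_plot.png"))

        report["complete"] = True
        finish()
        return report
    except PipelineError as exc:
        logger.error("pipeline aborted: %s", exc)
        finish(error=exc)
        raise
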