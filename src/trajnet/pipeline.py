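"""End-to-end orchestration: clean -> describe -> direction -> odds ratios
-> network -> trajectories, with seeded determinism and per-stage outputs.

Every output file starts with ``#`` header lines recording package version,
seed, and a hash of the effective configuration, so any table can be traced
back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    ExclusionConfig,
    apply_exclusions,
    first_onsets,
    multimorbidity_distribution,
    read_cohort,
    write_cohort,
)
from .descriptives import onset_age_histogram, onset_age_summary, weighted_prevalence
from .direction import (
    enumerate_pairs,
    results_frame,
    select_directed_pairs,
    run_pair_tests,
)
from .errors import ConfigurationError
from .matching import MatchConfig, estimate_all_pairs, estimates_frame
from .network import (
    build_network,
    export_network,
    linear_trajectories,
    rank_trajectories,
    trajectories_frame,
)
from .simulate import SimulationConfig, config_from_dict, simulate_cohort

log = logging.getLogger("trajnet")


@dataclass
class DirectionOptions:
    alpha: float = 0.05
    policy: str = "bonferroni_pairs"
    alternative: str = "two-sided"


@dataclass
class NetworkOptions:
    max_path_length: int = 4
    top_k: int = 10
    age_among: str = "stem"
    n_hubs: int = 4


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "trajnet_out"
    participants_path: Optional[str] = None
    events_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    direction: DirectionOptions = field(default_factory=DirectionOptions)
    matching: MatchConfig = field(default_factory=MatchConfig)
    network: NetworkOptions = field(default_factory=NetworkOptions)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        sim = None
        if data.get("simulation") is not None:
            sim_data = dict(data["simulation"])
            sim_data.setdefault("seed", data.get("seed", 0))
            sim = config_from_dict(sim_data)
        inputs = dict(data.get("inputs") or {})
        return cls(
            seed=int(data.get("seed", 0)),
            output_dir=str(data.get("output_dir", "trajnet_out")),
            participants_path=inputs.get("participants"),
            events_path=inputs.get("events"),
            simulation=sim,
            exclusions=ExclusionConfig(**dict(data.get("exclusions") or {})),
            direction=DirectionOptions(**dict(data.get("direction") or {})),
            matching=MatchConfig(
                **{"seed": int(data.get("seed", 0)), **dict(data.get("matching") or {})}
            ),
            network=NetworkOptions(**dict(data.get("network") or {})),
        )

    def config_hash(self) -> str:
        # dataclass repr is deterministic for a given construction, and
        # handles the tuple-keyed dependency matrix that JSON cannot;
        # output_dir is excluded: where results land is not part of the
        # analysis identity
        return hashlib.sha1(repr(replace(self, output_dir="")).encode()).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """Cross-field checks; returns human-readable findings (empty = ok)."""
    findings: list[str] = []
    has_files = config.participants_path is not None or config.events_path is not None
    if has_files and config.simulation is not None:
        findings.append("give either input files or a simulation config, not both")
    if not has_files and config.simulation is None:
        findings.append("one of input files or a simulation config is required")
    if has_files and (config.participants_path is None or config.events_path is None):
        findings.append("both participants and events paths are required")
    if config.matching.ratio < 1:
        findings.append("matching: ratio >= 1 required")
    if config.direction.policy not in ("bonferroni_pairs", "per_pair_n"):
        findings.append(f"direction: unknown policy {config.direction.policy!r}")
    if not (0 < config.direction.alpha < 1):
        findings.append("direction: alpha must be in (0, 1)")
    if config.network.max_path_length < 2:
        findings.append("network: max_path_length >= 2 required")
    if config.simulation is not None:
        try:
            config.simulation.validate()
        except ConfigurationError as exc:
            findings.append(f"simulation: {exc}")
    return findings


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"trajnet {__version__}",
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]


def _write_frame(df: pd.DataFrame, path: Path, config: PipelineConfig, sep="\t") -> None:
    with open(path, "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def _write_json(obj, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        json.dump({"meta": _header(config), "data": obj}, fh, indent=2, default=str)
        fh.write("\n")


def load_or_simulate(config: PipelineConfig) -> Cohort:
    if config.simulation is not None:
        cohort, _ = simulate_cohort(replace(config.simulation, seed=config.seed))
        return cohort
    return read_cohort(config.events_path, config.participants_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing intermediate tables under ``output_dir``.

    A stage failure preserves the outputs written so far and is recorded in
    the returned report under ``failed_stage``.
    """
    findings = validate_config(config)
    if findings:
        raise ConfigurationError("; ".join(findings))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "failed_stage": None,
    }
    stage = "load"
    try:
        raw = load_or_simulate(config)
        report["stages"]["load"] = {
            "participants": raw.n_participants, "events": raw.n_events,
        }

        stage = "clean"
        cohort, excl = apply_exclusions(raw, config.exclusions)
        if cohort.n_participants == 0:
            log.warning("cohort empty after exclusions")
        write_cohort(
            cohort,
            out / "events.csv",
            out / "participants.csv",
            header_lines=_header(config),
        )
        _write_json(excl.as_dict(), out / "exclusion_log.json", config)
        report["stages"]["clean"] = excl.as_dict()

        stage = "describe"
        dist_w = multimorbidity_distribution(cohort, weighted=True)
        dist_u = multimorbidity_distribution(cohort, weighted=False)
        _write_json(
            {"weighted": dist_w, "unweighted": dist_u},
            out / "multimorbidity.json",
            config,
        )
        records = first_onsets(cohort)
        _write_frame(onset_age_summary(records), out / "onset_age_summary.tsv", config)
        hist_rows = [
            {"disease": d, "age": a, "count": c}
            for d, counts in onset_age_histogram(cohort).items()
            for a, c in counts.items()
        ]
        _write_frame(
            pd.DataFrame(hist_rows, columns=["disease", "age", "count"]),
            out / "onset_age_histogram.tsv",
            config,
        )
        diseases = sorted({e.disease for e in cohort.events})
        prev = {d: weighted_prevalence(cohort, disease=d) for d in diseases} \
            if cohort.participants else {}
        _write_json(prev, out / "weighted_prevalence.json", config)
        report["stages"]["describe"] = {"diseases": diseases}

        stage = "direction"
        pairs = enumerate_pairs(diseases)
        results = run_pair_tests(
            cohort, pairs,
            alpha=config.direction.alpha,
            policy=config.direction.policy,
            alternative=config.direction.alternative,
        )
        _write_frame(results_frame(results), out / "direction_tests.tsv", config)
        directed = select_directed_pairs(results)
        report["stages"]["direction"] = {
            "pairs_tested": len(pairs),
            "pairs_directed": len(directed),
            "alpha": config.direction.alpha,
            "policy": config.direction.policy,
        }

        stage = "pairs"
        match_cfg = replace(config.matching, seed=config.seed)
        estimates = estimate_all_pairs(
            cohort, [(r.source, r.target) for r in directed], match_cfg
        )
        _write_frame(estimates_frame(estimates), out / "pair_estimates.tsv", config)
        selected = [e for e in estimates if e.selected]
        report["stages"]["pairs"] = {
            "pairs_estimated": len(estimates),
            "edges_selected": len(selected),
            "bootstrap_reps": match_cfg.bootstrap_reps,
        }

        stage = "network"
        net = build_network(selected, cohort)
        if not net.graph.edges:
            log.warning("no edges selected; network is empty")
        export_network(net, out / "network_edgelist.tsv", format="edgelist")
        export_network(net, out / "network.graphml", format="graphml")
        _write_json(net.roles(config.network.n_hubs), out / "network_roles.json", config)
        report["stages"]["network"] = {
            "nodes": len(net.graph.nodes),
            "edges": len(net.graph.edges),
            "has_cycle": net.has_cycle,
        }

        stage = "trajectories"
        rows = linear_trajectories(cohort, net, age_among=config.network.age_among)
        ranked = rank_trajectories(rows, k=config.network.top_k)
        _write_frame(trajectories_frame(ranked), out / "top_trajectories.tsv", config)
        report["stages"]["trajectories"] = {
            "candidates": len(rows),
            "ranked": len(ranked),
        }
    except Exception as exc:  # preserve partial outputs, mark the stage
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
        log.error("stage %s failed: %s", stage, exc)
    _write_json(report, out / "run_report.json", config)
    return report
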