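"""End-to-end orchestration: simulate -> psi -> classify -> metaprofile.

Every stage boundary is a plain-text TSV/JSON artifact, so each output is a
valid input for the next stage and the whole run is auditable and
reproducible: identical config and seed give byte-identical artifacts, which
the manifest records as SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clip_metaprofile import SECTION_WIDTH, WINDOW, metaprofile_report, write_metaprofiles
from .event_classification import classify, summary_line, write_classified
from .io_formats import read_bedgraph, read_counts, read_events
from .psi_inference import FilterThresholds, compare_conditions, write_results
from .synthetic_data import (
    CONTROL_SAMPLE,
    KNOCKDOWN_SAMPLE,
    SimulationConfig,
    simulate_all,
)

logger = logging.getLogger("tandem5ss")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str = "tandem5ss_run"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    events_path: str | None = None
    counts_path: str | None = None
    clip_path: str | None = None
    control: str = CONTROL_SAMPLE
    treatment: str = KNOCKDOWN_SAMPLE
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    l_inc: float = 1.0
    l_exc: float = 1.0
    grid_step: float = 0.001
    window: int = WINDOW
    section_width: int = SECTION_WIDTH

    def __post_init__(self) -> None:
        if self.window % self.section_width != 0:
            raise ValueError("window must be divisible by section width")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "simulation" in raw:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        if "thresholds" in raw:
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        cfg = cls(**raw)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = []
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    def done(name: str, t0: float, n_records: int) -> None:
        dt = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs (%d records)", name, dt, n_records)
        stages.append({"name": name, "seconds": round(dt, 3), "n_records": n_records})

    # stage 1: inputs
    t0 = stage("inputs")
    if config.simulate:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
        paths = simulate_all(sim, outdir)
        events_path, counts_path, clip_path = paths["events"], paths["counts"], paths["clip"]
        artifacts["truth"] = paths["truth"]
    else:
        for name, p in (
            ("events", config.events_path),
            ("counts", config.counts_path),
            ("clip", config.clip_path),
        ):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"stage inputs: required {name} file not found: {p}")
        events_path = Path(config.events_path)
        counts_path = Path(config.counts_path)
        clip_path = Path(config.clip_path)
    events = read_events(events_path)
    counts = read_counts(counts_path)
    track = read_bedgraph(clip_path)
    artifacts.update(events=events_path, counts=counts_path, clip=clip_path)
    done("inputs", t0, len(events))

    # stage 2: psi inference
    t0 = stage("psi")
    try:
        results = compare_conditions(
            counts,
            config.control,
            config.treatment,
            l_inc=config.l_inc,
            l_exc=config.l_exc,
            h=config.grid_step,
            thresholds=config.thresholds,
        )
    except Exception as exc:
        raise RuntimeError(f"stage psi failed: {exc}") from exc
    results_path = outdir / "psi_results.tsv"
    write_results(results, results_path)
    artifacts["psi_results"] = results_path
    done("psi", t0, len(results))

    # stage 3: classification
    t0 = stage("classify")
    classified, class_counts = classify(results)
    classified_path = outdir / "classified.tsv"
    write_classified(classified, classified_path)
    artifacts["classified"] = classified_path
    logger.info("%s", summary_line(class_counts))
    done("classify", t0, len(classified))

    # stage 4: metaprofiles
    t0 = stage("metaprofile")
    grid = metaprofile_report(events, classified, track)
    written = write_metaprofiles(grid, outdir)
    for p in written:
        artifacts[p.stem] = p
    done("metaprofile", t0, len(written))

    # stage 5: manifest
    t0 = stage("manifest")
    stages.append(
        {"name": "manifest", "seconds": round(time.perf_counter() - t0, 3), "n_records": len(artifacts)}
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds.__dict__,
        "class_counts": dict(class_counts),
        "stages": stages,
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in artifacts.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("manifest written to %s", manifest_path)
    return manifest
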