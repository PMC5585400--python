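"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the downstream products of a knockdown RNA-seq /
CLIP-seq study of tandem 5' splice sites: a table of two-donor events, two-
condition isoform-diagnostic read counts with known per-event inclusion
fractions, and per-base CLIP coverage in which a binding peak is planted at a
configurable position relative to the intron-distal donor, over Poisson
background. Every draw flows from ``SimulationConfig.seed``, so a fixed
config yields byte-identical output files.

Counts are simulated at the diagnostic-read level (total reads Poisson, the
proximal fraction binomial at the effective-length-adjusted psi): that is
exactly the summary the inference consumes. CLIP peaks are rectangular by
default so the section-argmax ground truth is exact; a Gaussian shape is
available. Peaks are planted only in distal-activated events, mirroring the
biology the cohort models (the regulator binds immediately upstream of the
distal donor in the events it represses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    CountRecord,
    CoverageTrack,
    TandemDonorEvent,
    write_bedgraph,
    write_counts,
    write_events,
)
from .psi_inference import read_probability

CONTROL_SAMPLE = "control"
KNOCKDOWN_SAMPLE = "knockdown"

_MARGIN = 250  # clearance per anchor so every 400-nt window fits its slot


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``offset_distribution`` and ``peak_center_offset`` accept either a fixed
    integer or an inclusive (low, high) range sampled uniformly per event.
    ``psi_control``/``psi_knockdown`` fix the inclusion fractions for every
    event when set; when None they are drawn per direction class using
    ``class_fractions`` (distal_activated, proximal_activated, unchanged) and
    ``effect_size``.
    """

    n_events: int = 200
    offset_distribution: int | tuple[int, int] = 11
    psi_control: float | None = None
    psi_knockdown: float | None = None
    class_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    effect_size: float = 0.4
    depth: float = 200.0
    l_inc: float = 1.0
    l_exc: float = 1.0
    peak_fraction: float = 0.9
    peak_center_offset: int | tuple[int, int] = -25
    peak_width: int = 30
    peak_height: float = 10.0
    peak_shape: str = "rect"
    background_rate: float = 1.0
    strand_mix: float = 0.5
    seed: int = 0
    chrom: str = "chrS"
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        probs = [self.peak_fraction, self.strand_mix, *self.class_fractions]
        if self.psi_control is not None:
            probs.append(self.psi_control)
        if self.psi_knockdown is not None:
            probs.append(self.psi_knockdown)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if min(self.depth, self.background_rate, self.peak_height) < 0 or self.peak_width < 0:
            raise ValueError("depth, rates and peak width must be non-negative")
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if self.peak_shape not in ("rect", "gaussian"):
            raise ValueError("peak_shape must be 'rect' or 'gaussian'")
        if min(self.l_inc, self.l_exc) <= 0:
            raise ValueError("effective lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("offset_distribution", "peak_center_offset", "class_fractions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EventTruth:
    psi_control: float
    psi_knockdown: float
    direction: str
    peak_planted: bool
    peak_center: int | None  # transcript-relative to the distal donor


@dataclass
class GroundTruth:
    """Per-event latent state the cohort was generated from."""

    events: dict[str, EventTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: asdict(v) for k, v in self.events.items()}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(events={k: EventTruth(**v) for k, v in raw.items()})


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _draw_int(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def _direction_from_delta(delta: float, threshold: float = 0.2) -> str:
    if delta <= -threshold:
        return "distal_activated"
    if delta >= threshold:
        return "proximal_activated"
    return "unchanged"


def simulate_events(
    config: SimulationConfig,
) -> tuple[list[TandemDonorEvent], GroundTruth]:
    """Place events in non-overlapping slots on a synthetic chromosome and
    draw their latent state (psi pair, direction class, CLIP peak)."""
    rng = _rng(config, 1)
    max_offset = (
        config.offset_distribution[1]
        if isinstance(config.offset_distribution, tuple)
        else config.offset_distribution
    )
    slot = 2 * _MARGIN + max_offset + 500
    required = 500 + config.n_events * slot
    if config.chrom_length is not None and required > config.chrom_length:
        raise ValueError(
            f"cannot place {config.n_events} non-overlapping 400-nt windows on a "
            f"chromosome of length {config.chrom_length} (need {required})"
        )

    events: list[TandemDonorEvent] = []
    truth = GroundTruth()
    for i in range(config.n_events):
        event_id = f"ev{i:05d}"
        offset = _draw_int(rng, config.offset_distribution)
        strand = "-" if rng.random() < config.strand_mix else "+"
        base = 500 + i * slot
        if strand == "+":
            distal, proximal = base, base + offset
            acceptor = proximal + 300
        else:
            proximal, distal = base, base + offset
            acceptor = proximal - 300
        events.append(
            TandemDonorEvent(event_id, config.chrom, strand, distal, proximal, acceptor)
        )

        direction = ("distal_activated", "proximal_activated", "unchanged")[
            int(rng.choice(3, p=config.class_fractions))
        ]
        if config.psi_control is not None:
            psi_c = config.psi_control
            psi_k = (
                config.psi_knockdown if config.psi_knockdown is not None else config.psi_control
            )
            direction = _direction_from_delta(psi_k - psi_c)
        elif direction == "distal_activated":
            psi_c = float(rng.uniform(max(config.effect_size, 0.6), 0.9))
            psi_k = psi_c - config.effect_size
        elif direction == "proximal_activated":
            psi_c = float(rng.uniform(0.1, min(1.0 - config.effect_size, 0.4)))
            psi_k = psi_c + config.effect_size
        else:
            psi_c = float(rng.uniform(0.2, 0.8))
            psi_k = psi_c

        planted = direction == "distal_activated" and rng.random() < config.peak_fraction
        center = _draw_int(rng, config.peak_center_offset) if planted else None
        truth.events[event_id] = EventTruth(psi_c, psi_k, direction, planted, center)
    return events, truth


def simulate_counts(
    events: Sequence[TandemDonorEvent], truth: GroundTruth, config: SimulationConfig
) -> list[CountRecord]:
    """Two-condition diagnostic counts: N ~ Poisson(depth), n_proximal ~
    Binomial(N, psi adjusted for effective lengths)."""
    rng = _rng(config, 2)
    missing = [ev.event_id for ev in events if ev.event_id not in truth.events]
    if missing:
        raise ValueError(f"ground truth missing for events {missing[:3]}...")
    records = []
    for ev in events:
        t = truth.events[ev.event_id]
        for sample, psi in ((CONTROL_SAMPLE, t.psi_control), (KNOCKDOWN_SAMPLE, t.psi_knockdown)):
            total = int(rng.poisson(config.depth))
            p = float(read_probability(np.array(psi), config.l_inc, config.l_exc))
            n_prox = int(rng.binomial(total, p)) if total > 0 else 0
            records.append(CountRecord(ev.event_id, sample, total - n_prox, n_prox))
    return records


def _peak_interval(center: int, width: int) -> tuple[int, int]:
    """Half-open transcript-relative span of a planted peak."""
    lo = center - width // 2
    return lo, lo + width


def simulate_clip(
    events: Sequence[TandemDonorEvent], truth: GroundTruth, config: SimulationConfig
) -> CoverageTrack:
    """Per-base CLIP coverage: Poisson background over each event's span plus,
    for peak-planted events, a peak relative to the distal donor (genomically
    mirrored on the minus strand)."""
    rng = _rng(config, 3)
    pieces: list[tuple[int, np.ndarray]] = []
    for ev in events:
        t = truth.events[ev.event_id]
        lo = min(ev.distal_donor, ev.proximal_donor) - _MARGIN
        hi = max(ev.distal_donor, ev.proximal_donor) + _MARGIN + 1
        dense = rng.poisson(config.background_rate, hi - lo).astype(float)
        if t.peak_planted:
            assert t.peak_center is not None
            r_lo, r_hi = _peak_interval(t.peak_center, config.peak_width)
            if r_lo < -_MARGIN or r_hi > _MARGIN:
                raise ValueError(
                    f"peak span [{r_lo}, {r_hi}) exceeds the +/-{_MARGIN} nt event slot"
                )
            rs = np.arange(r_lo, r_hi)
            if config.peak_shape == "rect":
                heights = np.full(rs.size, config.peak_height)
            else:
                sigma = max(config.peak_width / 4.0, 1.0)
                heights = config.peak_height * np.exp(
                    -0.5 * ((rs - t.peak_center) / sigma) ** 2
                )
            if ev.strand == "+":
                genomic = ev.distal_donor + rs
            else:
                genomic = ev.distal_donor - rs
            dense[genomic - lo] += heights
        pieces.append((lo, dense))
    if not pieces:
        return CoverageTrack()
    # events share one chromosome in non-overlapping slots; concatenate spans
    all_records = []
    for lo, dense in pieces:
        piece = CoverageTrack.from_dense({config.chrom: (lo, dense)})
        all_records.extend(piece.records())
    return CoverageTrack(all_records)


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all three generators and write the standard pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events, truth = simulate_events(config)
    counts = simulate_counts(events, truth, config)
    track = simulate_clip(events, truth, config)
    paths = {
        "events": outdir / "events.tsv",
        "counts": outdir / "counts.tsv",
        "clip": outdir / "clip.bedgraph",
        "truth": outdir / "truth.json",
    }
    write_events(events, paths["events"])
    write_counts(counts, paths["counts"])
    write_bedgraph(track, paths["clip"])
    truth.to_json(paths["truth"])
    return paths
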