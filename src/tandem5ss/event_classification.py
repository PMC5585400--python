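"""Partition significant events by which donor the perturbation activates.

psi measures proximal-donor (inclusion) usage, so a *fall* in psi upon
perturbation means the intron-distal donor gained usage. The sign convention
is fixed once here: distal_activated requires delta_psi <= -threshold with all
significance filters passed, proximal_activated requires delta_psi >=
+threshold, everything else is unchanged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .psi_inference import DeltaPsiResult

DIRECTIONS = ("distal_activated", "proximal_activated", "unchanged")


@dataclass(frozen=True)
class ClassifiedEvent:
    event_id: str
    direction: str
    delta_psi: float
    bayes_factor: float


def classify(results: Sequence[DeltaPsiResult]) -> tuple[list[ClassifiedEvent], Counter]:
    """Three-way partition of comparison results; exhaustive and exclusive."""
    events = []
    counts: Counter = Counter({d: 0 for d in DIRECTIONS})
    for r in results:
        if r.significant and r.delta_psi <= -r.thresholds.delta_psi:
            direction = "distal_activated"
        elif r.significant and r.delta_psi >= r.thresholds.delta_psi:
            direction = "proximal_activated"
        else:
            direction = "unchanged"
        events.append(ClassifiedEvent(r.event_id, direction, r.delta_psi, r.bayes_factor))
        counts[direction] += 1
    return events, counts


def summary_line(counts: Counter) -> str:
    total = sum(counts.values())
    return (
        f"{total} events: {counts['distal_activated']} distal_activated, "
        f"{counts['proximal_activated']} proximal_activated, "
        f"{counts['unchanged']} unchanged"
    )


def write_classified(events: Sequence[ClassifiedEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.event_id, e.direction, e.delta_psi, e.bayes_factor) for e in events],
        columns=["event_id", "direction", "delta_psi", "bayes_factor"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_classified(path: str | Path) -> list[ClassifiedEvent]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        if row.direction not in DIRECTIONS:
            raise ValueError(f"{path}: unknown direction {row.direction!r}")
        out.append(
            ClassifiedEvent(
                str(row.event_id), str(row.direction), float(row.delta_psi), float(row.bayes_factor)
            )
        )
    return out
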