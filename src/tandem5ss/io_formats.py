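"""File formats and core genomic types for the tandem-donor pipeline.

All genomic interval I/O is 0-based half-open. A donor's coordinate is the
position of its first intronic base, the single unambiguous anchor shared by
both strands. BedGraph gaps read as zero coverage: the metaprofile density is
defined at every window position.

Formats handled here:

* event table — bespoke BED-like TSV with one record per tandem-donor locus
  (chrom, distal_donor, proximal_donor, strand, event_id, [acceptor]); standard
  formats have no slot for two donors in one record;
* BedGraph (4-column, UCSC) for per-base CLIP tag coverage;
* counts TSV (event_id, sample_id, n_distal, n_proximal) of isoform-diagnostic
  reads;
* scoring-matrix TSV in two dialects — per-position A/C/G/T columns, or a
  two-column 9-mer -> score lookup — distinguished by header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .motif_scoring import BASES, ScoringMatrix

STRANDS = ("+", "-")

_EVENT_COLUMNS = ("chrom", "distal_donor", "proximal_donor", "strand", "event_id")
_COUNT_COLUMNS = ("event_id", "sample_id", "n_distal", "n_proximal")


@dataclass(frozen=True)
class TandemDonorEvent:
    """One alternative-5'SS locus: two competing donors, one shared acceptor.

    The intron-distal donor is the upstream donor in transcript orientation
    (selecting it truncates the exon-terminal segment); the intron-proximal
    donor is downstream and retains it. ``offset`` is their transcript-space
    distance in nucleotides.
    """

    event_id: str
    chrom: str
    strand: str
    distal_donor: int
    proximal_donor: int
    acceptor: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"event {self.event_id}: strand must be + or -, got {self.strand!r}")
        if self.distal_donor < 0 or self.proximal_donor < 0:
            raise ValueError(f"event {self.event_id}: negative donor coordinate")
        if self.offset < 1:
            raise ValueError(
                f"event {self.event_id}: proximal donor must lie downstream of the "
                f"distal donor in transcript orientation (offset {self.offset})"
            )

    @property
    def offset(self) -> int:
        """Transcript-orientation distance from distal to proximal donor."""
        if self.strand == "+":
            return self.proximal_donor - self.distal_donor
        return self.distal_donor - self.proximal_donor

    def donor_position(self, anchor: str) -> int:
        if anchor not in ("distal", "proximal"):
            raise ValueError(f"anchor must be 'distal' or 'proximal', got {anchor!r}")
        return self.distal_donor if anchor == "distal" else self.proximal_donor


@dataclass(frozen=True)
class CountRecord:
    """Diagnostic read counts for one event in one sample."""

    event_id: str
    sample_id: str
    n_distal: int
    n_proximal: int

    def __post_init__(self) -> None:
        for name in ("n_distal", "n_proximal"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


class CoverageTrack:
    """Per-base coverage over run-length interval records.

    Positions not covered by any interval read as 0, matching BedGraph
    semantics. Intervals may not overlap (coverage would be ambiguous) and
    values may not be negative.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]] = ()) -> None:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = np.array([i[0] for i in ivals], dtype=np.int64)
            ends = np.array([i[1] for i in ivals], dtype=np.int64)
            values = np.array([i[2] for i in ivals], dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative coverage value")
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"{chrom}: overlapping intervals "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def coverage(self, chrom: str, pos: int) -> float:
        """Coverage at a single 0-based position (0 outside all intervals)."""
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base coverage over the half-open window [start, end)."""
        if end <= start:
            raise ValueError("window end must exceed start")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = values[i]
        return out

    def records(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    @classmethod
    def from_dense(cls, chrom_arrays: dict[str, tuple[int, np.ndarray]]) -> "CoverageTrack":
        """Build a track from dense arrays: chrom -> (origin, per-base values).

        Zero runs are dropped (they read back as 0 anyway), so the encoding is
        a minimal run-length representation.
        """
        recs = []
        for chrom, (origin, arr) in chrom_arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            bounds = np.concatenate(([0], change, [arr.size]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                v = arr[a]
                if v != 0:
                    recs.append((chrom, origin + int(a), origin + int(b), float(v)))
        return cls(recs)


# ---------------------------------------------------------------------------
# event tables


def read_events(path: str | Path) -> list[TandemDonorEvent]:
    """Read a BED-like tandem-donor event table.

    Columns (tab or whitespace separated): chrom, distal_donor, proximal_donor,
    strand, event_id, and optionally acceptor. Lines starting with '#' are
    comments. Malformed records raise with the line number and field.
    """
    path = Path(path)
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 fields, got {len(fields)}")
            chrom, distal_s, proximal_s, strand, event_id = fields[:5]
            coords = {}
            for name, raw in (("distal_donor", distal_s), ("proximal_donor", proximal_s)):
                try:
                    coords[name] = int(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: field {name} is not an integer: {raw!r}"
                    ) from None
            acceptor = None
            if len(fields) >= 6 and fields[5] != ".":
                try:
                    acceptor = int(fields[5])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: field acceptor is not an integer: {fields[5]!r}"
                    ) from None
            try:
                ev = TandemDonorEvent(
                    event_id=event_id,
                    chrom=chrom,
                    strand=strand,
                    distal_donor=coords["distal_donor"],
                    proximal_donor=coords["proximal_donor"],
                    acceptor=acceptor,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            events.append(ev)
    return events


def write_events(events: Sequence[TandemDonorEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tdistal_donor\tproximal_donor\tstrand\tevent_id\tacceptor\n")
        for ev in events:
            acc = "." if ev.acceptor is None else str(ev.acceptor)
            fh.write(
                f"{ev.chrom}\t{ev.distal_donor}\t{ev.proximal_donor}\t"
                f"{ev.strand}\t{ev.event_id}\t{acc}\n"
            )


# ---------------------------------------------------------------------------
# BedGraph


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column UCSC BedGraph (0-based half-open) into a CoverageTrack."""
    path = Path(path)
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 BedGraph columns")
            chrom, start_s, end_s, value_s = fields
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed BedGraph record") from None
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value {value}")
            recs.append((chrom, start, end, value))
    try:
        return CoverageTrack(recs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# count tables


def read_counts(path: str | Path) -> list[CountRecord]:
    """Read the diagnostic-count TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        counts = {}
        for name in ("n_distal", "n_proximal"):
            raw = getattr(row, name)
            try:
                counts[name] = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer count {raw!r} for event "
                    f"{row.event_id!r} sample {row.sample_id!r}"
                ) from None
        records.append(
            CountRecord(str(row.event_id), str(row.sample_id), counts["n_distal"], counts["n_proximal"])
        )
    return records


def write_counts(records: Sequence[CountRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.event_id, r.sample_id, r.n_distal, r.n_proximal) for r in records],
        columns=list(_COUNT_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scoring matrices


def read_matrix(path: str | Path, kind: str | None = None) -> ScoringMatrix:
    """Read a scoring-matrix TSV; the header selects the dialect.

    A header containing a ``kmer`` column selects the 9-mer lookup dialect
    (columns kmer, score); otherwise per-position columns A, C, G, T are
    required, with an optional leading ``pos`` column. ``kind`` defaults to
    ``kmer_lookup`` or ``ese_pwm`` respectively.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "kmer" in cols:
        if "score" not in cols:
            raise ValueError(f"{path}: lookup dialect requires a 'score' column")
        kmers = df["kmer"].astype(str).str.upper()
        if kmers.duplicated().any():
            dup = kmers[kmers.duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate 9-mer key {dup!r}")
        lookup = dict(zip(kmers, df["score"].astype(float)))
        return ScoringMatrix(kind=kind or "kmer_lookup", lookup=lookup, name=path.name)
    missing = [b for b in BASES if b not in cols]
    if missing:
        raise ValueError(f"{path}: matrix dialect missing base column(s) {missing}")
    entries = df[list(BASES)].to_numpy(dtype=float)
    return ScoringMatrix(kind=kind or "ese_pwm", entries=entries, name=path.name)


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    if matrix.kind == "kmer_lookup":
        assert matrix.lookup is not None
        df = pd.DataFrame(sorted(matrix.lookup.items()), columns=["kmer", "score"])
        df.to_csv(path, sep="\t", index=False)
        return
    assert matrix.entries is not None
    df = pd.DataFrame(matrix.entries, columns=list(BASES))
    df.insert(0, "pos", np.arange(1, matrix.width + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
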