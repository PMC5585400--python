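"""Splice-donor strength and exonic-splicing-enhancer (ESE) motif scoring.

Two model families are supported:

* additive position-specific score matrices (PWMs), as used by ESEfinder for
  SR-protein binding motifs such as the SRSF1 heptamer model, and weight-matrix
  (WMM) log-odds models of the 9-nt donor site (3 exonic + 6 intronic bases);
* precomputed 9-mer score lookups, the distribution format of maximum-entropy
  donor models, consumed as-is rather than re-fitted.

The module also designs block-scanning substitution mutants of an exon, the
classic strategy for localizing a splicing *cis*-element: a splicing-neutral
heterologous sequence is substituted into consecutive blocks and each mutant is
annotated with the change in its best ESE score.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Splicing-neutral heterologous sequences used for block-scanning mutagenesis.
HETEROLOGOUS_15 = "TCAGTATGACTCTCA"
HETEROLOGOUS_19 = "TCAGTATGACTCTCAGTAT"

DONOR_LENGTH = 9  # 3 exonic + 6 intronic bases around the 5' splice site


class MissingKmerError(KeyError):
    """A 9-mer is absent from a lookup table (absence is not a zero score)."""


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map RNA U to DNA T, and validate the ACGT alphabet."""
    s = seq.strip().upper().replace("U", "T")
    for i, b in enumerate(s):
        if b not in _BASE_INDEX:
            raise ValueError(f"invalid base {b!r} at position {i} in {context}")
    return s


@dataclass
class ScoringMatrix:
    """A position-specific score matrix or a 9-mer score lookup.

    ``kind`` is one of ``ese_pwm`` (additive ESE matrix, ESEfinder style),
    ``donor_wmm`` (per-position base frequencies for a donor weight-matrix
    model) or ``kmer_lookup`` (9-mer -> score table). For matrix kinds
    ``entries`` has shape (width, 4) in A,C,G,T order; for lookups ``lookup``
    maps 9-mers to scores and ``complete`` records whether the table covers
    every valid 9-mer for its declared donor dinucleotide space.
    """

    kind: str
    entries: np.ndarray | None = None
    lookup: dict[str, float] | None = None
    threshold: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind in ("ese_pwm", "donor_wmm"):
            if self.entries is None:
                raise ValueError(f"kind {self.kind!r} requires matrix entries")
            self.entries = np.asarray(self.entries, dtype=float)
            if self.entries.ndim != 2 or self.entries.shape[1] != 4:
                raise ValueError("matrix entries must have shape (width, 4)")
            if not np.all(np.isfinite(self.entries)):
                raise ValueError("matrix entries must be finite")
        elif self.kind == "kmer_lookup":
            if self.lookup is None:
                raise ValueError("kind 'kmer_lookup' requires a lookup table")
            for k in self.lookup:
                if len(k) != DONOR_LENGTH or any(b not in _BASE_INDEX for b in k):
                    raise ValueError(f"lookup key {k!r} is not a 9-mer over ACGT")
        else:
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    @property
    def width(self) -> int:
        if self.entries is not None:
            return self.entries.shape[0]
        return DONOR_LENGTH

    def lookup_score(self, kmer: str) -> float:
        """Score of a 9-mer in a lookup table; absence raises, never reads 0."""
        if self.kind != "kmer_lookup":
            raise ValueError("lookup_score requires a kmer_lookup matrix")
        k = normalize_sequence(kmer, context="9-mer")
        assert self.lookup is not None
        try:
            return self.lookup[k]
        except KeyError:
            raise MissingKmerError(
                f"9-mer {k!r} missing from lookup table {self.name or '<unnamed>'}"
            ) from None


@dataclass
class EseHit:
    """One scored window of a PWM scan."""

    start: int
    window: str
    score: float
    is_max: bool = False
    is_tie: bool = False


@dataclass
class DonorScore:
    """Scores of one 9-nt splice donor under the available models."""

    nine_mer: str
    wmm_score: float | None = None
    maxent_score: float | None = None
    sd_score: float | None = None
    canonical_gt: bool = True


@dataclass
class BlockMutant:
    """One block-substitution mutant and its effect on the best ESE score."""

    block_index: int
    start: int
    end: int
    replacement: str
    sequence: str
    delta_max_ese: float | None = None


def pwm_score(seq: str, matrix: ScoringMatrix) -> float:
    """Additive PWM score of a window whose length equals the matrix width."""
    if matrix.kind not in ("ese_pwm", "donor_wmm"):
        raise ValueError(f"pwm_score requires a matrix kind, got {matrix.kind!r}")
    s = normalize_sequence(seq)
    if len(s) != matrix.width:
        raise ValueError(
            f"sequence length {len(s)} does not match matrix width {matrix.width}"
        )
    assert matrix.entries is not None
    idx = np.fromiter((_BASE_INDEX[b] for b in s), dtype=int, count=len(s))
    return float(matrix.entries[np.arange(len(s)), idx].sum())


def pwm_scan(seq: str, matrix: ScoringMatrix) -> list[EseHit]:
    """Score every window of ``seq``; the maximal hit(s) are flagged.

    Ties for the maximum are all flagged ``is_max`` and ``is_tie``.
    """
    s = normalize_sequence(seq)
    w = matrix.width
    if len(s) < w:
        raise ValueError(f"sequence length {len(s)} shorter than matrix width {w}")
    hits = [EseHit(i, s[i : i + w], pwm_score(s[i : i + w], matrix)) for i in range(len(s) - w + 1)]
    best = max(h.score for h in hits)
    winners = [h for h in hits if h.score == best]
    for h in winners:
        h.is_max = True
        h.is_tie = len(winners) > 1
    return hits


def max_ese_score(seq: str, matrix: ScoringMatrix) -> float:
    """Best window score of ``seq`` under an ESE matrix."""
    return max(h.score for h in pwm_scan(seq, matrix))


def donor_score(
    nine_mer: str,
    wmm: ScoringMatrix | None = None,
    background: Mapping[str, float] | Sequence[float] | None = None,
    maxent_table: ScoringMatrix | None = None,
    sd_table: ScoringMatrix | None = None,
) -> DonorScore:
    """Score a 9-nt donor site under the provided models.

    The WMM score is the log2-odds of the site under per-position base
    frequencies ``wmm.entries`` against a background composition (uniform by
    default). Maximum-entropy and donor-frequency (SD) scores come from lookup
    tables when supplied; a missing table leaves the score ``None`` — absent is
    reported as unavailable, never as 0 — while a 9-mer missing from a
    *provided* table raises :class:`MissingKmerError`.
    """
    s = normalize_sequence(nine_mer, context="donor 9-mer")
    if len(s) != DONOR_LENGTH:
        raise ValueError(f"donor site must be 9 nt, got {len(s)}")
    result = DonorScore(nine_mer=s, canonical_gt=s[3:5] == "GT")

    if wmm is not None:
        if wmm.kind != "donor_wmm":
            raise ValueError("wmm must have kind 'donor_wmm'")
        if wmm.width != DONOR_LENGTH:
            raise ValueError(f"donor WMM must have width {DONOR_LENGTH}")
        if background is None:
            bg = np.full(4, 0.25)
        elif isinstance(background, Mapping):
            bg = np.array([background[b] for b in BASES], dtype=float)
        else:
            bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-6:
            raise ValueError("background must be 4 strictly positive frequencies summing to 1")
        assert wmm.entries is not None
        idx = [_BASE_INDEX[b] for b in s]
        freqs = wmm.entries[np.arange(DONOR_LENGTH), idx]
        with np.errstate(divide="ignore"):
            result.wmm_score = float(np.sum(np.log2(freqs) - np.log2(bg[idx])))

    if maxent_table is not None:
        result.maxent_score = maxent_table.lookup_score(s)
    if sd_table is not None:
        result.sd_score = sd_table.lookup_score(s)
    return result


def block_scan_mutants(
    seq: str,
    blocks: Sequence[tuple[int, int]],
    replacements: Sequence[str],
    ese_matrix: ScoringMatrix | None = None,
) -> list[BlockMutant]:
    """Substitute each block of ``seq`` in turn with its heterologous sequence.

    Blocks are 0-based half-open, must be non-overlapping and lie within the
    sequence; a replacement need not match its block's length. When an ESE
    matrix is given each mutant carries the change in the sequence's best
    window score, the readout for whether a substitution destroyed (or gained)
    an enhancer.
    """
    s = normalize_sequence(seq)
    if len(blocks) != len(replacements):
        raise ValueError("one replacement per block required")
    order = sorted(range(len(blocks)), key=lambda i: blocks[i][0])
    prev_end = 0
    for i in order:
        start, end = blocks[i]
        if not (0 <= start < end <= len(s)):
            raise ValueError(f"block {i + 1} ({start}, {end}) outside sequence of length {len(s)}")
        if start < prev_end:
            raise ValueError(f"block {i + 1} overlaps a previous block")
        prev_end = end
    base_score = max_ese_score(s, ese_matrix) if ese_matrix is not None else None

    mutants = []
    for i, ((start, end), repl) in enumerate(zip(blocks, replacements)):
        r = normalize_sequence(repl, context=f"replacement for block {i + 1}")
        mutant_seq = s[:start] + r + s[end:]
        delta = None
        if ese_matrix is not None:
            assert base_score is not None
            delta = max_ese_score(mutant_seq, ese_matrix) - base_score
        mutants.append(BlockMutant(i + 1, start, end, r, mutant_seq, delta))
    return mutants


def tandem_block_scheme(
    seq: str,
    n_blocks: int = 12,
    block_len: int = 15,
    first_exempt: int = 3,
    last_exempt: int = 14,
) -> tuple[list[tuple[int, int]], list[str]]:
    """Block layout for scanning an exon that ends in a tandem donor pair.

    The first ``first_exempt`` and last ``last_exempt`` nucleotides are left
    untouched (the exon start and the region holding the upstream donor).
    Blocks 1..n-1 are ``block_len`` nt; the final block absorbs the remainder
    and receives the longer 19-nt heterologous sequence, the others the 15-nt
    one.
    """
    s = normalize_sequence(seq)
    region_len = len(s) - first_exempt - last_exempt
    if region_len < n_blocks * 1:
        raise ValueError("sequence too short for the requested block scheme")
    if (n_blocks - 1) * block_len >= region_len:
        raise ValueError("scannable region shorter than the fixed-length blocks")
    blocks = [
        (first_exempt + i * block_len, first_exempt + (i + 1) * block_len)
        for i in range(n_blocks - 1)
    ]
    blocks.append((first_exempt + (n_blocks - 1) * block_len, len(s) - last_exempt))
    replacements = [HETEROLOGOUS_15] * (n_blocks - 1) + [HETEROLOGOUS_19]
    return blocks, replacements


def load_esefinder_srsf1() -> ScoringMatrix:
    """The published ESEfinder SRSF1 (SF2/ASF) heptamer score matrix."""
    from . import io_formats

    ref = importlib.resources.files("tandem5ss.data") / "esefinder_srsf1.tsv"
    with importlib.resources.as_file(ref) as path:
        m = io_formats.read_matrix(path, kind="ese_pwm")
    m.name = "ESEfinder SRSF1"
    m.threshold = 1.956
    return m
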