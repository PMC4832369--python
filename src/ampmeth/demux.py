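"""Demultiplexing of dual-placement indexed reads.

The library design places a single sample index on either the forward or
the reverse adaptor, so a pool of k index oligos yields 2k distinguishable
sample assignments (480 indexes -> 960 combinations). The sample sheet
records, for every assignment, the index sequence, its adaptor placement
and the sample/replicate identity it encodes.

Index matching is Hamming-distance based with an ambiguity rule: a read is
assigned only if exactly one sheet entry attains the minimum distance and
that distance is within ``max_mismatch``; everything else is UNASSIGNED
(returned as ``None``) and counted, never dropped silently.

The physical location of the index is configurable because sequencer
layouts differ: by default the index is taken from the first
``index_length`` bases of the read; reverse-placement entries are instead
matched against a separate header/index read when one is provided.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pandas as pd

from ampmeth.errors import ValidationError

PLACEMENTS = ("forward", "reverse")

#: Sentinel key used in demux reports for reads that matched no index.
UNASSIGNED = "UNASSIGNED"

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class IndexAssignment:
    """One sample-sheet row: an index on one adaptor encodes one sample/replicate."""

    index_seq: str
    placement: str  # "forward" | "reverse"
    sample_id: str
    replicate_id: str

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValidationError(
                f"placement must be one of {PLACEMENTS}, got {self.placement!r}"
            )
        if not self.index_seq or set(self.index_seq) - _DNA:
            raise ValidationError(f"index_seq {self.index_seq!r} is not plain ACGT")

    @property
    def key(self) -> str:
        return f"{self.sample_id}/{self.replicate_id}"


@dataclass
class SampleSheet:
    """All index assignments for a run; all indexes share one length."""

    assignments: tuple[IndexAssignment, ...]
    index_length: int = 0

    def __post_init__(self) -> None:
        self.assignments = tuple(self.assignments)
        if not self.assignments:
            raise ValidationError("sample sheet has no assignments")
        lengths = {len(a.index_seq) for a in self.assignments}
        if len(lengths) != 1:
            raise ValidationError(f"index sequences have mixed lengths {sorted(lengths)}")
        inferred = lengths.pop()
        if self.index_length and self.index_length != inferred:
            raise ValidationError(
                f"index_length {self.index_length} != actual index length {inferred}"
            )
        self.index_length = inferred
        pairs = [(a.index_seq, a.placement) for a in self.assignments]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (index_seq, placement) pair in sample sheet")

    @classmethod
    def from_table(cls, source) -> "SampleSheet":
        """Build a sheet from delimited text with columns
        index_seq, placement, sample_id, replicate_id (TSV or CSV)."""
        if isinstance(source, pd.DataFrame):
            df = source
        else:
            df = pd.read_csv(source, sep=None, engine="python", dtype=str, comment="#")
        required = {"index_seq", "placement", "sample_id", "replicate_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing column(s) {sorted(missing)}")
        assignments = tuple(
            IndexAssignment(
                index_seq=str(r.index_seq).upper(),
                placement=str(r.placement).lower(),
                sample_id=str(r.sample_id),
                replicate_id=str(r.replicate_id),
            )
            for r in df.itertuples()
        )
        return cls(assignments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index_seq": [a.index_seq for a in self.assignments],
                "placement": [a.placement for a in self.assignments],
                "sample_id": [a.sample_id for a in self.assignments],
                "replicate_id": [a.replicate_id for a in self.assignments],
            }
        )


def enumerate_combinations(index_pool: Iterable[str]) -> int:
    """Number of distinct sample assignments an index pool supports.

    Each index oligo can be synthesized on the forward or the reverse
    adaptor, so the capacity is ``2 * |pool|``: the production pool of
    480 indexes yields 960 combinations.
    """
    pool = list(index_pool)
    if len(set(pool)) != len(pool):
        raise ValidationError("index pool contains duplicate sequences")
    return 2 * len(pool)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def assign_read(
    seq: str,
    sheet: SampleSheet,
    max_mismatch: int = 1,
    header_index: Optional[str] = None,
) -> Optional[IndexAssignment]:
    """Match one read to its sample-sheet entry, or ``None`` if UNASSIGNED.

    For each sheet entry the candidate index region is the read's first
    ``index_length`` bases, except for reverse-placement entries when a
    separate ``header_index`` is available. The unique entry at minimum
    Hamming distance <= ``max_mismatch`` wins; ties are UNASSIGNED.
    """
    length = sheet.index_length
    if len(seq) < length:
        return None
    prefix = seq[:length]
    best: list[IndexAssignment] = []
    best_d = max_mismatch + 1
    for entry in sheet.assignments:
        region = prefix
        if entry.placement == "reverse" and header_index is not None:
            if len(header_index) != length:
                continue
            region = header_index
        d = hamming(entry.index_seq, region)
        if d < best_d:
            best, best_d = [entry], d
        elif d == best_d:
            best.append(entry)
    if len(best) == 1 and best_d <= max_mismatch:
        return best[0]
    return None


def demultiplex(
    reads: Iterable[tuple],
    sheet: SampleSheet,
    max_mismatch: int = 1,
) -> Iterator[tuple[Optional[IndexAssignment], str, str, str]]:
    """Assign and index-trim a stream of reads.

    ``reads`` yields ``(read_id, seq, qual)`` or ``(read_id, seq, qual,
    header_index)`` tuples. Yields ``(assignment_or_None, read_id,
    trimmed_seq, trimmed_qual)``; the index region is trimmed from the
    read start whenever it was matched in-read (assigned reads only).
    """
    length = sheet.index_length
    for item in reads:
        read_id, seq, qual = item[0], item[1], item[2]
        header_index = item[3] if len(item) > 3 else None
        entry = assign_read(seq, sheet, max_mismatch=max_mismatch, header_index=header_index)
        if entry is None:
            yield None, read_id, seq, qual
            continue
        in_read = not (entry.placement == "reverse" and header_index is not None)
        if in_read:
            yield entry, read_id, seq[length:], qual[length:] if qual else qual
        else:
            yield entry, read_id, seq, qual


def demux_report(counts: Counter) -> pd.DataFrame:
    """Tabulate per-sample assigned read counts plus the unassigned total.

    ``counts`` maps ``sample_id/replicate_id`` keys (or :data:`UNASSIGNED`)
    to read counts, as accumulated by the pipeline.
    """
    unassigned = counts.get(UNASSIGNED, 0)
    rows = []
    for key in sorted(k for k in counts if k != UNASSIGNED):
        sample_id, _, replicate_id = key.partition("/")
        rows.append(
            {
                "sample_id": sample_id,
                "replicate_id": replicate_id,
                "reads_assigned": counts[key],
                "reads_unassigned": "",
            }
        )
    rows.append(
        {
            "sample_id": UNASSIGNED,
            "replicate_id": "",
            "reads_assigned": 0,
            "reads_unassigned": unassigned,
        }
    )
    return pd.DataFrame(rows)
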