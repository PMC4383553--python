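"""Shared containers and helpers for the retromod pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based inclusive (GFF3) happens only at file boundaries in
:mod:`retromod.io_formats`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

__version__ = "0.1.0"

logger = logging.getLogger("retromod")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Interval algebra (0-based half-open [start, end) tuples)
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list. Adjacent intervals fuse."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intersection of two disjoint sorted interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Positions in ``a`` not covered by ``b``; both disjoint and sorted."""
    out: list[Interval] = []
    b = merge_intervals(b)
    for s, e in merge_intervals(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_bp(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def canonicalize_deletions(deletions: list[Interval], sequence: str) -> list[Interval]:
    """Left-normalise deletion intervals against the sequence they delete from.

    A deletion ``[s, e)`` can slide one base left whenever
    ``sequence[s-1] == sequence[e-1]`` without changing the retained
    sequence (the same ambiguity VCF indel normalisation resolves). Each
    deletion is shifted maximally left; deletions that become adjacent are
    fused and shifted further. The result is a unique canonical
    representative of all deletion sets yielding the same derived sequence,
    used both when planting synthetic elements and when mapping elements
    back onto the consensus.
    """
    out: list[Interval] = []
    for s, e in merge_intervals(deletions):
        while True:
            bound = out[-1][1] if out else 0
            while s > bound and sequence[s - 1] == sequence[e - 1]:
                s -= 1
                e -= 1
            if out and s == out[-1][1]:
                s = out.pop()[0]
                continue
            break
        out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Genome containers
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    """A gene model: strand plus sorted non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        exs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: exons out of order or overlapping")
        self.exons = exs

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


# Canonical segment order of the full-length element consensus. The two LTR
# copies are identical in sequence and pooled under one "LTR" key when
# coverage fractions are computed.
SEGMENT_ORDER = ("LTR5", "seg2", "gag", "prt", "pol", "seg6", "RTE", "ppt", "LTR3")
SEGMENT_KEYS = ("LTR", "seg2", "gag", "prt", "pol", "seg6", "RTE", "ppt")


@dataclass
class ConsensusModel:
    """Full-length element consensus sequence plus its segment map.

    ``segments`` maps each name in :data:`SEGMENT_ORDER` to one interval;
    intervals are non-overlapping, ordered, and tile ``[0, len(sequence))``.
    """

    sequence: str
    segments: dict[str, Interval]

    def __post_init__(self) -> None:
        pos = 0
        for name in SEGMENT_ORDER:
            s, e = self.segments[name]
            if s != pos or e <= s:
                raise ValueError(f"consensus segments do not tile: {name} = [{s},{e}) at {pos}")
            pos = e
        if pos != len(self.sequence):
            raise ValueError("consensus segments do not cover the full sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def segment_intervals(self, key: str) -> list[Interval]:
        """Intervals for a pooled segment key ('LTR' covers both copies)."""
        if key == "LTR":
            return [self.segments["LTR5"], self.segments["LTR3"]]
        return [self.segments[key]]


@dataclass
class GenomeBundle:
    """Sequences plus gene annotation — the substrate for element scanning."""

    sequences: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    consensus: ConsensusModel | None = None

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]
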