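"""Consensus mapping, structural class calls, and the shared core across
suppressed elements.

Each element is globally aligned to the full-length consensus; the covered
consensus intervals give per-segment coverage fractions, the class decision
cascade assigns exactly one structural class, and the intersection of
covered intervals over a set of suppressed elements yields the minimal
shared sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

from .core import (
    ConsensusModel,
    Interval,
    SEGMENT_KEYS,
    canonicalize_deletions,
    intersect_intervals,
    merge_intervals,
    revcomp,
    subtract_intervals,
    total_bp,
)
from .synthetic_data import canonical_id1_interval

LENGTH_TOLERANCE = 50  # bp by which an element may exceed the consensus


@dataclass
class ConsensusMap:
    """Covered consensus intervals and per-segment coverage fractions."""

    element_id: str
    covered_intervals: list[Interval]
    segment_coverage: dict[str, float]
    edit_distance: int = 0


@dataclass
class ClassCall:
    element_id: str
    structural_class: str
    rationale: str


@dataclass
class ClassifyParams:
    """Thresholds of the class decision cascade.

    The canonical IΔ1 interval defaults to the package's synthetic
    convention (3' half of gag through prt) and must be overridden for real
    elements, whose subfamily breakpoints are an empirical matter.
    """

    full_length_min_bp: int = 7000
    full_length_min_coverage: float = 0.95
    solo_ltr_max_nonltr: float = 0.05
    id1_interval: Interval | None = None  # default: canonical_id1_interval(consensus)
    id1_tolerance_bp: int = 100
    dpol_max_pol_fraction: float = 0.5
    dpol_min_prt_fraction: float = 0.5


_ANCHOR = 32  # bp anchor for re-synchronising after a deletion

# Affine scoring for diverged elements: the gap-open cost is high enough
# that a deletion is never split by chance matches inside the deleted
# region (a split must gain > 20 consecutive matches to pay for itself).
_AFFINE = dict(match_score=1, mismatch_score=-3, open_gap_score=-20, extend_gap_score=-0.05)


def _pure_deletion_intervals(element: str, consensus: str) -> list[Interval] | None:
    """Deletion set of a deletion-only derivative, found by greedy anchored
    matching; returns None if the element is not reproduced exactly."""
    L, M = len(consensus), len(element)
    i = j = 0
    dels: list[Interval] = []
    while j < M and i < L:
        if consensus[i] == element[j]:
            i += 1
            j += 1
            continue
        anchor = element[j : j + _ANCHOR]
        nxt = consensus.find(anchor, i + 1)
        if nxt < 0:
            return None
        dels.append((i, nxt))
        i = nxt
    if j < M:
        return None
    if i < L:
        dels.append((i, L))
    rebuilt_len = L - sum(e - s for s, e in dels)
    if rebuilt_len != M:
        return None
    covered = subtract_intervals([(0, L)], dels)
    if "".join(consensus[s:e] for s, e in covered) != element:
        return None
    return dels


def _affine_covered(element: str, consensus: str) -> list[Interval]:
    aligner = Align.PairwiseAligner(mode="global", **_AFFINE)
    aln = aligner.align(consensus, element)[0]
    return merge_intervals([(int(s), int(e)) for s, e in aln.aligned[0]])


def map_to_consensus(
    element_seq: str, consensus: ConsensusModel, element_id: str = ""
) -> ConsensusMap:
    """Align an element to the consensus and report per-segment coverage.

    Both orientations are tried (by edit distance) and the better one kept,
    so genomic-strand sequences can be passed directly. Deletion-only
    derivatives are mapped exactly by anchored matching; diverged elements
    fall back to a global alignment with affine gaps. In either case gap
    placement is canonicalised by maximal left-shift (every optimal
    alignment of a deletion derivative differs only by slides of deletions
    across repeated context, so the left-normal form is unique and matches
    the canonical form recorded by the synthetic generator).
    """
    if not element_seq or not consensus.sequence:
        raise ValueError("element and consensus must be non-empty")
    if len(element_seq) > consensus.length + LENGTH_TOLERANCE:
        raise ValueError(
            f"{element_id or 'element'}: length {len(element_seq)} exceeds consensus "
            f"{consensus.length} + {LENGTH_TOLERANCE} bp; not a simple deletion derivative"
        )
    d_fwd = edlib.align(element_seq, consensus.sequence, mode="NW", task="distance")["editDistance"]
    d_rev = edlib.align(revcomp(element_seq), consensus.sequence, mode="NW", task="distance")["editDistance"]
    # prefer the given orientation on ties: short elements embed as scattered
    # subsequences either way, making the unit-cost distance orientation-blind
    dist, seq = (d_fwd, element_seq) if d_fwd <= d_rev else (d_rev, revcomp(element_seq))
    covered = None
    if dist == consensus.length - len(seq):
        dels = _pure_deletion_intervals(seq, consensus.sequence)
        if dels is not None:
            covered = subtract_intervals([(0, consensus.length)], dels)
            pure = True
    if covered is None:
        covered = _affine_covered(seq, consensus.sequence)
        pure = total_bp(covered) == len(seq) and "".join(
            consensus.sequence[s:e] for s, e in covered
        ) == seq
    if pure:
        gaps = canonicalize_deletions(
            subtract_intervals([(0, consensus.length)], covered), consensus.sequence
        )
        covered = subtract_intervals([(0, consensus.length)], gaps)
    coverage = {
        key: (
            total_bp(intersect_intervals(covered, consensus.segment_intervals(key)))
            / total_bp(consensus.segment_intervals(key))
        )
        for key in SEGMENT_KEYS
    }
    return ConsensusMap(element_id, covered, coverage, int(dist))


def classify(
    cmap: ConsensusMap,
    element_length: int,
    consensus: ConsensusModel,
    params: ClassifyParams | None = None,
) -> ClassCall:
    """Assign one structural class by a fixed decision cascade:
    solo LTR → full length → IΔ1 → Δpol → other."""
    p = params or ClassifyParams()
    cov = cmap.segment_coverage

    non_ltr = [k for k in SEGMENT_KEYS if k != "LTR"]
    non_ltr_bp = sum(
        cov[k] * total_bp(consensus.segment_intervals(k)) for k in non_ltr
    )
    non_ltr_total = sum(total_bp(consensus.segment_intervals(k)) for k in non_ltr)
    if non_ltr_bp / non_ltr_total < p.solo_ltr_max_nonltr and cov["LTR"] > 0:
        return ClassCall(cmap.element_id, "solo_LTR",
                         f"non-LTR coverage {non_ltr_bp / non_ltr_total:.3f} < {p.solo_ltr_max_nonltr}")

    if element_length > p.full_length_min_bp and all(
        cov[k] >= p.full_length_min_coverage for k in SEGMENT_KEYS
    ):
        return ClassCall(cmap.element_id, "full_length",
                         f"length {element_length} > {p.full_length_min_bp} and all segments covered")

    deletions = subtract_intervals([(0, consensus.length)], cmap.covered_intervals)
    canon = p.id1_interval or canonical_id1_interval(consensus)
    canon = canonicalize_deletions([canon], consensus.sequence)[0]
    if len(deletions) == 1:
        (ds, de) = deletions[0]
        if abs(ds - canon[0]) <= p.id1_tolerance_bp and abs(de - canon[1]) <= p.id1_tolerance_bp:
            return ClassCall(cmap.element_id, "ID1",
                             f"single deletion [{ds},{de}) matches canonical IΔ1 within "
                             f"{p.id1_tolerance_bp} bp")

    if cov["pol"] <= p.dpol_max_pol_fraction and cov["prt"] > p.dpol_min_prt_fraction:
        return ClassCall(cmap.element_id, "Dpol",
                         f"pol coverage {cov['pol']:.2f} <= {p.dpol_max_pol_fraction}, "
                         f"prt coverage {cov['prt']:.2f} > {p.dpol_min_prt_fraction}")

    return ClassCall(cmap.element_id, "other", "no named class matched")


def shared_core(maps: list[ConsensusMap]) -> list[Interval]:
    """Consensus positions covered by every element, as disjoint sorted
    intervals. Associative and commutative; total bp is non-increasing as
    maps are added."""
    if not maps:
        raise ValueError("shared_core requires at least one map (>= 2 to be meaningful)")
    core = merge_intervals(maps[0].covered_intervals)
    for m in maps[1:]:
        core = intersect_intervals(core, merge_intervals(m.covered_intervals))
    return core
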