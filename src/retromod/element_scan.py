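"""Element discovery: seed scanning, hit merging, host-intron assignment,
curation, and the orientation/size-bias statistics.

The scanner reports every fixed-length window on either strand within a
Hamming-distance budget of any seed; it is an exact (ungapped) scan, not an
aligner. Hit coordinates are always on the forward reference strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core import GenomeBundle, Interval, logger, revcomp
from .io_formats import RepeatRecord

DEFAULT_MAX_GAP = 2000
DEFAULT_SIZE_THRESHOLD = 1000
DEFAULT_RECIPROCAL_OVERLAP = 0.5


@dataclass(frozen=True)
class SeedHit:
    """One seed match on the forward reference."""

    seed_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class IapElement:
    """A candidate element: merged seed hits and/or a repeat-table record."""

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    source: str  # seed_scan | repeat_table | both
    host_gene: str | None = None
    host_intron: int | None = None
    orientation: str | None = None  # sense | antisense | intergenic
    curation_flag: str = "pass"

    @property
    def length(self) -> int:
        return self.end - self.start


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def scan_seeds(
    sequences: dict[str, str], seeds: dict[str, str], max_mismatch: int = 0
) -> list[SeedHit]:
    """Hamming-distance scan of every seed against both strands.

    Equivalent to the naive all-window scan: every window whose distance to a
    seed (or its reverse complement) is ≤ ``max_mismatch`` is reported, with
    coordinates on the forward strand. Seeds must be non-empty A/C/G/T.
    """
    if not seeds:
        raise ValueError("seed panel is empty")
    for sid, s in seeds.items():
        if not s or any(b not in _BASE_CODE for b in s):
            raise ValueError(f"seed {sid!r} contains non-ACGT characters or is empty")
        if max_mismatch >= len(s) / 2:
            raise ValueError(f"max_mismatch {max_mismatch} too large for seed {sid!r}")

    hits: list[SeedHit] = []
    for chrom, seq in sequences.items():
        genome = _encode(seq)
        for sid, s in seeds.items():
            k = len(s)
            if len(seq) < k:
                continue
            for strand, probe in (("+", s), ("-", revcomp(s))):
                pat = _encode(probe)
                mism = np.zeros(len(seq) - k + 1, dtype=np.int32)
                for j in range(k):
                    mism += genome[j : len(seq) - k + 1 + j] != pat[j]
                for pos in np.flatnonzero(mism <= max_mismatch):
                    hits.append(SeedHit(sid, chrom, int(pos), int(pos) + k, strand, int(mism[pos])))
    hits.sort(key=lambda h: (h.chrom, h.start, h.end, h.strand, h.seed_id))
    return hits


def merge_hits(hits: list[SeedHit], max_gap: int = DEFAULT_MAX_GAP) -> list[IapElement]:
    """Chain same-chromosome, same-strand hits whose gaps are ≤ ``max_gap``
    into elements spanning min start to max end. Strands never mix."""
    elements: list[IapElement] = []
    by_group: dict[tuple[str, str], list[SeedHit]] = {}
    for h in hits:
        by_group.setdefault((h.chrom, h.strand), []).append(h)
    n = 0
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda h: (h.start, h.end))
        cur_start, cur_end = group[0].start, group[0].end
        for h in group[1:]:
            if h.start - cur_end <= max_gap:
                cur_end = max(cur_end, h.end)
            else:
                n += 1
                elements.append(IapElement(f"E{n:04d}", chrom, cur_start, cur_end, strand, "seed_scan"))
                cur_start, cur_end = h.start, h.end
        n += 1
        elements.append(IapElement(f"E{n:04d}", chrom, cur_start, cur_end, strand, "seed_scan"))
    elements.sort(key=lambda e: (e.chrom, e.start))
    return [replace(e, element_id=f"E{i + 1:04d}") for i, e in enumerate(elements)]


def elements_from_repeats(records: list[RepeatRecord]) -> list[IapElement]:
    """Lift repeat-annotation rows into candidate elements."""
    return [
        IapElement(f"R{i + 1:04d}", r.chrom, r.start, r.end, r.strand, "repeat_table")
        for i, r in enumerate(sorted(records, key=lambda r: (r.chrom, r.start)))
    ]


def merge_censuses(
    seed_elements: list[IapElement],
    repeat_elements: list[IapElement],
    min_reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
) -> list[IapElement]:
    """Deduplicate the two censuses into a superset.

    Same-strand elements with ≥ ``min_reciprocal_overlap`` reciprocal overlap
    collapse to their union interval with source "both"; everything else
    passes through.
    """
    out: list[IapElement] = []
    used: set[int] = set()
    for e in seed_elements:
        merged = e
        for j, r in enumerate(repeat_elements):
            if j in used or r.chrom != e.chrom or r.strand != e.strand:
                continue
            ov = min(e.end, r.end) - max(e.start, r.start)
            if ov > 0 and ov >= min_reciprocal_overlap * e.length and ov >= min_reciprocal_overlap * r.length:
                merged = replace(
                    e, start=min(e.start, r.start), end=max(e.end, r.end), source="both"
                )
                used.add(j)
                break
        out.append(merged)
    out.extend(r for j, r in enumerate(repeat_elements) if j not in used)
    out.sort(key=lambda e: (e.chrom, e.start))
    return [replace(e, element_id=f"E{i + 1:04d}") for i, e in enumerate(out)]


def assign_host(elements: list[IapElement], annotation: GenomeBundle) -> list[IapElement]:
    """Assign host gene/intron and relative orientation.

    An element fully contained in an intron is sense or antisense by strand
    comparison with the host gene; overlap with any exon flags it
    ``non_intronic``; elements outside genes are ``intergenic``.
    """
    out = []
    for e in elements:
        host_gene = host_intron = None
        orientation = "intergenic"
        flag = e.curation_flag
        for gene in annotation.genes_on(e.chrom):
            if any(e.start < xe and xs < e.end for xs, xe in gene.exons):
                flag = "non_intronic"
                orientation = "intergenic"
                host_gene = host_intron = None
                break
            for idx, (istart, iend) in enumerate(gene.introns):
                if istart <= e.start and e.end <= iend:
                    host_gene, host_intron = gene.gene_id, idx
                    orientation = "sense" if e.strand == gene.strand else "antisense"
                    break
            if host_gene is not None:
                break
        out.append(
            replace(e, host_gene=host_gene, host_intron=host_intron,
                    orientation=orientation, curation_flag=flag)
        )
    return out


def curate(
    elements: list[IapElement],
    duplicate_gene_pairs: list[tuple[str, str]] | None = None,
    annotation: GenomeBundle | None = None,
) -> list[IapElement]:
    """Rule-based curation: drop non-intronic elements and flag/drop elements
    lying between annotated duplicate gene copies (likely tandem-duplication
    annotation artifacts). Every removal is logged with its rule; everything
    else passes through unchanged."""
    spans = {g.gene_id: (g.chrom, g.start, g.end) for g in annotation.genes} if annotation else {}
    kept: list[IapElement] = []
    for e in elements:
        if e.curation_flag == "non_intronic":
            logger.info("curate: removed %s (rule: non_intronic)", e.element_id)
            continue
        if e.host_gene is None and duplicate_gene_pairs and spans:
            dup = next(
                (
                    (ga, gb)
                    for ga, gb in duplicate_gene_pairs
                    if _between_spans(e, spans.get(ga), spans.get(gb))
                ),
                None,
            )
            if dup is not None:
                logger.info(
                    "curate: removed %s (rule: duplication_artifact %s/%s)", e.element_id, *dup
                )
                continue
        kept.append(e)
    return kept


def _between_spans(e: IapElement, a, b) -> bool:
    if a is None or b is None or a[0] != e.chrom or b[0] != e.chrom:
        return False
    left, right = (a, b) if a[1] <= b[1] else (b, a)
    return left[2] <= e.start and e.end <= right[1]


# ---------------------------------------------------------------------------
# Orientation / size bias
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientationBias:
    """2x2 census of orientation x size with its exact test."""

    table: tuple[tuple[int, int], tuple[int, int]]  # rows sense/antisense, cols <=thr / >thr
    size_threshold: int
    odds_ratio: float
    p_value: float | None


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p by hypergeometric enumeration (the
    minimum-likelihood definition: sum of all tables whose point probability
    does not exceed the observed one)."""
    arr = np.asarray(table)
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("Fisher's exact p is undefined for an empty margin")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def orientation_bias_test(
    elements: list[IapElement], size_threshold: int = DEFAULT_SIZE_THRESHOLD
) -> OrientationBias:
    """Test whether sense elements are enriched for short (≤ threshold)
    insertions relative to antisense elements."""
    if size_threshold <= 0:
        raise ValueError("size_threshold must be positive")
    counts = {("sense", True): 0, ("sense", False): 0, ("antisense", True): 0, ("antisense", False): 0}
    for e in elements:
        if e.orientation in ("sense", "antisense"):
            counts[(e.orientation, e.length <= size_threshold)] += 1
    table = (
        (counts[("sense", True)], counts[("sense", False)]),
        (counts[("antisense", True)], counts[("antisense", False)]),
    )
    arr = np.asarray(table)
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        logger.warning("orientation_bias_test: empty margin, p undefined")
        return OrientationBias(table, size_threshold, float("nan"), None)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return OrientationBias(table, size_threshold, float(odds), float(p))
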