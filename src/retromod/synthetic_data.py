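"""Synthetic genomes, planted retroelement insertions, and simulated
measurements with full ground truth.

The generator emulates the study conditions of a congenic suppression
screen: a toy genome with multi-exon genes on both strands, sense and
antisense intronic insertions of a long-terminal-repeat (LTR) retroelement
drawn from the structural classes {solo LTR, IΔ1, Δpol, full-length, other},
qPCR quantification-cycle (Cq) tables with planted uninserted/inserted
expression effects (up to ~1000-fold) and genotype-dependent suppression
effects (~1.1–7.8-fold), and splicing-array inclusion/exclusion intensities
with planted separation scores. Every simulated measurement traces back to
exactly one truth record.

Noise model: Gaussian on the Cq (log) scale, i.e. lognormal on quantities,
matching qPCR practice. Per-assay baseline Cq values are drawn in [18, 28].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConsensusModel,
    Gene,
    GenomeBundle,
    Interval,
    SEGMENT_ORDER,
    canonicalize_deletions,
    merge_intervals,
    revcomp,
    subtract_intervals,
    total_bp,
)

STRUCTURAL_CLASSES = ("solo_LTR", "ID1", "Dpol", "full_length", "other")

# Segment lengths of the 7.5 kb reference consensus; other consensus lengths
# scale these proportionally. The 3' LTR is an exact copy of the 5' LTR.
_CANONICAL_SEGMENT_BP = {
    "LTR5": 350,
    "seg2": 400,
    "gag": 2000,
    "prt": 900,
    "pol": 2900,
    "seg6": 300,
    "RTE": 200,
    "ppt": 100,
    "LTR3": 350,
}

SEED_LENGTH = 35


@dataclass
class InsertionSpec:
    """One planned intronic element insertion.

    ``deleted_consensus_intervals`` are [start, end) on the consensus;
    ``u_over_i_effect`` is the uninserted/inserted expression fold change and
    ``c_over_b_effect`` the suppressed/unsuppressed genotype fold change,
    both ≥ 1.
    """

    element_id: str
    host_gene: str
    intron_index: int
    offset_in_intron: int
    strand_relative: str  # sense | antisense
    structural_class: str
    deleted_consensus_intervals: list[Interval] = field(default_factory=list)
    u_over_i_effect: float = 1.0
    c_over_b_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.strand_relative not in ("sense", "antisense"):
            raise ValueError(f"{self.element_id}: strand_relative must be sense or antisense")
        if self.structural_class not in STRUCTURAL_CLASSES:
            raise ValueError(f"{self.element_id}: unknown structural class {self.structural_class!r}")
        if self.u_over_i_effect < 1 or self.c_over_b_effect < 1:
            raise ValueError(f"{self.element_id}: effects must be >= 1")
        ivs = sorted(self.deleted_consensus_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.element_id}: deleted intervals overlap")
        if any(s < 0 or s >= e for s, e in ivs):
            raise ValueError(f"{self.element_id}: invalid deleted interval")
        if self.structural_class == "full_length" and ivs:
            raise ValueError(f"{self.element_id}: full_length elements carry no deletions")
        self.deleted_consensus_intervals = ivs


@dataclass
class MeasurementDesign:
    """Sampling design for the simulated qPCR experiment.

    ``n_pairs`` littermate pairs drive the paired genotype (C/B) contrast;
    ``n_per_strain`` animals per strain drive the unpaired strain (U/I)
    contrast; ``efficiency`` is the per-cycle amplification factor.
    """

    n_pairs: int = 10
    n_per_strain: int = 5
    n_tech_reps: int = 3
    cq_noise_sd: float = 0.4
    efficiency: float = 2.0
    reference_assays: tuple[str, ...] = ("Gapdh", "Sdha", "Ppia")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        if not (1 < self.efficiency <= 2):
            raise ValueError("efficiency must be in (1, 2]")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a synthetic run: planted insertions, planted
    per-sample log2 expression, and planted array separation scores."""

    insertion_specs: list[InsertionSpec]
    planted: pd.DataFrame  # element_id, chrom, start, end, strand, ...
    expression: pd.DataFrame | None = None  # sample_id, assay_id, log2_expression
    array_scores: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Consensus and genome generation
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def build_consensus(length: int = 7500, seed: int = 0) -> ConsensusModel:
    """Random full-length consensus with the canonical segment map.

    ``length`` must be at least 7001 so that full-length derivatives exceed
    the >7 kb class threshold. The 3' LTR is an exact copy of the 5' LTR, as
    in a freshly integrated provirus.
    """
    if length < 7001:
        raise ValueError("consensus length must be >= 7001 bp")
    base = sum(_CANONICAL_SEGMENT_BP.values())
    sizes = {k: max(20, round(v * length / base)) for k, v in _CANONICAL_SEGMENT_BP.items()}
    sizes["LTR3"] = sizes["LTR5"]
    sizes["ppt"] += length - sum(sizes.values())  # absorb rounding remainder
    if sizes["ppt"] < 20:
        raise ValueError("consensus length leaves no room for the ppt segment")
    segments: dict[str, Interval] = {}
    pos = 0
    for name in SEGMENT_ORDER:
        segments[name] = (pos, pos + sizes[name])
        pos += sizes[name]
    rng = np.random.default_rng(seed)
    internal = _random_dna(rng, length - 2 * sizes["LTR5"])
    ltr = _random_dna(rng, sizes["LTR5"])
    return ConsensusModel(ltr + internal + ltr, segments)


def generate_genome(
    n_genes: int,
    intron_length_range: tuple[int, int] = (1500, 4000),
    consensus_length: int = 7500,
    seed: int = 0,
    n_exons_range: tuple[int, int] = (3, 5),
    exon_length_range: tuple[int, int] = (100, 300),
    intergenic_gap_range: tuple[int, int] = (2500, 6000),
    chrom_name: str = "chr1",
) -> GenomeBundle:
    """Random genome with ``n_genes`` multi-exon genes on both strands and a
    packaged full-length element consensus.

    Deterministic given ``seed``. Raises on impossible geometry (introns too
    short to host an insertion point with flanks).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = intron_length_range
    if lo <= 0 or hi < lo:
        raise ValueError("intron_length_range must be positive and ordered")
    if lo < 2 * SEED_LENGTH:
        raise ValueError(
            "impossible geometry: minimum intron length "
            f"{lo} bp is smaller than the minimum plantable element footprint "
            f"({2 * SEED_LENGTH} bp of intronic flank)"
        )
    rng = np.random.default_rng(seed)
    consensus = build_consensus(consensus_length, seed=int(rng.integers(0, 2**31 - 1)))

    genes: list[Gene] = []
    cursor = int(rng.integers(*intergenic_gap_range))
    for i in range(n_genes):
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[Interval] = []
        pos = cursor
        for j in range(n_exons):
            ex_len = int(rng.integers(exon_length_range[0], exon_length_range[1] + 1))
            exons.append((pos, pos + ex_len))
            pos += ex_len
            if j < n_exons - 1:
                pos += int(rng.integers(lo, hi + 1))
        genes.append(Gene(f"gene{i + 1:03d}", chrom_name, strand, exons))
        cursor = pos + int(rng.integers(*intergenic_gap_range))
    sequence = _random_dna(rng, cursor)
    return GenomeBundle({chrom_name: sequence}, genes, consensus)


# ---------------------------------------------------------------------------
# Planting insertions
# ---------------------------------------------------------------------------


def element_sequence(spec: InsertionSpec, consensus: ConsensusModel) -> tuple[str, list[Interval]]:
    """Element sequence in consensus orientation plus the canonical deletion
    set actually planted (left-normalised against the consensus)."""
    L = consensus.length
    if any(e > L for _, e in spec.deleted_consensus_intervals):
        raise ValueError(f"{spec.element_id}: deleted interval beyond consensus length")
    dels = canonicalize_deletions(spec.deleted_consensus_intervals, consensus.sequence)
    retained = subtract_intervals([(0, L)], dels)
    if spec.structural_class == "full_length" and L <= 7000:
        raise ValueError(f"{spec.element_id}: full_length requires consensus > 7000 bp")
    if spec.structural_class == "solo_LTR":
        non_ltr: list[Interval] = []
        for key in ("seg2", "gag", "prt", "pol", "seg6", "RTE", "ppt"):
            non_ltr.append(consensus.segments[key])
        from .core import intersect_intervals

        if total_bp(intersect_intervals(retained, merge_intervals(non_ltr))) > 0:
            raise ValueError(f"{spec.element_id}: solo_LTR must retain only LTR sequence")
    seq = "".join(consensus.sequence[s:e] for s, e in retained)
    return seq, dels


def plant_insertions(
    genome: GenomeBundle, specs: list[InsertionSpec], seed: int = 0
) -> tuple[GenomeBundle, TruthTable]:
    """Insert elements into host introns, shifting downstream annotation.

    Sense insertions go on the host gene's strand, antisense on the opposite
    strand (antisense elements are reverse-complemented whole). The returned
    truth table records the exact planted interval of every element in the
    mutated genome. ``seed`` is accepted for interface symmetry; planting
    itself is fully determined by the specs.
    """
    del seed  # planting has no randomness of its own
    if genome.consensus is None:
        raise ValueError("genome bundle has no packaged consensus")
    genes = {g.gene_id: g for g in genome.genes}

    plans = []  # (chrom, insert_pos_in_original_coords, spec, seq, strand, dels)
    seen: set[tuple[str, int, int]] = set()
    for spec in specs:
        gene = genes.get(spec.host_gene)
        if gene is None:
            raise ValueError(f"{spec.element_id}: host gene {spec.host_gene!r} not in annotation")
        introns = gene.introns
        if not 0 <= spec.intron_index < len(introns):
            raise ValueError(f"{spec.element_id}: intron {spec.intron_index} does not exist")
        istart, iend = introns[spec.intron_index]
        if not SEED_LENGTH <= spec.offset_in_intron <= (iend - istart) - SEED_LENGTH:
            raise ValueError(
                f"{spec.element_id}: offset {spec.offset_in_intron} leaves less than "
                f"{SEED_LENGTH} bp of intronic flank in a {iend - istart} bp intron"
            )
        key = (spec.host_gene, spec.intron_index, spec.offset_in_intron)
        if key in seen:
            raise ValueError(
                f"{spec.element_id}: overlapping insertions in one intron of {spec.host_gene}"
            )
        seen.add(key)
        seq, dels = element_sequence(spec, genome.consensus)
        strand = gene.strand if spec.strand_relative == "sense" else ("-" if gene.strand == "+" else "+")
        plans.append((gene.chrom, istart + spec.offset_in_intron, spec, seq, strand, dels))

    plans.sort(key=lambda p: (p[0], p[1]))

    new_sequences = dict(genome.sequences)
    rows = []
    for chrom in genome.sequences:
        chrom_plans = [p for p in plans if p[0] == chrom]
        pieces, prev, shift = [], 0, 0
        for _, pos, spec, seq, strand, dels in chrom_plans:
            pieces.append(genome.sequences[chrom][prev:pos])
            pieces.append(seq if strand == "+" else revcomp(seq))
            start = pos + shift
            rows.append(
                {
                    "element_id": spec.element_id,
                    "chrom": chrom,
                    "start": start,
                    "end": start + len(seq),
                    "strand": strand,
                    "host_gene": spec.host_gene,
                    "intron_index": spec.intron_index,
                    "strand_relative": spec.strand_relative,
                    "structural_class": spec.structural_class,
                    "length": len(seq),
                    "canonical_deletions": json.dumps(dels),
                    "u_over_i_effect": spec.u_over_i_effect,
                    "c_over_b_effect": spec.c_over_b_effect,
                }
            )
            prev = pos
            shift += len(seq)
        pieces.append(genome.sequences[chrom][prev:])
        new_sequences[chrom] = "".join(pieces)

    # shift gene annotation past each insertion point
    inserts_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, _, seq, _, _ in plans:
        inserts_by_chrom.setdefault(chrom, []).append((pos, len(seq)))

    def shifted(chrom: str, coord: int) -> int:
        return coord + sum(ln for p, ln in inserts_by_chrom.get(chrom, []) if p <= coord)

    new_genes = [
        Gene(g.gene_id, g.chrom, g.strand, [(shifted(g.chrom, s), shifted(g.chrom, e)) for s, e in g.exons])
        for g in genome.genes
    ]
    planted = pd.DataFrame(
        rows,
        columns=[
            "element_id", "chrom", "start", "end", "strand", "host_gene", "intron_index",
            "strand_relative", "structural_class", "length", "canonical_deletions",
            "u_over_i_effect", "c_over_b_effect",
        ],
    )
    bundle = GenomeBundle(new_sequences, new_genes, genome.consensus)
    return bundle, TruthTable(list(specs), planted)


def class_spec(
    structural_class: str,
    consensus: ConsensusModel,
    element_id: str,
    host_gene: str,
    intron_index: int = 0,
    offset_in_intron: int = 200,
    strand_relative: str = "sense",
    u_over_i_effect: float = 1.0,
    c_over_b_effect: float = 1.0,
) -> InsertionSpec:
    """Class-conforming :class:`InsertionSpec` for the given consensus.

    The IΔ1 deletion spans the 3' half of gag through prt (the package's
    canonical interval); Δpol removes 60% of pol; "other" removes 60% of gag,
    which matches no named class.
    """
    seg = consensus.segments
    if structural_class == "full_length":
        dels: list[Interval] = []
    elif structural_class == "solo_LTR":
        dels = [(seg["LTR5"][1], consensus.length)]
    elif structural_class == "ID1":
        dels = [canonical_id1_interval(consensus)]
    elif structural_class == "Dpol":
        ps, pe = seg["pol"]
        dels = [(ps, ps + int(0.6 * (pe - ps)))]
    elif structural_class == "other":
        gs, ge = seg["gag"]
        dels = [(gs, gs + int(0.6 * (ge - gs)))]
    else:
        raise ValueError(f"unknown structural class {structural_class!r}")
    return InsertionSpec(
        element_id, host_gene, intron_index, offset_in_intron, strand_relative,
        structural_class, dels, u_over_i_effect, c_over_b_effect,
    )


def canonical_id1_interval(consensus: ConsensusModel) -> Interval:
    """Default canonical IΔ1 deletion: 3' half of gag through the end of prt."""
    gs, ge = consensus.segments["gag"]
    return (gs + (ge - gs) // 2, consensus.segments["prt"][1])


def design_seed_panel(consensus: ConsensusModel, step: int = 250) -> dict[str, str]:
    """35-bp seed panel tiling the consensus, emulating a panel of
    subfamily-conserved search sequences.

    Seeds are placed every ``step`` bp plus flush against every segment
    boundary and the canonical IΔ1 deletion edges, so that derivative
    elements of every structural class retain seeds at both of their exact
    ends.
    """
    L = consensus.length
    starts = set(range(0, L - SEED_LENGTH + 1, step))
    boundaries = {0, L}
    for s, e in consensus.segments.values():
        boundaries.update((s, e))
    boundaries.update(canonical_id1_interval(consensus))
    for b in boundaries:
        if b + SEED_LENGTH <= L:
            starts.add(b)
        if b - SEED_LENGTH >= 0:
            starts.add(b - SEED_LENGTH)
    return {
        f"seed{p:05d}": consensus.sequence[p : p + SEED_LENGTH] for p in sorted(starts)
    }


# ---------------------------------------------------------------------------
# Simulated measurements
# ---------------------------------------------------------------------------


def _sample_frame(design: MeasurementDesign) -> pd.DataFrame:
    rows = []
    for i in range(1, design.n_per_strain + 1):
        rows.append((f"U{i}", "uninserted", "B", ""))
        rows.append((f"I{i}", "inserted", "B", ""))
    for p in range(1, design.n_pairs + 1):
        rows.append((f"P{p}B", "inserted", "B", f"P{p}"))
        rows.append((f"P{p}C", "inserted", "C", f"P{p}"))
    return pd.DataFrame(rows, columns=["sample_id", "strain", "genotype", "pair_id"])


def simulate_expression(truth: TruthTable, design: MeasurementDesign) -> pd.DataFrame:
    """Simulate a replicate-level Cq table for every planted insertion assay
    plus the reference assays.

    Per sample and assay the planted log2 quantity is baseline, minus
    log2(U/I effect) in inserted-strain samples, plus log2(C/B effect) in
    suppressed-genotype samples; reference assays are flat. A per-sample
    loading offset affects all assays equally (removed by reference
    normalization). Cq = baseline_cq − log_eff(quantity) + N(0, sd) per
    technical replicate. Deterministic given ``design.seed``; the planted
    noiseless quantities are stored on ``truth.expression``.
    """
    rng = np.random.default_rng(design.seed)
    samples = _sample_frame(design)
    target_assays = list(truth.planted["host_gene"])
    if len(set(target_assays)) != len(target_assays):
        raise ValueError("each insertion needs a distinct host gene for its assay")
    assays = target_assays + list(design.reference_assays)
    effects = {
        r.host_gene: (np.log2(r.u_over_i_effect), np.log2(r.c_over_b_effect))
        for r in truth.planted.itertuples()
    }

    baseline_cq = {a: rng.uniform(18.0, 28.0) for a in assays}
    loading = {s: rng.normal(0.0, 0.5) for s in samples["sample_id"]}
    log_eff = np.log2(design.efficiency)

    truth_rows, cq_rows = [], []
    for srow in samples.itertuples():
        for assay in assays:
            expr = 5.0
            if assay in effects:
                d_ui, d_cb = effects[assay]
                if srow.strain == "inserted":
                    expr -= d_ui
                if srow.genotype == "C":
                    expr += d_cb
            total = expr + loading[srow.sample_id]
            truth_rows.append((srow.sample_id, assay, expr))
            noise = rng.normal(0.0, design.cq_noise_sd, design.n_tech_reps)
            for rep in range(1, design.n_tech_reps + 1):
                cq = baseline_cq[assay] - total / log_eff + noise[rep - 1]
                cq_rows.append(
                    (srow.sample_id, assay, rep, cq, srow.strain, srow.genotype, srow.pair_id)
                )
    truth.expression = pd.DataFrame(
        truth_rows, columns=["sample_id", "assay_id", "log2_expression"]
    )
    return pd.DataFrame(
        cq_rows,
        columns=["sample_id", "assay_id", "replicate", "cq", "strain", "genotype", "pair_id"],
    )


def simulate_array(
    truth: TruthTable, n_pairs: int = 3, intensity_noise_cv: float = 0.2, seed: int = 0
) -> pd.DataFrame:
    """Simulate inclusion/exclusion intensities realizing the planted
    separation scores in expectation.

    Genotype C samples have their inclusion/exclusion ratio multiplied by
    2**score (split symmetrically between the two intensities); multiplicative
    lognormal noise with the given coefficient of variation is applied to
    every intensity. Deterministic given ``seed``.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if not truth.array_scores:
        raise ValueError("truth table has no planted array separation scores")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(intensity_noise_cv**2)))
    rows = []
    for event_id, score in truth.array_scores.items():
        base_incl = 2.0 ** rng.uniform(6, 12)
        base_excl = 2.0 ** rng.uniform(6, 12)
        for p in range(1, n_pairs + 1):
            for genotype in ("B", "C"):
                tilt = 2.0 ** (score / 2) if genotype == "C" else 1.0
                noise_i = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                noise_x = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                rows.append(
                    (
                        event_id,
                        f"P{p}{genotype}",
                        f"P{p}",
                        genotype,
                        base_incl * tilt * noise_i,
                        base_excl / tilt * noise_x,
                    )
                )
    return pd.DataFrame(
        rows, columns=["event_id", "sample_id", "pair_id", "genotype", "inclusion", "exclusion"]
    )
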