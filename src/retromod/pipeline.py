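"""End-to-end orchestration: simulate → scan → classify → quantify → screen
→ report, as a single reproducible run.

A run is driven by one :class:`RunConfig` (loadable from YAML, seed
mandatory); every output table carries the config hash, stage logging
reports record counts in and out, and identical config + seed yields a
byte-identical JSON summary.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import element_classify as ec
from . import element_scan as es
from . import expression_stats as xs
from . import io_formats as iof
from . import splice_screen as ss
from . import synthetic_data as sd
from .core import __version__, config_hash, logger, revcomp, total_bp

# Default planted scenario: sense insertions of every structural class with
# effect sizes inside the observed 1.2–1000 (U/I) and 1.1–7.8 (C/B) ranges,
# plus antisense insertions that should show no suppression.
DEFAULT_INSERTIONS: list[dict] = [
    dict(element_id="ins01", host_gene="gene001", structural_class="full_length",
         strand_relative="sense", u_over_i_effect=50.0, c_over_b_effect=2.5),
    dict(element_id="ins02", host_gene="gene002", structural_class="ID1",
         strand_relative="sense", u_over_i_effect=8.0, c_over_b_effect=2.0),
    dict(element_id="ins03", host_gene="gene003", structural_class="Dpol",
         strand_relative="sense", u_over_i_effect=3.0, c_over_b_effect=1.0),
    dict(element_id="ins04", host_gene="gene004", structural_class="solo_LTR",
         strand_relative="sense", u_over_i_effect=1.0, c_over_b_effect=1.0),
    dict(element_id="ins05", host_gene="gene005", structural_class="other",
         strand_relative="sense", u_over_i_effect=5.0, c_over_b_effect=1.8),
    dict(element_id="ins06", host_gene="gene006", structural_class="full_length",
         strand_relative="sense", u_over_i_effect=1000.0, c_over_b_effect=3.0),
    dict(element_id="ins07", host_gene="gene007", structural_class="ID1",
         strand_relative="sense", u_over_i_effect=1.5, c_over_b_effect=1.2),
    dict(element_id="ins08", host_gene="gene008", structural_class="full_length",
         strand_relative="antisense", u_over_i_effect=1.0, c_over_b_effect=1.0),
    dict(element_id="ins09", host_gene="gene009", structural_class="ID1",
         strand_relative="antisense", u_over_i_effect=1.0, c_over_b_effect=1.0),
    dict(element_id="ins10", host_gene="gene010", structural_class="solo_LTR",
         strand_relative="antisense", u_over_i_effect=1.0, c_over_b_effect=1.0),
]


@dataclass
class RunConfig:
    """All pipeline parameters, namespaced per stage."""

    seed: int
    n_genes: int = 12
    intron_length_range: tuple[int, int] = (1500, 4000)
    consensus_length: int = 7500
    insertions: list[dict] = field(default_factory=lambda: [dict(d) for d in DEFAULT_INSERTIONS])
    insertion_offset: int = 500
    # measurement design
    n_pairs: int = 10
    n_per_strain: int = 5
    n_tech_reps: int = 3
    cq_noise_sd: float = 0.4
    efficiency: float = 2.0
    reference_assays: tuple[str, ...] = ("Gapdh", "Sdha", "Ppia")
    qc_max_cv: float = 0.5
    # scan
    max_mismatch: int = 0
    max_gap: int = es.DEFAULT_MAX_GAP
    size_threshold: int = es.DEFAULT_SIZE_THRESHOLD
    seed_panel_step: int = 250
    # array screen
    array_n_pairs: int = 3
    array_noise_cv: float = 0.2
    array_n_null_events: int = 200
    score_threshold: float = ss.DEFAULT_SCORE_THRESHOLD
    q_threshold: float = ss.DEFAULT_Q_THRESHOLD
    version: str = __version__

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.intron_length_range = tuple(self.intron_length_range)  # type: ignore[assignment]
        self.reference_assays = tuple(self.reference_assays)  # type: ignore[assignment]

    @property
    def hash(self) -> str:
        return config_hash(asdict(self))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def assay_qc_filter(
    cq: pd.DataFrame, max_cv: float, efficiency: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop assays whose between-replicate coefficient of variation (on the
    linear quantity scale) exceeds ``max_cv``, emulating a data-driven assay
    attrition step. Returns (filtered table, per-assay QC log)."""

    def assay_cv(sub: pd.DataFrame) -> float:
        cvs = []
        for _, grp in sub.groupby("sample_id"):
            q = efficiency ** (grp["cq"].min() - grp["cq"])
            if len(q) > 1 and q.mean() > 0:
                cvs.append(q.std(ddof=1) / q.mean())
        return float(np.mean(cvs)) if cvs else 0.0

    qc = (
        cq.groupby("assay_id", sort=False)
        .apply(assay_cv, include_groups=False)
        .rename("replicate_cv")
        .reset_index()
    )
    qc["dropped"] = qc["replicate_cv"] > max_cv
    for assay in qc.loc[qc["dropped"], "assay_id"]:
        logger.info("assay_qc_filter: dropped %s (replicate CV > %.2f)", assay, max_cv)
    keep = set(qc.loc[~qc["dropped"], "assay_id"])
    return cq[cq["assay_id"].isin(keep)].reset_index(drop=True), qc


def _stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("stage %-12s in=%d out=%d", name, n_in, n_out)


def run_pipeline(config: RunConfig, outdir: str | os.PathLike | None = None) -> dict:
    """Run the full synthetic pipeline and return the report bundle.

    When ``outdir`` is given, writes the element census (BED6 + TSV), the
    suppression table, the event calls, the shared-core intervals and a JSON
    summary, all stamped with the config hash.
    """
    rng = np.random.default_rng(config.seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    genome_seed, design_seed, array_seed = sub(), sub(), sub()
    chash = config.hash

    # --- simulate substrate -------------------------------------------------
    genome = sd.generate_genome(
        config.n_genes,
        intron_length_range=config.intron_length_range,
        consensus_length=config.consensus_length,
        seed=genome_seed,
    )
    specs = [
        sd.class_spec(
            d["structural_class"],
            genome.consensus,
            d["element_id"],
            d["host_gene"],
            intron_index=d.get("intron_index", 0),
            offset_in_intron=d.get("offset_in_intron", config.insertion_offset),
            strand_relative=d.get("strand_relative", "sense"),
            u_over_i_effect=d.get("u_over_i_effect", 1.0),
            c_over_b_effect=d.get("c_over_b_effect", 1.0),
        )
        for d in config.insertions
    ]
    mutated, truth = sd.plant_insertions(genome, specs)
    _stage("simulate", config.n_genes, len(truth.planted))

    # --- scan ---------------------------------------------------------------
    panel = sd.design_seed_panel(genome.consensus, step=config.seed_panel_step)
    hits = es.scan_seeds(mutated.sequences, panel, max_mismatch=config.max_mismatch)
    elements = es.merge_hits(hits, max_gap=config.max_gap)
    elements = es.assign_host(elements, mutated)
    elements = es.curate(elements, annotation=mutated)
    _stage("scan", len(hits), len(elements))
    bias = es.orientation_bias_test(elements, size_threshold=config.size_threshold)

    # --- classify -----------------------------------------------------------
    maps, calls = {}, {}
    for e in elements:
        seq = mutated.sequences[e.chrom][e.start : e.end]
        if e.strand == "-":
            seq = revcomp(seq)
        cmap = ec.map_to_consensus(seq, genome.consensus, element_id=e.element_id)
        maps[e.element_id] = cmap
        calls[e.element_id] = ec.classify(cmap, e.length, genome.consensus)
    _stage("classify", len(elements), len(calls))

    # --- quantify -----------------------------------------------------------
    design = sd.MeasurementDesign(
        n_pairs=config.n_pairs,
        n_per_strain=config.n_per_strain,
        n_tech_reps=config.n_tech_reps,
        cq_noise_sd=config.cq_noise_sd,
        efficiency=config.efficiency,
        reference_assays=config.reference_assays,
        seed=design_seed,
    )
    cq = sd.simulate_expression(truth, design)
    cq_kept, qc = assay_qc_filter(cq, config.qc_max_cv, efficiency=config.efficiency)
    expr = xs.normalize(cq_kept, config.reference_assays, efficiency=config.efficiency)
    class_by_gene = {}
    for e in elements:
        if e.host_gene is not None and e.element_id in calls:
            class_by_gene[e.host_gene] = calls[e.element_id].structural_class
    suppression = xs.suppression_analysis(expr, class_by_gene)
    _stage("quantify", len(cq), len(suppression))

    # --- array screen -------------------------------------------------------
    truth.array_scores = {
        f"ev_{r.host_gene}": float(np.log2(r.c_over_b_effect))
        for r in truth.planted.itertuples()
        if r.strand_relative == "sense"
    }
    truth.array_scores.update(
        {f"null{i:04d}": 0.0 for i in range(1, config.array_n_null_events + 1)}
    )
    array = sd.simulate_array(
        truth, n_pairs=config.array_n_pairs, intensity_noise_cv=config.array_noise_cv,
        seed=array_seed,
    )
    events = ss.call_events(
        array, score_threshold=config.score_threshold, q_threshold=config.q_threshold
    )
    _stage("array-screen", len(array), len(events))

    # --- shared core --------------------------------------------------------
    suppressed_genes = set(
        suppression.loc[(suppression["q"] < 0.05) & (suppression["c_over_b"] > 1), "assay_id"]
    )
    core_maps = [
        maps[e.element_id]
        for e in elements
        if e.host_gene in suppressed_genes and e.orientation == "sense"
    ]
    core = ec.shared_core(core_maps) if len(core_maps) >= 2 else []

    # --- truth comparison ---------------------------------------------------
    planted_iv = {
        (r.chrom, r.start, r.end, r.strand) for r in truth.planted.itertuples()
    }
    found_iv = {(e.chrom, e.start, e.end, e.strand) for e in elements}
    class_truth = dict(zip(truth.planted["element_id"], truth.planted["structural_class"]))
    planted_by_iv = {
        (r.chrom, r.start, r.end, r.strand): r.element_id for r in truth.planted.itertuples()
    }
    class_correct = sum(
        1
        for e in elements
        if (e.chrom, e.start, e.end, e.strand) in planted_by_iv
        and calls[e.element_id].structural_class
        == class_truth[planted_by_iv[(e.chrom, e.start, e.end, e.strand)]]
    )

    census = {
        "n_elements": len(elements),
        "n_sense": sum(e.orientation == "sense" for e in elements),
        "n_antisense": sum(e.orientation == "antisense" for e in elements),
        "n_le_threshold": sum(e.length <= config.size_threshold for e in elements),
        "by_class": dict(
            pd.Series([c.structural_class for c in calls.values()]).value_counts().sort_index()
        ),
    }
    report = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "census": {k: (v if not isinstance(v, dict) else {kk: int(vv) for kk, vv in v.items()})
                   for k, v in census.items()},
        "orientation_bias": {
            "table": [list(r) for r in bias.table],
            "p": bias.p_value,
            "size_threshold": bias.size_threshold,
        },
        "assay_qc": {"n_assays": int(len(qc)), "n_dropped": int(qc["dropped"].sum())},
        "suppression": {
            "n_assays": int(len(suppression)),
            "n_suppressed_q05": int(((suppression["q"] < 0.05) & (suppression["c_over_b"] > 1)).sum()),
        },
        "array_screen": {
            "n_events": int(len(events)),
            "n_significant": int(events["significant"].sum()),
        },
        "shared_core": {"intervals": [list(iv) for iv in core], "total_bp": total_bp(core)},
        "truth_comparison": {
            "planted": len(planted_iv),
            "recovered_exact": len(planted_iv & found_iv),
            "false_elements": len(found_iv - planted_iv),
            "classes_correct": class_correct,
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        iof.write_sequences(outdir / "genome.fasta", mutated.sequences)
        iof.write_annotation(outdir / "genes.gff3", mutated.genes, "gff3", config_hash=chash)
        iof.write_bed6(
            outdir / "elements.bed",
            [(e.chrom, e.start, e.end, e.element_id, 0, e.strand) for e in elements],
            config_hash=chash,
        )
        element_table = pd.DataFrame(
            [
                {
                    "element_id": e.element_id,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                    "strand": e.strand,
                    "length": e.length,
                    "host_gene": e.host_gene,
                    "orientation": e.orientation,
                    "structural_class": calls[e.element_id].structural_class,
                    **{f"cov_{k}": round(v, 4) for k, v in maps[e.element_id].segment_coverage.items()},
                }
                for e in elements
            ]
        )
        iof.write_table(outdir / "elements.tsv", element_table, config_hash=chash)
        iof.write_table(outdir / "suppression.tsv", suppression, config_hash=chash)
        iof.write_table(outdir / "event_calls.tsv", events, config_hash=chash)
        iof.write_table(outdir / "assay_qc.tsv", qc, config_hash=chash)
        iof.write_bed6(
            outdir / "shared_core.bed",
            [("consensus", s, e, f"core{i + 1}", 0, "+") for i, (s, e) in enumerate(core)],
            config_hash=chash,
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
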