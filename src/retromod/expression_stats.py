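"""qPCR normalization and the suppression statistics.

Relative quantities are normalized against the geometric mean of multiple
reference-gene quantities. Suppression is quantified per assay as the
uninserted/inserted (U/I) strain ratio with a two-tailed Mann-Whitney test
on unpaired samples and as the suppressed/unsuppressed genotype (C/B) ratio
with a one-tailed Wilcoxon signed-rank test on littermate pairs, followed by
Benjamini-Hochberg FDR within structural classes and Fisher's combined
probability meta-analysis across experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import logger

EXACT_MAX_N = 25  # exact rank-test null up to this n when there are no ties


@dataclass
class SuppressionResult:
    assay_id: str
    u_over_i: float
    p_ui: float
    c_over_b: float
    p_cb: float
    structural_class: str = "unclassified"
    q: float = float("nan")
    p_meta: float = float("nan")


def normalize(
    cq: pd.DataFrame,
    reference_assays: list[str] | tuple[str, ...],
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Collapse technical replicates on the Cq scale and normalize each
    target quantity by the geometric mean of the reference quantities.

    The relative quantity of an assay is efficiency ** (−Cq), and NRQ =
    RQ(target) / geometric-mean(RQ over references) =
    efficiency ** (mean reference Cq − target Cq). No calibrator anchoring
    is applied, so adding a constant to every Cq of a sample leaves its NRQ
    values strictly unchanged (the defining property of reference-gene
    normalization); anchored variants differ only by a per-assay constant.
    Samples missing any reference assay are excluded with a logged warning.
    Returns one row per sample x target assay with columns nrq, strain,
    genotype, pair_id.
    """
    if not (1 < efficiency <= 2):
        raise ValueError("efficiency must be in (1, 2]")
    refs = list(reference_assays)
    meta_cols = [c for c in ("strain", "genotype", "pair_id") if c in cq.columns]
    mean_cq = (
        cq.groupby(["sample_id", "assay_id"] + meta_cols, as_index=False, sort=False, dropna=False)
        .agg(cq=("cq", "mean"))
    )
    wide = mean_cq.pivot_table(index="sample_id", columns="assay_id", values="cq", sort=False)
    missing = [a for a in refs if a not in wide.columns]
    if missing:
        raise ValueError(f"reference assays absent from the table: {missing}")
    ok = wide[refs].notna().all(axis=1)
    for sample in wide.index[~ok]:
        logger.warning("normalize: sample %s excluded (missing reference assay)", sample)
    ref_mean_cq = wide.loc[ok, refs].mean(axis=1)

    out = mean_cq[
        mean_cq["sample_id"].isin(ref_mean_cq.index) & ~mean_cq["assay_id"].isin(refs)
    ].copy()
    out["nrq"] = efficiency ** (
        out["sample_id"].map(ref_mean_cq).to_numpy() - out["cq"].to_numpy()
    )
    return out[["sample_id", "assay_id", "nrq"] + meta_cols].reset_index(drop=True)


def ratio_test(expr: pd.DataFrame, mode: str = "unpaired_strain") -> tuple[float, float]:
    """Suppression ratio and p-value for one assay.

    ``unpaired_strain``: median(uninserted)/median(inserted) with a
    two-tailed Mann-Whitney test. ``paired_genotype``: median per-pair C/B
    with a one-tailed (C > B) Wilcoxon signed-rank test on paired samples.
    ``unpaired_edited``: median(edited)/median(B) with a one-tailed
    Mann-Whitney test for the predicted increase in edited animals. Exact
    null distributions are used when there are no ties and n permits;
    otherwise a normal approximation with continuity correction.
    """
    if (expr["nrq"] <= 0).any():
        raise ValueError("normalized quantities must be positive")
    if mode == "unpaired_strain" or mode == "unpaired_edited":
        if mode == "unpaired_strain":
            a = expr.loc[expr["strain"] == "uninserted", "nrq"].to_numpy()
            b = expr.loc[expr["strain"] == "inserted", "nrq"].to_numpy()
            alternative = "two-sided"
        else:
            a = expr.loc[expr["genotype"] == "edited", "nrq"].to_numpy()
            b = expr.loc[expr["genotype"] == "B", "nrq"].to_numpy()
            alternative = "greater"
        if min(len(a), len(b)) < 3:
            raise ValueError("need >= 3 samples per group")
        pooled = np.concatenate([a, b])
        method = (
            "exact"
            if len(np.unique(pooled)) == len(pooled) and max(len(a), len(b)) <= EXACT_MAX_N
            else "asymptotic"
        )
        stat = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
        return float(np.median(a) / np.median(b)), float(stat.pvalue)
    if mode == "paired_genotype":
        wide = expr.pivot_table(index="pair_id", columns="genotype", values="nrq", sort=False)
        wide = wide.dropna(subset=["B", "C"])
        if len(wide) < 3:
            raise ValueError("need >= 3 complete pairs")
        ratios = (wide["C"] / wide["B"]).to_numpy()
        d = np.log(ratios)
        if np.all(d == 0):
            return 1.0, 1.0
        # the exact conditional null (sign flips given observed ranks) is
        # valid with tied magnitudes; zeros are dropped by the test itself
        method = "exact" if len(d) <= EXACT_MAX_N else "approx"
        stat = stats.wilcoxon(
            d[d != 0], alternative="greater", method=method, correction=True
        )
        return float(np.median(ratios)), float(stat.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def class_fdr(results: pd.DataFrame, grouping: str = "by_class", p_col: str = "p_cb") -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values, within each structural class
    (``by_class``) or across all rows (``pooled``)."""
    out = results.copy()
    if grouping == "pooled":
        out["q"] = multipletests(out[p_col].to_numpy(), method="fdr_bh")[1]
    elif grouping == "by_class":
        out["q"] = np.nan
        for _, idx in out.groupby("structural_class").groups.items():
            out.loc[idx, "q"] = multipletests(out.loc[idx, p_col].to_numpy(), method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values: q_(i) = min_{j>=i} p_(j)·m/j, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def fisher_combined(p_values) -> float:
    """Fisher's combined probability: X = −2·Σ ln p against chi-square with
    2k degrees of freedom. Raises on p = 0 (caller must floor)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(stats.combine_pvalues(p, method="fisher").pvalue)


def groupwise_test(log_ratios) -> float:
    """Pooled one-sided signed-rank test across assays in a class: normal
    approximation with continuity correction on per-pair log ratios."""
    d = np.asarray(log_ratios, dtype=float)
    if len(d) < 6:
        raise ValueError("pooled group-wise test needs >= 6 pairs")
    if np.all(d == 0):
        return 1.0
    return float(
        stats.wilcoxon(d, alternative="greater", method="approx", correction=True).pvalue
    )


def context_correlates(
    features: pd.DataFrame, ratios: pd.Series
) -> pd.DataFrame:
    """Per-feature association with the (log) suppression ratio.

    Numeric features: Spearman correlation with average ranks for ties;
    constant features are reported as missing, never as zero. Categorical
    features (object/category dtype): tie-corrected Kruskal-Wallis p.
    """
    if len(features) < 5:
        raise ValueError("need >= 5 elements")
    y = np.asarray(ratios, dtype=float)
    rows = []
    for name in features.columns:
        col = features[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            groups = [y[(col == level).to_numpy()] for level in col.unique()]
            groups = [g for g in groups if len(g)]
            if len(groups) < 2:
                rows.append((name, "categorical", np.nan, np.nan))
                continue
            stat = stats.kruskal(*groups)
            rows.append((name, "categorical", np.nan, float(stat.pvalue)))
        else:
            x = col.to_numpy(dtype=float)
            if np.all(x == x[0]):
                logger.warning("context_correlates: %s is constant, rho undefined", name)
                rows.append((name, "numeric", np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append((name, "numeric", float(rho), float(p)))
    return pd.DataFrame(rows, columns=["feature", "kind", "rho", "p"])


def suppression_analysis(
    expr: pd.DataFrame,
    class_map: dict[str, str],
    fdr_grouping: str = "by_class",
    extra_pvalues: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-assay suppression table: U/I and C/B ratios with their tests,
    class-wise BH q on the paired p, and Fisher combined meta p where a
    second experiment's p-value is supplied."""
    rows = []
    for assay, sub in expr.groupby("assay_id", sort=False):
        ui_sub = sub[sub["pair_id"].astype(str).isin(["", "nan"]) | sub["pair_id"].isna()]
        cb_sub = sub[~sub.index.isin(ui_sub.index)]
        u_over_i, p_ui = ratio_test(ui_sub, "unpaired_strain")
        c_over_b, p_cb = ratio_test(cb_sub, "paired_genotype")
        rows.append(
            {
                "assay_id": assay,
                "u_over_i": u_over_i,
                "p_ui": p_ui,
                "c_over_b": c_over_b,
                "p_cb": p_cb,
                "structural_class": class_map.get(assay, "unclassified"),
            }
        )
    table = class_fdr(pd.DataFrame(rows), grouping=fdr_grouping)
    extra = extra_pvalues or {}
    table["p_meta"] = [
        fisher_combined([p, extra[a]]) if a in extra else np.nan
        for a, p in zip(table["assay_id"], table["p_cb"])
    ]
    return table
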