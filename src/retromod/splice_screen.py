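"""Splicing-array separation scores, significance calling, and gel-band
isoform ratios.

The separation score of an event is the mean over littermate pairs of
log2 of the ratio of (inclusion/exclusion) isoform ratios between the two
genotypes; an event is significant when |score| exceeds the score threshold
(default 0.5, ~1.4-fold change in isoform ratio) and its BH q-value is below
the q threshold (default 0.05). Event-level p-values come from a paired
t-test on the per-pair log2 ratios, a deliberate substitution for the
array-vendor pipeline statistic, and are flagged as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import logger
from .expression_stats import ratio_test

DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_Q_THRESHOLD = 0.05
P_VALUE_METHOD = "paired t on per-pair log2 ratio (substitution)"


@dataclass
class EventCall:
    event_id: str
    separation_score: float
    p: float
    q: float
    significant: bool


def _pair_log2_ratios(events: pd.DataFrame) -> pd.DataFrame:
    """Per (event, pair) log2 of (inclusion/exclusion ratio C) / (ratio B)."""
    if (events[["inclusion", "exclusion"]] <= 0).any().any():
        raise ValueError("intensities must be positive")
    work = events.copy()
    work["log2_ratio"] = np.log2(work["inclusion"] / work["exclusion"])
    wide = work.pivot_table(
        index=["event_id", "pair_id"], columns="genotype", values="log2_ratio", sort=False
    )
    if not {"B", "C"}.issubset(wide.columns):
        raise ValueError("each event needs both genotypes per pair")
    wide = wide.dropna(subset=["B", "C"])
    wide["d"] = wide["C"] - wide["B"]
    return wide.reset_index()


def separation_scores(events: pd.DataFrame) -> pd.Series:
    """Per-event separation score: mean over pairs of log2(r_C / r_B)."""
    pairs = _pair_log2_ratios(events)
    if pairs.empty:
        raise ValueError("no complete genotype pairs")
    return pairs.groupby("event_id", sort=False)["d"].mean().rename("separation_score")


def call_events(
    events: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Score every event and call significance.

    Events with a single complete pair get no p-value and are reported
    uncalled (significant = False, p and q missing). BH correction runs
    across all events with a p-value.
    """
    pairs = _pair_log2_ratios(events)
    rows = []
    for event_id, sub in pairs.groupby("event_id", sort=False):
        d = sub["d"].to_numpy()
        score = float(d.mean())
        if len(d) < 2:
            logger.info("call_events: %s has a single pair, left uncalled", event_id)
            rows.append((event_id, score, np.nan))
        else:
            if np.allclose(d, d[0]):
                # zero variance: the t statistic is undefined; a perfectly
                # reproduced nonzero shift is maximal evidence, no shift is none
                p = 0.0 if abs(score) > 0 else 1.0
            else:
                p = float(stats.ttest_1samp(d, 0.0).pvalue)
            rows.append((event_id, score, p))
    out = pd.DataFrame(rows, columns=["event_id", "separation_score", "p"])
    out["q"] = np.nan
    has_p = out["p"].notna()
    if has_p.any():
        out.loc[has_p, "q"] = multipletests(out.loc[has_p, "p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = has_p & (out["separation_score"].abs() > score_threshold) & (
        out["q"] < q_threshold
    )
    out["p_value_method"] = P_VALUE_METHOD
    return out


def gel_band_ratio(bands: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-pair C/B ratio of two-band isoform ratios plus a one-sided
    signed-rank p for suppression.

    Expects columns sample_id, pair_id, genotype, band1, band2 and an
    optional boolean ``saturated`` column; saturated samples are excluded
    with a logged message. The per-sample isoform ratio is band1/band2.
    """
    work = bands.copy()
    if "saturated" in work.columns:
        for s in work.loc[work["saturated"].astype(bool), "sample_id"]:
            logger.warning("gel_band_ratio: sample %s excluded (saturated intensity)", s)
        work = work[~work["saturated"].astype(bool)]
    if (work[["band1", "band2"]] <= 0).any().any():
        raise ValueError("band intensities must be positive")
    work["nrq"] = work["band1"] / work["band2"]
    ratio, p = ratio_test(work[["pair_id", "genotype", "nrq"]], mode="paired_genotype")
    wide = work.pivot_table(index="pair_id", columns="genotype", values="nrq", sort=False)
    per_pair = (wide["C"] / wide["B"]).dropna().rename("c_over_b")
    return per_pair, p
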