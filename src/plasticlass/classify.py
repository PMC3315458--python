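"""Transcript classification: robust / Class I / Class II.

Class I: significant treatment term at FDR < 0.05 and no significant
sex-by-treatment interaction (interaction-significant transcripts are
set aside and their count reported).  Class II is found by a two-filter
cascade applied per sex: CVME above the 95th percentile of the Class I
CVME distribution, AND a genetic-variation FDR above a stringent floor
(little evidence of among-line variance in the inbred panel); Class II
candidates overlapping Class I are removed.  Class II transcripts are
split into high/low expression groups per sex by the exhaustive optimal
1-D bipartition minimizing total within-group sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaResult
from .io import SEXES

ROBUST = "robust"
CLASS_I = "classI"
CLASS_I_EXCLUDED = "classI_excluded_interaction"
CLASS_II = "classII"


@dataclass
class ClassAssignment:
    """Per-transcript class labels with Class II sex and expression sublabels."""

    table: pd.DataFrame  # label, classII_sex, classII_expr_female, classII_expr_male
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["label"].value_counts().to_dict()
        for label in (ROBUST, CLASS_I, CLASS_I_EXCLUDED, CLASS_II):
            c.setdefault(label, 0)
        return c

    @property
    def classII_sex_counts(self) -> dict[str, int]:
        sub = self.table.loc[self.table["label"] == CLASS_II, "classII_sex"]
        return {k: int((sub == k).sum()) for k in ("female_only", "male_only", "both")}

    def ids(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])


def assign_class1(anova: AnovaResult, q_level: float = 0.05) -> ClassAssignment:
    """Label treatment-responsive transcripts from the ANOVA FDR flags."""
    env = anova.flags("env", q_level)
    inter = anova.flags("int", q_level)
    label = pd.Series(ROBUST, index=anova.table.index, name="label")
    label[env & ~inter] = CLASS_I
    label[env & inter] = CLASS_I_EXCLUDED
    table = pd.DataFrame(
        {
            "label": label,
            "classII_sex": "n/a",
            "classII_expr_female": "n/a",
            "classII_expr_male": "n/a",
        }
    )
    return ClassAssignment(table=table)


def class1_cvme_threshold(
    profile: pd.DataFrame,
    class1_ids: list[str],
    quantile: float = 0.95,
    method: str = "linear",
) -> dict[str, float]:
    """Per-sex CVME cut-off: the 95th percentile of Class I CVME."""
    thresholds = {}
    for sex in SEXES:
        cvme = profile.xs(sex, level="sex")["CVME"].reindex(class1_ids).dropna()
        if len(cvme) < 20:
            raise ValueError(
                f"too few Class I transcripts with CVME for sex {sex!r} ({len(cvme)})"
            )
        thresholds[sex] = float(np.quantile(cvme.values, quantile, method=method))
    return thresholds


def assign_class2(
    profile: pd.DataFrame,
    thresholds: dict[str, float],
    genetic_q: pd.DataFrame,
    classes: ClassAssignment,
    genetic_fdr_floor: float = 1e-4,
) -> ClassAssignment:
    """Complete the assignment with the Class II filter cascade.

    Per sex: candidate = CVME > threshold AND genetic-variation q >
    ``genetic_fdr_floor``.  A transcript is Class II if it is a candidate
    in either sex and is not Class I; the sex category records which.
    """
    table = classes.table.copy()
    cand = {}
    for sex in SEXES:
        cvme = profile.xs(sex, level="sex")["CVME"].reindex(table.index)
        q = genetic_q[sex].reindex(table.index)
        cand[sex] = (cvme > thresholds[sex]) & (q > genetic_fdr_floor)
        cand[sex] = cand[sex].fillna(False)
    either = cand["female"] | cand["male"]
    is_class1 = table["label"] == CLASS_I
    is2 = either & ~is_class1 & (table["label"] != CLASS_I_EXCLUDED)

    table.loc[is2, "label"] = CLASS_II
    sex_cat = np.select(
        [cand["female"] & cand["male"], cand["female"], cand["male"]],
        ["both", "female_only", "male_only"],
        default="n/a",
    )
    table.loc[is2, "classII_sex"] = pd.Series(sex_cat, index=table.index)[is2]
    return ClassAssignment(table=table, thresholds=dict(thresholds))


def optimal_bipartition(values) -> tuple[np.ndarray, float]:
    """Globally optimal 2-group split of 1-D values by within-group SS.

    Exhaustive over the n-1 contiguous splits of the sorted values (the
    1-D optimum is always contiguous); both groups nonempty.  Returns
    labels ('low'/'high' by group mean, aligned to the input order) and
    the total within-group sum of squares.  SS ties assign the boundary
    value to the low group.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("bipartition needs at least 2 values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.cumsum(xs)
    csq = np.cumsum(xs ** 2)
    total_sum, total_sq = csum[-1], csq[-1]
    k = np.arange(1, n)  # left group sizes
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    right_ss = (total_sq - csq[:-1]) - (total_sum - csum[:-1]) ** 2 / (n - k)
    ss = left_ss + right_ss
    best = ss.min()
    # ties -> boundary value to the low (left) group -> largest split index
    split = int(np.flatnonzero(np.isclose(ss, best, rtol=0, atol=1e-12))[-1]) + 1
    labels = np.empty(n, dtype=object)
    labels[order[:split]] = "low"
    labels[order[split:]] = "high"
    return labels, float(best)


def split_class2_expression(
    profile: pd.DataFrame, classes: ClassAssignment
) -> ClassAssignment:
    """Split Class II transcripts into high/low mean-expression groups per sex."""
    table = classes.table.copy()
    ids = classes.ids(CLASS_II)
    if len(ids) >= 2:
        for sex in SEXES:
            means = profile.xs(sex, level="sex")["mean"].reindex(ids)
            labels, _ = optimal_bipartition(means.values)
            table.loc[ids, f"classII_expr_{sex}"] = labels
    return ClassAssignment(table=table, thresholds=classes.thresholds)


def dimorphism_relation(profile: pd.DataFrame, classes: ClassAssignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sexual dimorphism of mean expression vs dimorphism of plasticity.

    Per transcript: mean_dimorphism = female mean - male mean (log2) and
    plasticity_dimorphism = female CVME - male CVME (percent).  Per class,
    the Spearman rank correlation between the two with its p-value.
    """
    wide = profile.unstack("sex")
    per_transcript = pd.DataFrame(
        {
            "mean_dimorphism": wide[("mean", "female")] - wide[("mean", "male")],
            "plasticity_dimorphism": wide[("CVME", "female")] - wide[("CVME", "male")],
            "label": classes.table["label"].reindex(wide.index),
        }
    )
    rows = []
    for label, sub in per_transcript.groupby("label"):
        sub = sub.dropna()
        if len(sub) < 3 or sub["mean_dimorphism"].nunique() < 2:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(
                sub["mean_dimorphism"], sub["plasticity_dimorphism"]
            )
        rows.append({"label": label, "n": len(sub), "spearman_rho": rho, "p": p})
    return per_transcript, pd.DataFrame(rows).set_index("label")
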