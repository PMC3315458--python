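"""End-to-end classification pipeline and recovery bookkeeping.

Chains the stages: two-way variance partition on the outbred matrix,
variability profiles, Class I assignment, Class II filter cascade
against the inbred panel, and the high/low expression split — and
reports the count identities (Class II sex-category sums, the
interaction-excluded count) that the per-stage outputs must satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import anova, classify, variability
from .io import ExpressionMatrix
from .simulate import GroundTruth


@dataclass
class ClassificationRun:
    anova: anova.AnovaResult
    profile: pd.DataFrame  # outbred CV panel (transcript x sex)
    genetic_profile: pd.DataFrame  # inbred CVL/CVE panel
    genetic_q: pd.DataFrame
    classes: classify.ClassAssignment

    @property
    def summary(self) -> dict:
        counts = self.classes.counts
        sex_counts = self.classes.classII_sex_counts
        n = len(self.classes.table)
        env_sig = counts["classI"] + counts["classI_excluded_interaction"]
        return {
            "n_transcripts": n,
            "n_env_significant": env_sig,
            "n_classI": counts["classI"],
            "n_excluded_interaction": counts["classI_excluded_interaction"],
            "n_classII": counts["classII"],
            "classII_female_only": sex_counts["female_only"],
            "classII_male_only": sex_counts["male_only"],
            "classII_both": sex_counts["both"],
            "n_robust": counts["robust"],
            "frac_env_significant": env_sig / n,
            "cvme_thresholds": self.classes.thresholds,
        }


def classify_transcriptome(
    outbred: ExpressionMatrix,
    panel: ExpressionMatrix,
    q_level: float = 0.05,
    genetic_fdr_floor: float = 1e-4,
    cvme_quantile: float = 0.95,
) -> ClassificationRun:
    """Run the full robust / Class I / Class II partition."""
    fit = anova.fit_two_way_anova(outbred)
    classes = classify.assign_class1(fit, q_level=q_level)
    profile = variability.macroenv_profile(outbred)
    gprofile = variability.genetic_profile(panel)
    genetic_q = anova.genetic_variation_fdr(panel)
    thresholds = classify.class1_cvme_threshold(
        profile, classes.ids(classify.CLASS_I), quantile=cvme_quantile
    )
    classes = classify.assign_class2(
        profile, thresholds, genetic_q, classes, genetic_fdr_floor=genetic_fdr_floor
    )
    classes = classify.split_class2_expression(profile, classes)
    return ClassificationRun(
        anova=fit,
        profile=profile,
        genetic_profile=gprofile,
        genetic_q=genetic_q,
        classes=classes,
    )


def recovery_metrics(classes: classify.ClassAssignment, truth: GroundTruth) -> dict:
    """Sensitivity / empirical FDR of the recovered classes vs planted truth."""
    out = {}
    for label in ("classI", "classII"):
        planted = set(truth.ids(label))
        found = set(classes.ids(label))
        tp = len(planted & found)
        out[f"{label}_sensitivity"] = tp / len(planted) if planted else float("nan")
        out[f"{label}_fdr"] = (
            (len(found) - tp) / len(found) if found else 0.0
        )
    overlap = set(classes.ids("classI")) & set(classes.ids("classII"))
    out["classI_classII_overlap"] = len(overlap)
    return out
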