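"""Coefficient-of-variation panel for expression variability.

From the outbred multi-environment design (per transcript, per sex):

* CVME  — CV of the per-treatment means (macroenvironmental variation);
* CVEW  — mean of the within-treatment replicate CVs;
* STD_CVEW — sd of those within-treatment CVs;
* mean / std_mean — mean and sd of the treatment means.

From the inbred panel (per transcript, per sex):

* CVL — CV of the line means (genetic variation);
* CVE — mean of the within-line replicate CVs (micro-environmental).

All CVs are percent, computed on positive log2-scale values with the
sample (n-1) standard deviation; matrices must be un-centered.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SEXES


def cv(values) -> float:
    """Percent coefficient of variation: 100 * sample sd / mean."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cv of an empty vector")
    mean = x.mean()
    if mean <= 0:
        raise ValueError(f"cv undefined for mean <= 0 (mean={mean:.4g})")
    if x.size == 1:
        return 0.0
    return float(100.0 * x.std(ddof=1) / mean)


def _within_group_cvs(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-transcript CV within each group (column = group), percent.

    Groups with fewer than 2 replicates contribute nothing (warned);
    group cells whose mean is non-positive are masked (warned) since a
    CV around zero is meaningless.
    """
    out = {}
    skipped = []
    for group, sub in m.values.T.groupby(m.design["group"]):
        if len(sub) < 2:
            skipped.append(group)
            continue
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = 100.0 * sd / mean
        nonpos = mean <= 0
        if nonpos.any():
            warnings.warn(
                f"{int(nonpos.sum())} transcript(s) with non-positive mean in "
                f"group {group!r}; excluded from within-group CV"
            )
            c[nonpos] = np.nan
        out[group] = c
    if skipped:
        warnings.warn(f"groups with <2 replicates skipped in within-group CV: {skipped}")
    return pd.DataFrame(out)


def _sex_profile(m: ExpressionMatrix, sex: str) -> pd.DataFrame:
    sub = m.subset_sex(sex)
    gm = sub.group_means()  # transcripts x groups
    mean = gm.mean(axis=1)
    if (mean <= 0).any():
        raise ValueError("non-positive mean expression; CVs need un-centered values")
    sd = gm.std(axis=1, ddof=1)
    within = _within_group_cvs(sub)
    return pd.DataFrame(
        {
            "mean": mean,
            "std_mean": sd,
            "CVME": 100.0 * sd / mean,
            "CVEW": within.mean(axis=1),
            "STD_CVEW": within.std(axis=1, ddof=1),
        }
    )


def macroenv_profile(m: ExpressionMatrix) -> pd.DataFrame:
    """Outbred-design variability profile, per transcript x sex.

    Returns a tidy DataFrame with MultiIndex (transcript, sex) and
    columns mean, std_mean, CVME, CVEW, STD_CVEW.
    """
    if m.centering != "raw":
        raise ValueError("CVs are computed on un-centered matrices only")
    parts = {sex: _sex_profile(m, sex) for sex in SEXES if (m.design["sex"] == sex).any()}
    return pd.concat(parts, names=["sex", "transcript"]).swaplevel().sort_index()


def genetic_profile(panel: ExpressionMatrix) -> pd.DataFrame:
    """Inbred-panel variability profile: CVL and CVE per transcript x sex."""
    if panel.centering != "raw":
        raise ValueError("CVs are computed on un-centered matrices only")
    parts = {}
    for sex in SEXES:
        if not (panel.design["sex"] == sex).any():
            continue
        sub = panel.subset_sex(sex)
        lm = sub.group_means()
        mean = lm.mean(axis=1)
        if (mean <= 0).any():
            raise ValueError("non-positive mean expression; CVs need un-centered values")
        parts[sex] = pd.DataFrame(
            {
                "mean_line": mean,
                "CVL": 100.0 * lm.std(axis=1, ddof=1) / mean,
                "CVE": _within_group_cvs(sub).mean(axis=1),
            }
        )
    return pd.concat(parts, names=["sex", "transcript"]).swaplevel().sort_index()
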