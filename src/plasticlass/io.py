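"""Reading, summarizing, normalizing and centering expression matrices.

The pipeline starts from a log2 expression matrix (transcripts x samples,
TSV) plus a design sheet describing each sample.  Two designs occur:

* outbred multi-environment: ``group`` is a treatment name, one treatment
  is flagged as the standard/reference rearing condition;
* inbred panel: ``group`` is a line name (no standard flag needed).

All values are median log2 signal intensities.  Probe-level data are
collapsed to one row per probe set by the within-sample median.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("sample_id", "sex", "group", "replicate")
SEXES = ("female", "male")


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix with its sample design sheet.

    ``values`` is a transcripts x samples DataFrame; ``design`` is indexed
    by sample_id (same order as the columns of ``values``) with columns
    ``sex``, ``group``, ``replicate`` and optionally ``is_standard``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    background_threshold: float | None = None
    centering: str = "raw"

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("design rows must align with matrix columns")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        return sorted(self.design["group"].unique())

    @property
    def standard_group(self) -> str | None:
        if "is_standard" not in self.design.columns:
            return None
        std = self.design.loc[self.design["is_standard"].astype(bool), "group"].unique()
        return std[0] if len(std) else None

    def subset_sex(self, sex: str) -> "ExpressionMatrix":
        keep = self.design["sex"] == sex
        return replace(
            self, values=self.values.loc[:, keep.values], design=self.design.loc[keep]
        )

    def group_means(self, sex: str | None = None) -> pd.DataFrame:
        """Per-group (treatment or line) mean expression, optionally per sex."""
        m = self.subset_sex(sex) if sex is not None else self
        return m.values.T.groupby(m.design["group"]).mean().T


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design sheet missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids in design: {dups}")
    bad_sex = set(design["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    return design.set_index("sample_id")


def read_expression(table_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix and its design sheet.

    The matrix header row holds sample_ids, the first column transcript
    ids.  Sample sets must match exactly; non-numeric or blank cells are
    hard errors naming the offending transcript and sample.
    """
    design = read_design(design_path)
    raw = pd.read_csv(table_path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    matrix_ids, design_ids = set(raw.columns), set(design.index)
    if matrix_ids != design_ids:
        only_m = sorted(matrix_ids - design_ids)
        only_d = sorted(design_ids - matrix_ids)
        raise ValueError(
            f"sample_ids disagree between matrix and design: "
            f"matrix-only={only_m}, design-only={only_d}"
        )

    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = np.argwhere(values.isna().values)[0]
        raise ValueError(
            f"non-numeric or blank cell at transcript {values.index[bad[0]]!r}, "
            f"sample {values.columns[bad[1]]!r}"
        )
    # align column order to the design sheet
    values = values.loc[:, design.index]
    return ExpressionMatrix(values=values, design=design)


def summarize_probes(probe_values: pd.DataFrame, probe_sets: Sequence[str]) -> pd.DataFrame:
    """Collapse per-probe intensities to one row per probe set.

    Each probe-set row is the median over the set's probes within each
    sample; even-sized sets use the midpoint of the two central order
    statistics.
    """
    probe_sets = pd.Series(list(probe_sets), index=probe_values.index, name="probe_set")
    if len(probe_sets) != len(probe_values):
        raise ValueError("one probe-set id per probe row required")
    if probe_sets.isna().any() or (probe_sets == "").any():
        raise ValueError("empty probe-set id")
    return probe_values.groupby(probe_sets).median()


def median_standardize(m: ExpressionMatrix, target: float | None = None) -> ExpressionMatrix:
    """Shift each sample (additively, log2 scale) to a common median.

    The target defaults to the global median of per-sample medians, so an
    already-standardized matrix is left unchanged.
    """
    medians = m.values.median(axis=0)
    if target is None:
        target = float(medians.median())
    shifted = m.values + (target - medians)
    return replace(m, values=shifted)


def filter_background(
    m: ExpressionMatrix,
    negative_control_values: Iterable[float],
    quantile: float = 0.95,
    per_sex: bool = False,
) -> ExpressionMatrix:
    """Drop transcripts below background under every treatment.

    The background threshold is a quantile (default 95th) of the
    negative-control log2 intensities; a transcript is retained if its
    per-treatment mean (pooled over sexes and replicates by default)
    exceeds the threshold in at least one treatment.
    """
    controls = np.asarray(list(negative_control_values), dtype=float)
    if controls.size == 0:
        raise ValueError("negative-control distribution is empty")
    threshold = float(np.quantile(controls, quantile))

    if per_sex:
        above = pd.Series(False, index=m.values.index)
        for sex in SEXES:
            if (m.design["sex"] == sex).any():
                above |= (m.group_means(sex) > threshold).any(axis=1)
    else:
        above = (m.group_means() > threshold).any(axis=1)

    if not above.any():
        warnings.warn("all transcripts fall below background; empty matrix returned")
    return replace(m, values=m.values.loc[above], background_threshold=threshold)


def sex_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each transcript's per-sex mean across all conditions.

    Per sex, the mean of the treatment means becomes zero for every
    transcript, so both sexes contribute deviations on a common scale.
    Between-treatment contrasts within a sex are unchanged.
    """
    present = set(m.design["sex"])
    absent = set(SEXES) - present
    if absent:
        raise ValueError(f"sex-centering needs both sexes; missing {sorted(absent)}")
    centered = m.values.copy()
    for sex in SEXES:
        cols = m.design.index[m.design["sex"] == sex]
        sex_mean = m.group_means(sex).mean(axis=1)
        centered.loc[:, cols] = centered.loc[:, cols].sub(sex_mean, axis=0)
    return replace(m, values=centered, centering="sex_centered")


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a result table as TSV with a JSON sidecar of run parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(params, indent=2, default=str) + "\n")


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, design_path: str | Path) -> None:
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(matrix_path, sep="\t")
    m.design.to_csv(design_path, sep="\t")
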