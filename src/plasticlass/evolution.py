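"""Molecular-evolution summaries across transcript classes.

Consumes per-gene tables: polymorphism/divergence counts (Pn, Ps, Dn,
Ds) for the McDonald-Kreitman alpha, per-gene omega (dN/dS) values, and
gene x species homolog presence tables.  Distribution differences
between classes are tested with the log-likelihood-ratio G-test on
binned counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def mk_alpha(table: pd.DataFrame) -> pd.Series:
    """Per-gene McDonald-Kreitman alpha: 1 - (Pn/Ps)(Ds/Dn).

    The estimated fraction of adaptive nonsynonymous fixations.
    Undefined (NaN) when Ps = 0 or Dn = 0.
    """
    required = {"Pn", "Ps", "Dn", "Ds"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if (table[list(required)] < 0).any().any():
        raise ValueError("counts must be nonnegative")
    Pn, Ps = table["Pn"].astype(float), table["Ps"].astype(float)
    Dn, Ds = table["Dn"].astype(float), table["Ds"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = 1.0 - (Pn / Ps) * (Ds / Dn)
    alpha[(Ps == 0) | (Dn == 0)] = np.nan
    return alpha.rename("alpha")


def _pool_sparse_bins(counts: np.ndarray, min_expected: float = 1.0) -> np.ndarray:
    """Merge adjacent bin columns until every independence-expected count
    is at least ``min_expected`` (chi-square validity)."""
    counts = counts.astype(float)
    while counts.shape[1] > 2:
        total = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
        bad = np.flatnonzero((expected < min_expected).any(axis=0))
        if bad.size == 0:
            break
        j = bad[0]
        k = j + 1 if j + 1 < counts.shape[1] else j - 1
        lo, hi = min(j, k), max(j, k)
        counts[:, lo] += counts[:, hi]
        counts = np.delete(counts, hi, axis=1)
    return counts


def g_test(counts, pool: bool = True, min_expected: float = 1.0) -> tuple[float, int, float]:
    """Log-likelihood-ratio G-test of independence on a class x bin table.

    G = 2 sum O ln(O/E) with independence expectations; df =
    (rows-1)(cols-1); p from the chi-square tail.  Bins with expected
    count below ``min_expected`` are pooled with a neighbor first.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an m x k contingency table with m, k >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    if pool:
        counts = _pool_sparse_bins(counts, min_expected)
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(counts / expected), 0.0)
    G = float(2.0 * terms.sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return G, df, float(stats.chi2.sf(G, df))


def homolog_fraction(
    presence: pd.DataFrame, class_labels: pd.Series, missing_as_absent: bool = True
) -> pd.DataFrame:
    """Percent of genes per class with a homolog in each species.

    ``presence`` is a gene x species 0/1 table.  Genes classed but
    absent from the table are counted as having no homolog (warned),
    unless ``missing_as_absent`` is False, in which case they are
    dropped from the denominators.
    """
    missing = class_labels.index.difference(presence.index)
    if len(missing):
        warnings.warn(f"{len(missing)} classed gene(s) missing from the homolog table")
        if not missing_as_absent:
            class_labels = class_labels.drop(missing)
    aligned = presence.reindex(class_labels.index).fillna(0).astype(bool)
    out = {}
    for label, sub in aligned.groupby(class_labels):
        out[label] = 100.0 * sub.mean(axis=0)
    return pd.DataFrame(out).T


def compare_distributions(
    values: pd.Series,
    class_labels: pd.Series,
    bins: int | np.ndarray = 10,
    reference: str = "robust",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin per-gene values by class and G-test each class against robust.

    Default binning: equal-width bins on [0, max].  Returns the binned
    class x bin count table and a per-class results frame (G, df, p);
    empty classes are skipped with a warning.
    """
    values = values.dropna()
    labels = class_labels.reindex(values.index)
    if np.isscalar(bins):
        edges = np.linspace(0.0, float(values.max()), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    binned = pd.cut(values, edges, include_lowest=True)
    counts = pd.crosstab(labels, binned, dropna=False)
    if reference not in counts.index:
        raise ValueError(f"reference class {reference!r} absent")
    rows = []
    for label in counts.index:
        if label == reference:
            continue
        if counts.loc[label].sum() == 0:
            warnings.warn(f"class {label!r} empty; skipped")
            continue
        table = counts.loc[[label, reference]].values
        table = table[:, table.sum(axis=0) > 0]
        G, df, p = g_test(table)
        rows.append({"class": label, "G": G, "df": df, "p": p})
    return counts, pd.DataFrame(rows)
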