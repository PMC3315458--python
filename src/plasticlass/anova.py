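"""Per-transcript fixed-effects variance partition and post-hoc contrasts.

Each transcript is fit by ordinary least squares to

    Y = mu + S + E + SxE + eps

with sum-to-zero contrasts, so on balanced designs the term F statistics
reproduce the classical two-way decomposition and on unbalanced cells
they are Type-III tests (full model vs the model with the term's columns
dropped).  FDR control is Benjamini-Hochberg per term across transcripts.
Post-hoc LSD contrasts compare every treatment against the standard
condition using the pooled residual mean square, uncorrected across
treatments (the LSD convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

_ZERO_RESID_TOL = 1e-10


@dataclass
class AnovaResult:
    """Per-transcript F, p and BH-adjusted q for sex, environment, interaction."""

    table: pd.DataFrame  # F_*, p_*, q_* per transcript
    df_resid: int
    mse: pd.Series

    def flags(self, term: str, q_level: float = 0.05) -> pd.Series:
        return self.table[f"q_{term}"] < q_level


def _sum_to_zero(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding; last level is the reference."""
    levels = sorted(pd.unique(labels))
    k = len(levels)
    X = np.zeros((len(labels), k - 1))
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
    X[labels == levels[-1], :] = -1.0
    return X, levels


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n x G) on X, per column of Y."""
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", proj, proj)


def bh_fdr(p: np.ndarray | pd.Series, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted values and rejection flags."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def fit_two_way_anova(m: ExpressionMatrix) -> AnovaResult:
    """Vectorized two-way (sex x treatment) ANOVA over all transcripts."""
    design = m.design
    sexes = design["sex"].values
    groups = design["group"].values
    cells = pd.crosstab(pd.Series(sexes), pd.Series(groups))
    if (cells == 0).any().any():
        empty = [
            (s, g) for s in cells.index for g in cells.columns if cells.loc[s, g] == 0
        ]
        raise ValueError(f"empty sex x treatment cells: {empty}")
    if len(cells.index) < 2 or len(cells.columns) < 2:
        raise ValueError("need at least 2 sexes and 2 treatments")

    S, _ = _sum_to_zero(sexes)
    E, _ = _sum_to_zero(groups)
    inter = np.einsum("ni,nj->nij", S, E).reshape(len(sexes), -1)
    ones = np.ones((len(sexes), 1))
    X_full = np.hstack([ones, S, E, inter])

    Y = m.values.values.T  # samples x transcripts
    n, G = Y.shape
    p_full = X_full.shape[1]
    df_resid = n - p_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (need replicates)")

    rss_full = _rss(X_full, Y)
    terms = {
        "sex": (np.hstack([ones, E, inter]), S.shape[1]),
        "env": (np.hstack([ones, S, inter]), E.shape[1]),
        "int": (np.hstack([ones, S, E]), inter.shape[1]),
    }

    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    degenerate = rss_full < _ZERO_RESID_TOL * scale
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} transcript(s) with zero residual variance; "
            "p-values set by convention (0 if the term SS > 0, else 1)"
        )

    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = rss_full / df_resid
        for term, (X_red, df_term) in terms.items():
            ss_term = _rss(X_red, Y) - rss_full
            ss_term = np.maximum(ss_term, 0.0)
            F = (ss_term / df_term) / mse
            p = stats.f.sf(F, df_term, df_resid)
            if degenerate.any():
                term_nonzero = ss_term > _ZERO_RESID_TOL * scale
                p = np.where(degenerate, np.where(term_nonzero, 0.0, 1.0), p)
                F = np.where(degenerate, np.where(term_nonzero, np.inf, 0.0), F)
            out[f"F_{term}"] = F
            out[f"p_{term}"] = p

    table = pd.DataFrame(out, index=m.values.index)
    for term in terms:
        table[f"q_{term}"], _ = bh_fdr(table[f"p_{term}"].values)
    return AnovaResult(table=table, df_resid=df_resid, mse=pd.Series(mse, index=m.values.index))


def fit_one_way_anova(m: ExpressionMatrix) -> pd.DataFrame:
    """One-way ANOVA per transcript on ``group`` (e.g. Y = mu + line + eps)."""
    groups = m.design["group"].values
    G, _ = _sum_to_zero(groups)
    ones = np.ones((len(groups), 1))
    X_full = np.hstack([ones, G])
    Y = m.values.values.T
    n = Y.shape[0]
    df_g, df_resid = G.shape[1], n - X_full.shape[1]
    rss_full = _rss(X_full, Y)
    ss_g = np.maximum(_rss(ones, Y) - rss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_g / df_g) / (rss_full / df_resid)
    p = stats.f.sf(F, df_g, df_resid)
    q, _ = bh_fdr(p)
    return pd.DataFrame({"F": F, "p": p, "q": q}, index=m.values.index)


def genetic_variation_fdr(panel: ExpressionMatrix) -> pd.DataFrame:
    """Per-sex BH-adjusted p for among-line variation in the inbred panel.

    Returns a transcript x sex DataFrame of q-values; the Class II filter
    keeps transcripts whose q exceeds a stringent floor (little evidence
    of genetic variation).
    """
    out = {}
    for sex in ("female", "male"):
        out[sex] = fit_one_way_anova(panel.subset_sex(sex))["q"]
    return pd.DataFrame(out)


@dataclass
class LsdResult:
    """LSD contrasts of every non-standard treatment against the standard."""

    diff: pd.DataFrame  # transcripts x treatments, log2 mean difference
    tstat: pd.DataFrame
    pvalue: pd.DataFrame
    signs: pd.DataFrame  # -1 / 0 / +1, nonzero iff p < alpha
    standard: str
    alpha: float = 0.05


def lsd_contrasts(
    m: ExpressionMatrix,
    anova: AnovaResult,
    standard: str | None = None,
    transcripts: list[str] | None = None,
    alpha: float = 0.05,
) -> LsdResult:
    """Two-sided t tests of treatment means vs the standard condition.

    Uses the two-way ANOVA's pooled residual mean square and df;
    p-values are deliberately uncorrected across treatments.
    """
    standard = standard or m.standard_group
    if standard is None or standard not in set(m.design["group"]):
        raise ValueError(f"standard treatment {standard!r} absent from design")
    values = m.values if transcripts is None else m.values.loc[transcripts]
    mse = anova.mse if transcripts is None else anova.mse.loc[transcripts]

    means = values.T.groupby(m.design["group"]).mean().T
    counts = m.design["group"].value_counts()
    others = [t for t in means.columns if t != standard]

    diff = means[others].sub(means[standard], axis=0)
    se = pd.DataFrame(
        np.sqrt(np.outer(mse, [1.0 / counts[t] + 1.0 / counts[standard] for t in others])),
        index=diff.index, columns=others,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / se
    pval = pd.DataFrame(
        2.0 * stats.t.sf(np.abs(tstat.values), anova.df_resid),
        index=diff.index, columns=others,
    )
    signs = pd.DataFrame(
        np.where(pval.values < alpha, np.sign(diff.values), 0).astype(int),
        index=diff.index, columns=others,
    )
    return LsdResult(diff=diff, tstat=tstat, pvalue=pval, signs=signs,
                     standard=standard, alpha=alpha)


def treatment_overlap_counts(lsd: LsdResult) -> pd.DataFrame:
    """Pairwise counts of transcripts flagged under both of two treatments.

    The diagonal holds per-treatment flagged counts.
    """
    flagged = (lsd.signs != 0).astype(int)
    counts = flagged.T @ flagged
    return counts
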