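"""Trait-transcript association, residual modules, and pleiotropy tests.

Transcripts are associated with organismal phenotypic variation across
treatments by regressing the trait's treatment means on the transcript's
treatment-mean expression.  Traits with a significant sex-by-treatment
interaction are analyzed per sex; otherwise trait and expression are both
sex-centered and sexes pooled.  Residuals from the reverse regressions
(expression on trait) give environmental correlations that are clustered
into covariant modules; module overlap between traits is tested with a
hypergeometric tail probability and Bonferroni correction, ignoring pairs
sharing fewer than three transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import fit_two_way_anova
from .io import ExpressionMatrix, SEXES
from .modules import ModulePartition, mmc_cluster


def trait_interaction_flags(trait_reps: pd.DataFrame, alpha: float = 0.05) -> dict[str, bool]:
    """Per-trait sex-by-treatment interaction flag from replicate values.

    Fits the two-way fixed-effects model to each trait's replicate-level
    table (trait, treatment, sex, replicate, value) and flags traits whose
    interaction p-value falls below ``alpha``.
    """
    flags = {}
    for trait, sub in trait_reps.groupby("trait"):
        design = pd.DataFrame(
            {
                "sex": sub["sex"].values,
                "group": sub["treatment"].values,
                "replicate": sub["replicate"].values,
            },
            index=[f"s{i}" for i in range(len(sub))],
        )
        m = ExpressionMatrix(
            values=pd.DataFrame([sub["value"].values], index=[trait], columns=design.index),
            design=design,
        )
        res = fit_two_way_anova(m)
        flags[trait] = bool(res.table.loc[trait, "p_int"] < alpha)
    return flags


def _trait_wide(traits: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = traits[traits["trait"] == trait]
    return sub.pivot(index="treatment", columns="sex", values="mean")


def _paired_vectors(
    trait_wide: pd.DataFrame, expr_means: dict[str, pd.DataFrame], sexed: bool
):
    """Yield (mode, trait vector, expression matrix) pairings for regression.

    For sexed traits one pairing per sex; otherwise a single pooled
    pairing of sex-centered deviations (per-sex means removed from both
    trait and expression).  Treatments missing from the trait table are
    dropped pairwise.
    """
    if sexed:
        for sex in SEXES:
            y = trait_wide[sex].dropna()
            X = expr_means[sex].loc[:, y.index]
            yield f"per_sex_{sex}", y.values, X
    else:
        ys, Xs = [], []
        for sex in SEXES:
            y = trait_wide[sex].dropna()
            X = expr_means[sex].loc[:, y.index]
            ys.append(y.values - y.values.mean())
            Xs.append(X.sub(X.mean(axis=1), axis=0))
        yield "sex_centered", np.concatenate(ys), pd.concat(Xs, axis=1)


def associate_transcripts(
    traits: pd.DataFrame,
    m: ExpressionMatrix,
    transcript_ids: list[str],
    interaction_flags: dict[str, bool],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regress each trait on each transcript's treatment-mean expression.

    ``traits`` is tidy (trait, treatment, sex, mean, ...).  Returns one
    row per trait x transcript x mode with slope, p-value and a
    significance flag at ``alpha`` (two-sided slope test).
    """
    expr_means = {sex: m.group_means(sex).loc[transcript_ids] for sex in SEXES}
    rows = []
    for trait in traits["trait"].unique():
        wide = _trait_wide(traits, trait)
        sexed = interaction_flags[trait]
        for mode, y, X in _paired_vectors(wide, expr_means, sexed):
            n = len(y)
            x = X.values
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean()
            sxx = np.einsum("ij,ij->i", xc, xc)
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = (xc @ yc) / sxx
                resid_ss = np.maximum(yc @ yc - slope ** 2 * sxx, 0.0)
                se = np.sqrt(resid_ss / (n - 2) / sxx)
                tstat = slope / se
            p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
            p = np.where(np.isfinite(tstat), p, 0.0)  # exact fits: p -> 0 limit
            for gid, b, pv in zip(X.index, slope, p):
                rows.append(
                    {
                        "trait": trait,
                        "transcript": gid,
                        "mode": mode,
                        "slope": b,
                        "p": pv,
                        "significant": bool(pv < alpha),
                    }
                )
    return pd.DataFrame(rows)


def significant_ids(associations: pd.DataFrame, trait: str) -> list[str]:
    """Transcripts significantly associated with a trait (any analysis mode)."""
    sub = associations[(associations["trait"] == trait) & associations["significant"]]
    return sorted(sub["transcript"].unique())


def residualize_on_trait(
    m: ExpressionMatrix,
    traits: pd.DataFrame,
    trait: str,
    transcript_ids: list[str],
    sexed: bool,
) -> pd.DataFrame:
    """Residuals of expression treatment means on the trait covariate.

    Per transcript, least-squares residuals of the per-treatment mean
    expression on the trait value (per sex when the trait is sexed, else
    on pooled sex-centered deviations).  Residuals are orthogonal to the
    trait covariate.  Columns are the stacked (sex, treatment) points.
    """
    if not transcript_ids:
        raise ValueError("significant transcript set is empty")
    expr_means = {sex: m.group_means(sex).loc[transcript_ids] for sex in SEXES}
    wide = _trait_wide(traits, trait)
    blocks = []
    for mode, y, X in _paired_vectors(wide, expr_means, sexed):
        x = np.asarray(y, dtype=float)
        xc = x - x.mean()
        E = X.values
        Ec = E - E.mean(axis=1, keepdims=True)
        denom = xc @ xc
        slope = (Ec @ xc) / denom if denom > 0 else np.zeros(E.shape[0])
        resid = Ec - np.outer(slope, xc)
        cols = [f"{mode}:{t}" for t in X.columns]
        blocks.append(pd.DataFrame(resid, index=X.index, columns=cols))
    return pd.concat(blocks, axis=1)


def trait_modules(residuals: pd.DataFrame, seed: int = 0) -> tuple[ModulePartition, np.ndarray]:
    """Cluster trait-associated transcripts on residual correlations."""
    if len(residuals) < 2:
        part = ModulePartition(
            modules=pd.Series(1, index=residuals.index, dtype=int),
            modularity=0.0,
            sigma=float("nan"),
        )
        return part, np.ones((len(residuals), len(residuals)))
    r = np.corrcoef(residuals.values)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return mmc_cluster(list(residuals.index), r, seed=seed), r


def pleiotropy_overlap(
    partition_a: ModulePartition,
    partition_b: ModulePartition,
    universe_size: int,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Hypergeometric module-overlap (pleiotropy) test between two traits.

    For modules A (size K) and B (size n) over a universe of N
    transcripts sharing k: p = P(X >= k), X ~ Hypergeom(N, K, n).
    Bonferroni correction over the considered pairs; pairs sharing fewer
    than ``min_shared`` transcripts are reported but not considered.
    """
    sizes_a = partition_a.modules.value_counts()
    sizes_b = partition_b.modules.value_counts()
    if universe_size < max(sizes_a.max(), sizes_b.max()):
        raise ValueError("universe smaller than a module")
    rows = []
    for ma in sorted(sizes_a.index):
        set_a = set(partition_a.members(ma))
        for mb in sorted(sizes_b.index):
            set_b = set(partition_b.members(mb))
            shared = len(set_a & set_b)
            p = float(
                stats.hypergeom.sf(shared - 1, universe_size, len(set_a), len(set_b))
            )
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "size_a": len(set_a),
                    "size_b": len(set_b),
                    "shared": shared,
                    "p": p,
                    "considered": shared >= min_shared,
                }
            )
    out = pd.DataFrame(rows)
    n_tests = int(out["considered"].sum())
    out["p_bonferroni"] = np.where(
        out["considered"], np.minimum(out["p"] * max(n_tests, 1), 1.0), np.nan
    )
    return out
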