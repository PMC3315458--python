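"""Covariant-module clustering of plastic transcripts.

Transcripts are grouped by maximizing weighted-graph modularity on a
sharpened |correlation| graph (MMC-style).  Edge weights are
exp(-(1-|r|)^2 / (2 sigma^2)); the sharpening parameter sigma is chosen
by grid search to maximize the modularity of the best partition found by
the Leiden algorithm (seeded, hence deterministic).  Modules are ordered
by decreasing strength (mean within-module |r|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SEXES

DEFAULT_SIGMAS = tuple(np.geomspace(0.05, 1.0, 10))


def treatment_correlations(
    m: ExpressionMatrix, ids: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Pearson correlations of sex-centered per-treatment mean profiles.

    Profiles stack the female and male per-treatment means (so 20
    treatments x 2 sexes give 40 points).  Zero-variance transcripts are
    excluded with a warning.
    """
    if m.centering != "sex_centered":
        raise ValueError("treatment correlations require a sex-centered matrix")
    profiles = pd.concat(
        [m.group_means(sex) for sex in SEXES if (m.design["sex"] == sex).any()], axis=1
    )
    if ids is not None:
        profiles = profiles.loc[ids]
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 conditions for correlations")
    sd = profiles.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance transcript(s) excluded from correlations"
        )
        profiles = profiles.loc[keep]
    r = np.atleast_2d(np.corrcoef(profiles.values))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return list(profiles.index), r


@dataclass
class ModulePartition:
    """Transcript -> module map with strength ordering diagnostics."""

    modules: pd.Series  # transcript -> module id (1 = strongest)
    modularity: float
    sigma: float

    @property
    def n_modules(self) -> int:
        return int(self.modules.nunique())

    def members(self, module_id: int) -> list[str]:
        return list(self.modules.index[self.modules == module_id])


def _sharpen(r_abs: np.ndarray, sigma: float) -> np.ndarray:
    w = np.exp(-((1.0 - r_abs) ** 2) / (2.0 * sigma ** 2))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


def _within_strength(r: np.ndarray, members: np.ndarray) -> float:
    """Mean |r| over distinct pairs within a module; singletons get 0."""
    if len(members) < 2:
        return 0.0
    sub = np.abs(r[np.ix_(members, members)])
    iu = np.triu_indices_from(sub, k=1)
    return float(sub[iu].mean())


def mmc_cluster(
    ids: list[str],
    r: np.ndarray,
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS,
    seed: int = 0,
) -> ModulePartition:
    """Partition transcripts into covariant modules by modularity maximization.

    For each candidate sigma the sharpened |r| graph is clustered with
    Leiden (modularity objective); the sigma whose partition attains the
    highest weighted modularity wins.  Modules are relabeled 1..K in
    order of decreasing mean within-module |r|.
    """
    n = len(ids)
    if n < 2:
        return ModulePartition(
            modules=pd.Series(1, index=ids, dtype=int), modularity=0.0, sigma=float("nan")
        )
    r_abs = np.abs(np.asarray(r, dtype=float))

    best = None
    for sigma in sigmas:
        w = _sharpen(r_abs, float(sigma))
        g = ig.Graph.Weighted_Adjacency(w.tolist(), mode="undirected", attr="weight", loops=False)
        part = la.find_partition(
            g, la.ModularityVertexPartition, weights="weight", seed=seed, n_iterations=-1
        )
        q = g.modularity(part.membership, weights="weight")
        if best is None or q > best[0]:
            best = (q, float(sigma), np.asarray(part.membership))

    q, sigma, membership = best
    # order modules by decreasing strength, then decreasing size for stability
    strengths = {}
    for mod in np.unique(membership):
        members = np.flatnonzero(membership == mod)
        strengths[mod] = (_within_strength(r, members), len(members))
    ordered = sorted(strengths, key=lambda mkey: (-strengths[mkey][0], -strengths[mkey][1], mkey))
    relabel = {old: new + 1 for new, old in enumerate(ordered)}
    modules = pd.Series([relabel[mod] for mod in membership], index=ids, dtype=int)
    return ModulePartition(modules=modules, modularity=float(q), sigma=sigma)


def module_diagnostics(
    partition: ModulePartition, r: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within- and cross-module mean |r| diagnostics.

    Returns (per-module summary, cross-module mean |r| matrix).  The
    summary holds size, mean within-module |r| (NaN for singletons) and
    the fraction of negative within-module correlations.
    """
    ids = list(partition.modules.index)
    idx = {t: i for i, t in enumerate(ids)}
    r = np.asarray(r, dtype=float)
    mods = sorted(partition.modules.unique())
    rows = []
    cross = pd.DataFrame(np.nan, index=mods, columns=mods)
    members = {mod: np.array([idx[t] for t in partition.members(mod)]) for mod in mods}
    for mod in mods:
        mi = members[mod]
        if len(mi) >= 2:
            sub = r[np.ix_(mi, mi)]
            iu = np.triu_indices_from(sub, k=1)
            within = float(np.abs(sub[iu]).mean())
            neg = float((sub[iu] < 0).mean())
        else:
            within, neg = np.nan, np.nan
        rows.append({"module": mod, "size": len(mi), "within_mean_abs_r": within,
                     "frac_negative_r": neg})
        cross.loc[mod, mod] = within
        for other in mods:
            if other <= mod:
                continue
            block = np.abs(r[np.ix_(mi, members[other])])
            cross.loc[mod, other] = cross.loc[other, mod] = float(block.mean())
    return pd.DataFrame(rows).set_index("module"), cross
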