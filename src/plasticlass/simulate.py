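"""Synthetic data generator with planted transcript classes.

Emulates the two experimental designs the pipeline consumes:

* an outbred multi-environment experiment (20 treatments x 2 sexes x 3
  replicates) in which Class I transcripts carry additive treatment
  effects and Class II transcripts carry a treatment-redrawn
  macroenvironmental random effect plus strongly inflated
  within-treatment noise (which is what hides them from the omnibus
  treatment F test);
* an inbred reference panel (40 lines x 2 sexes x 2 replicates) in which
  line effects supply genetic variance — amplified for Class I, shrunken
  for Class II.

Organismal trait tables linearly linked to chosen Class I transcripts and
polymorphism/divergence count tables with a known adaptive fraction are
generated for the downstream association and molecular-evolution stages.
All draws are Normal on the log2 scale; every operation takes an explicit
seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

ROBUST, CLASS_I, CLASS_II = "robust", "classI", "classII"


@dataclass
class SimulationConfig:
    """Study-design and effect-size knobs for the generator.

    Effect sizes are log2 units.  Class II baselines are drawn from the
    upper half of the expression range because their macroenvironmental
    variance tracks mean expression; their within-treatment noise is
    inflated (``classII_within_sd``) so the treatment F test has little
    power on them, and their inbred-line effects are shrunken
    (``classII_line_shrink``) so genetic variance stays low.
    """

    n_transcripts: int = 2000
    n_treatments: int = 20
    n_lines: int = 40
    n_replicates: int = 3
    panel_replicates: int = 2
    class_fractions: tuple[float, float, float] = (0.875, 0.075, 0.05)  # robust, I, II
    treatment_effect_sd: float = 1.0
    min_affected_treatments: int = 3
    max_affected_treatments: int = 6
    interaction_fraction: float = 0.0
    interaction_effect_sd: float = 1.0
    line_effect_sd: float = 0.5
    classI_line_scale: float = 1.5
    classII_line_shrink: float = 0.1
    within_noise_sd: float = 0.25
    classII_macroenv_sd: float = 1.0
    classII_within_sd: float = 5.0
    sex_bias_sd: float = 0.5
    classII_sex_bias_sd: float = 2.0
    sex_plasticity_anticorr: float = 0.7
    baseline_range: tuple[float, float] = (4.0, 14.0)
    classII_baseline_range: tuple[float, float] = (8.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.class_fractions), 1.0):
            raise ValueError("class_fractions must sum to 1")
        for name in (
            "treatment_effect_sd", "line_effect_sd", "within_noise_sd",
            "classII_macroenv_sd", "classII_within_sd", "sex_bias_sd",
            "classII_sex_bias_sd", "interaction_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def class_counts(self) -> dict[str, int]:
        n = self.n_transcripts
        n1 = int(round(n * self.class_fractions[1]))
        n2 = int(round(n * self.class_fractions[2]))
        return {ROBUST: n - n1 - n2, CLASS_I: n1, CLASS_II: n2}


@dataclass
class GroundTruth:
    """Planted structure the pipeline is asked to recover."""

    labels: pd.Series  # transcript -> robust / classI / classII
    baseline: pd.Series  # transcript -> mean log2 expression
    sex_bias: pd.Series  # transcript -> female mean minus male mean
    classI_effects: dict[str, dict[str, float]]  # transcript -> {treatment: effect}
    interaction_ids: list[str] = field(default_factory=list)
    classII_sex_scale: pd.DataFrame | None = None  # per Class II transcript x sex
    trait_links: dict[str, dict[str, float]] = field(default_factory=dict)

    def ids(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _treatments(n: int) -> list[str]:
    return [f"T{i + 1:02d}" for i in range(n)]


def _lines(n: int) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(n)]


def _transcripts(n: int) -> list[str]:
    return [f"g{i + 1:05d}" for i in range(n)]


def _outbred_design(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in _treatments(cfg.n_treatments):
        for sex in ("female", "male"):
            for r in range(1, cfg.n_replicates + 1):
                rows.append((f"{t}_{sex[0]}{r}", sex, t, r, t == "T01"))
    return pd.DataFrame(
        rows, columns=["sample_id", "sex", "group", "replicate", "is_standard"]
    ).set_index("sample_id")


def _panel_design(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for ln in _lines(cfg.n_lines):
        for sex in ("female", "male"):
            for r in range(1, cfg.panel_replicates + 1):
                rows.append((f"{ln}_{sex[0]}{r}", sex, ln, r))
    return pd.DataFrame(
        rows, columns=["sample_id", "sex", "group", "replicate"]
    ).set_index("sample_id")


def simulate_outbred(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the outbred multi-environment expression matrix.

    Per transcript g, sex s, treatment e, replicate r:

        y = mu_g + (+-) beta_g / 2 + gamma_{g,e} [Class I]
            + (+-) delta_{g,e} / 2 [planted interaction]
            + eta_{g,e} * scale_{g,s} [Class II] + eps

    with eta redrawn per treatment and eps ~ N(0, within sd^2); the
    within sd itself is inflated and sex-scaled for Class II.  The
    per-sex Class II amplitude scale is anti-correlated with the sex
    bias of the mean (a female-biased mean implies male-biased
    plasticity), with strength ``sex_plasticity_anticorr``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.class_counts
    ids = _transcripts(cfg.n_transcripts)
    labels = pd.Series(
        [CLASS_I] * counts[CLASS_I] + [CLASS_II] * counts[CLASS_II]
        + [ROBUST] * counts[ROBUST],
        index=ids, name="label",
    )
    is1 = (labels == CLASS_I).values
    is2 = (labels == CLASS_II).values

    lo, hi = cfg.baseline_range
    baseline = rng.uniform(lo, hi, cfg.n_transcripts)
    lo2, hi2 = cfg.classII_baseline_range
    baseline[is2] = rng.uniform(lo2, hi2, is2.sum())

    sex_bias = rng.normal(0.0, cfg.sex_bias_sd, cfg.n_transcripts)
    sex_bias[is2] = rng.normal(0.0, cfg.classII_sex_bias_sd, is2.sum())

    treatments = _treatments(cfg.n_treatments)
    classI_effects: dict[str, dict[str, float]] = {}
    effect_matrix = np.zeros((cfg.n_transcripts, cfg.n_treatments))
    for gi in np.flatnonzero(is1):
        k = int(rng.integers(cfg.min_affected_treatments, cfg.max_affected_treatments + 1))
        which = rng.choice(cfg.n_treatments, size=k, replace=False)
        effects = rng.normal(0.0, cfg.treatment_effect_sd, k)
        effect_matrix[gi, which] = effects
        classI_effects[ids[gi]] = {treatments[j]: float(e) for j, e in zip(which, effects)}

    n_int = int(round(cfg.interaction_fraction * counts[CLASS_I]))
    interaction_ids = [ids[i] for i in np.flatnonzero(is1)[:n_int]]
    int_matrix = np.zeros((cfg.n_transcripts, cfg.n_treatments))
    for gid in interaction_ids:
        gi = ids.index(gid)
        which = rng.choice(cfg.n_treatments, size=3, replace=False)
        int_matrix[gi, which] = rng.normal(0.0, cfg.interaction_effect_sd, 3)

    # Class II: shared macroenvironmental draw per treatment, per-sex
    # amplitude anti-correlated with the sex bias of the mean; amplitudes
    # clipped to [0.5, 2] so extreme biases cannot inflate the noise to the
    # point of non-positive intensities
    a = cfg.sex_plasticity_anticorr
    scale_f = np.clip(np.exp(-a * sex_bias / 2.0), 0.5, 2.0)
    scale_m = np.clip(np.exp(+a * sex_bias / 2.0), 0.5, 2.0)
    eta = np.zeros((cfg.n_transcripts, cfg.n_treatments))
    eta[is2] = rng.normal(0.0, cfg.classII_macroenv_sd, (is2.sum(), cfg.n_treatments))

    design = _outbred_design(cfg)
    values = np.empty((cfg.n_transcripts, len(design)))
    sexes = design["sex"].values
    tidx = np.array([treatments.index(g) for g in design["group"]])
    for ci, (sex, ti) in enumerate(zip(sexes, tidx)):
        sgn = 0.5 if sex == "female" else -0.5
        scale = scale_f if sex == "female" else scale_m
        mean = (
            baseline
            + sgn * sex_bias
            + effect_matrix[:, ti]
            + sgn * int_matrix[:, ti]
        )
        mean = mean + np.where(is2, eta[:, ti] * scale, 0.0)
        noise_sd = np.where(is2, cfg.classII_within_sd * scale, cfg.within_noise_sd)
        values[:, ci] = mean + rng.normal(0.0, 1.0, cfg.n_transcripts) * noise_sd

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=design.index), design=design
    )
    class2_ids = [ids[i] for i in np.flatnonzero(is2)]
    truth = GroundTruth(
        labels=labels,
        baseline=pd.Series(baseline, index=ids, name="baseline"),
        sex_bias=pd.Series(sex_bias, index=ids, name="sex_bias"),
        classI_effects=classI_effects,
        interaction_ids=interaction_ids,
        classII_sex_scale=pd.DataFrame(
            {"female": scale_f[is2], "male": scale_m[is2]}, index=class2_ids
        ),
    )
    return matrix, truth


def simulate_inbred_panel(cfg: SimulationConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Simulate the matched inbred-line reference panel.

    Line effects ~ N(0, line sd^2), scaled up for Class I (genetically
    variable) and shrunken by ``classII_line_shrink`` for Class II so
    the coefficient of variation among lines (CVL) is low for Class II.
    Replicate noise uses the baseline within-noise sd for all classes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    ids = list(truth.labels.index)
    labels = truth.labels.values
    n = len(ids)
    line_sd = np.full(n, cfg.line_effect_sd)
    line_sd[labels == CLASS_I] *= cfg.classI_line_scale
    line_sd[labels == CLASS_II] *= cfg.classII_line_shrink

    design = _panel_design(cfg)
    lines = _lines(cfg.n_lines)
    line_effects = rng.normal(0.0, 1.0, (n, cfg.n_lines)) * line_sd[:, None]

    baseline = truth.baseline.values
    sex_bias = truth.sex_bias.values
    values = np.empty((n, len(design)))
    lidx = np.array([lines.index(g) for g in design["group"]])
    for ci, (sex, li) in enumerate(zip(design["sex"].values, lidx)):
        sgn = 0.5 if sex == "female" else -0.5
        mean = baseline + sgn * sex_bias + line_effects[:, li]
        values[:, ci] = mean + rng.normal(0.0, cfg.within_noise_sd, n)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=design.index), design=design
    )


def simulate_phenotypes(
    truth: GroundTruth,
    matrix: ExpressionMatrix,
    n_traits: int = 4,
    n_linked: int = 2,
    link_strength: float = 1.0,
    noise_sd: float = 0.2,
    n_replicates: int = 4,
    n_sexed_traits: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate organismal trait tables linked to planted Class I transcripts.

    Each trait's treatment x sex cell mean is an intercept plus
    ``link_strength`` times the per-sex treatment-mean expression of its
    linked transcripts, plus N(0, noise_sd^2).  The first
    ``n_sexed_traits`` traits (default half) use sex-specific link
    coefficients, which plants a sex-by-treatment interaction.  Returns a
    tidy replicate-level table (trait, treatment, sex, replicate, value);
    aggregate with :func:`trait_means` for the mean/se form.
    """
    rng = np.random.default_rng(seed)
    class1 = truth.ids(CLASS_I)
    if len(class1) < n_linked:
        raise ValueError("not enough planted Class I transcripts to link traits")
    if n_sexed_traits is None:
        n_sexed_traits = n_traits // 2

    # traits respond to robustly plastic transcripts: link candidates are the
    # upper half of Class I by planted effect magnitude
    magnitude = {
        g: float(np.sqrt(sum(e ** 2 for e in truth.classI_effects[g].values())))
        for g in class1
    }
    cut = float(np.median(list(magnitude.values())))
    candidates = [g for g in class1 if magnitude[g] >= cut]

    rows = []
    for ti in range(n_traits):
        trait = f"trait{ti + 1}"
        linked = rng.choice(candidates, size=n_linked, replace=False)
        coefs = {g: link_strength for g in linked}
        truth.trait_links[trait] = coefs
        sexed = ti < n_sexed_traits
        pooled = matrix.group_means()  # shared signal for non-sexed traits
        for sex in ("female", "male"):
            if sexed:
                mult = 1.5 if sex == "female" else 0.5
                gm = matrix.group_means(sex)
            else:
                mult, gm = 1.0, pooled
            # unit-variance profiles: every linked transcript contributes
            # equally, so link_strength / noise_sd set the planted SNR
            signal = sum(
                c * mult * (gm.loc[g] - gm.loc[g].mean()) / gm.loc[g].std(ddof=1)
                for g, c in coefs.items()
            )
            for treatment in gm.columns:
                cell = 10.0 + signal[treatment]
                for r in range(1, n_replicates + 1):
                    rows.append(
                        (trait, treatment, sex, r, cell + rng.normal(0.0, noise_sd))
                    )
    return pd.DataFrame(rows, columns=["trait", "treatment", "sex", "replicate", "value"])


def trait_means(trait_reps: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate-level trait values to the mean/se table."""
    g = trait_reps.groupby(["trait", "treatment", "sex"])["value"]
    out = g.agg(mean="mean", se="sem", n="count").reset_index()
    return out


def simulate_mk_tables(
    n_genes: int, alpha_true: float, depth: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate per-gene polymorphism/divergence count tables.

    Counts are Poisson with expectations E[Ps] = E[Ds] = E[Dn] = depth and
    E[Pn] = depth * (1 - alpha_true), so the expected counts satisfy
    1 - (Pn/Ps)(Ds/Dn) = alpha_true.
    """
    if not 0 <= alpha_true < 1:
        raise ValueError("alpha_true must be in [0, 1)")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    lam = np.array([depth * (1 - alpha_true), depth, depth, depth], dtype=float)
    counts = rng.poisson(lam, size=(n_genes, 4))
    return pd.DataFrame(
        counts,
        columns=["Pn", "Ps", "Dn", "Ds"],
        index=[f"gene{i + 1:04d}" for i in range(n_genes)],
    )
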