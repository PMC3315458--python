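import warnings

import numpy as np
import pandas as pd
import pytest

import plasticlass as pl


def make_matrix(values, sexes, groups, replicates=None, standard=None):
    """Assemble an ExpressionMatrix from parallel per-sample metadata lists."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    sample_ids = [f"s{i + 1}" for i in range(n)]
    design = pd.DataFrame(
        {
            "sex": sexes,
            "group": groups,
            "replicate": replicates or [1] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if standard is not None:
        design["is_standard"] = [g == standard for g in groups]
    vals = pd.DataFrame(
        values, index=[f"g{i + 1}" for i in range(values.shape[0])], columns=sample_ids
    )
    return pl.ExpressionMatrix(values=vals, design=design)


def balanced_design(n_treatments=3, n_reps=2, n_transcripts=1, rng=None, noise=1.0):
    """Balanced 2-sex x treatment x replicate design with pure-noise values."""
    rng = rng or np.random.default_rng(0)
    sexes, groups, reps = [], [], []
    for t in range(n_treatments):
        for sex in ("female", "male"):
            for r in range(n_reps):
                sexes.append(sex)
                groups.append(f"T{t + 1:02d}")
                reps.append(r + 1)
    values = 8.0 + rng.normal(0.0, noise, (n_transcripts, len(sexes)))
    return make_matrix(values, sexes, groups, reps, standard="T01")


@pytest.fixture(scope="session")
def sim400():
    """Default-parameter simulation at 400 transcripts with its panel."""
    cfg = pl.SimulationConfig(n_transcripts=400, seed=11)
    matrix, truth = pl.simulate_outbred(cfg)
    panel = pl.simulate_inbred_panel(cfg, truth)
    return cfg, matrix, truth, panel


@pytest.fixture(scope="session")
def run400(sim400):
    _, matrix, _, panel = sim400
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.classify_transcriptome(matrix, panel)
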