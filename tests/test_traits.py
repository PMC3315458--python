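import itertools
import math

import numpy as np
import pandas as pd
import pytest

import plasticlass as pl
from plasticlass.modules import ModulePartition


@pytest.fixture(scope="module")
def linked_world():
    cfg = pl.SimulationConfig(n_transcripts=300, seed=19)
    matrix, truth = pl.simulate_outbred(cfg)
    reps = pl.simulate_phenotypes(truth, matrix, seed=19)
    flags = pl.trait_interaction_flags(reps)
    means = pl.trait_means(reps)
    return matrix, truth, reps, flags, means


class TestInteractionFlags:
    def test_sexed_traits_flagged_others_not(self, linked_world):
        _, _, _, flags, _ = linked_world
        assert flags["trait1"] and flags["trait2"]  # sex-specific link multipliers
        assert not flags["trait3"] and not flags["trait4"]


class TestAssociateTranscripts:
    def test_noiseless_link_recovers_slope(self):
        cfg = pl.SimulationConfig(
            n_transcripts=80, within_noise_sd=0.0, classII_within_sd=0.0, seed=23
        )
        matrix, truth = pl.simulate_outbred(cfg)
        reps = pl.simulate_phenotypes(
            truth, matrix, n_traits=1, n_linked=1, noise_sd=0.0,
            n_sexed_traits=0, seed=23,
        )
        means = pl.trait_means(reps)
        (gid,) = truth.trait_links["trait1"]
        assoc = pl.associate_transcripts(means, matrix, [gid], {"trait1": False})
        row = assoc.iloc[0]
        assert row["p"] < 1e-12
        assert row["significant"]
        # slope on the standardized profile: link / profile sd
        profile = matrix.group_means().loc[gid]
        assert row["slope"] == pytest.approx(1.0 / profile.std(ddof=1), rel=1e-6)

    def test_planted_links_recovered(self, linked_world):
        matrix, truth, _, flags, means = linked_world
        assoc = pl.associate_transcripts(
            means, matrix, truth.ids("classI"), flags
        )
        recovered = total = 0
        for trait, linked in truth.trait_links.items():
            sig = set(pl.significant_ids(assoc, trait))
            recovered += len(set(linked) & sig)
            total += len(linked)
        assert recovered / total >= 0.9

    def test_sexed_trait_uses_per_sex_modes(self, linked_world):
        matrix, truth, _, flags, means = linked_world
        assoc = pl.associate_transcripts(means, matrix, truth.ids("classI")[:5], flags)
        modes = set(assoc.loc[assoc["trait"] == "trait1", "mode"])
        assert modes == {"per_sex_female", "per_sex_male"}
        assert set(assoc.loc[assoc["trait"] == "trait3", "mode"]) == {"sex_centered"}

    def test_invariant_to_trait_affine_rescale(self, linked_world):
        matrix, truth, _, flags, means = linked_world
        ids = truth.ids("classI")[:20]
        a = pl.associate_transcripts(means, matrix, ids, flags)
        shifted = means.assign(mean=3.0 * means["mean"] + 7.0)
        b = pl.associate_transcripts(shifted, matrix, ids, flags)
        assert (a["significant"] == b["significant"]).all()
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-9)


class TestResidualize:
    def test_exact_linear_dependence_gives_zero_residuals(self, linked_world):
        matrix, truth, _, _, means = linked_world
        # build a fake transcript exactly linear in the trait
        trait = "trait3"
        gid = matrix.transcript_ids[0]
        wide = means[means["trait"] == trait].pivot(
            index="treatment", columns="sex", values="mean"
        )
        m2 = matrix.values.copy()
        for sex in ("female", "male"):
            cols = matrix.design.index[matrix.design["sex"] == sex]
            tvals = wide[sex].reindex(matrix.design.loc[cols, "group"]).values
            m2.loc[gid, cols] = 2.0 + 3.0 * tvals
        fake = pl.ExpressionMatrix(values=m2, design=matrix.design)
        res = pl.residualize_on_trait(fake, means, trait, [gid], sexed=False)
        np.testing.assert_allclose(res.loc[gid].values, 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_trait(self, linked_world):
        matrix, truth, _, flags, means = linked_world
        trait = "trait3"
        ids = truth.ids("classI")[:10]
        res = pl.residualize_on_trait(matrix, means, trait, ids, sexed=False)
        wide = means[means["trait"] == trait].pivot(
            index="treatment", columns="sex", values="mean"
        )
        x = np.concatenate(
            [wide[s].values - wide[s].values.mean() for s in ("female", "male")]
        )
        for gid in ids:
            assert abs(res.loc[gid].values @ x) < 1e-9 * max(1.0, np.abs(x).sum())

    def test_shared_trait_signal_removed(self):
        # two transcripts share only a trait-driven component
        rng = np.random.default_rng(31)
        t = rng.normal(0, 1, 20)
        e1 = 5.0 + 2.0 * t + rng.normal(0, 0.2, 20)
        e2 = 7.0 - 1.5 * t + rng.normal(0, 0.2, 20)
        before = np.corrcoef(e1, e2)[0, 1]
        tc = t - t.mean()
        r1 = (e1 - e1.mean()) - ((e1 - e1.mean()) @ tc) / (tc @ tc) * tc
        r2 = (e2 - e2.mean()) - ((e2 - e2.mean()) @ tc) / (tc @ tc) * tc
        after = np.corrcoef(r1, r2)[0, 1]
        assert abs(before) > 0.9
        assert abs(after) < 0.35

    def test_empty_set_errors(self, linked_world):
        matrix, _, _, _, means = linked_world
        with pytest.raises(ValueError, match="empty"):
            pl.residualize_on_trait(matrix, means, "trait3", [], sexed=False)


class TestTraitModules:
    def test_planted_blocks_in_residuals_recovered(self):
        rng = np.random.default_rng(41)
        n_per, n_pts = 10, 30
        base = [rng.normal(0, 1, n_pts) for _ in range(2)]
        rows = []
        for b in range(2):
            for _ in range(n_per):
                rows.append(base[b] + rng.normal(0, 0.1, n_pts))
        res = pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * n_per)])
        part, r = pl.trait_modules(res, seed=0)
        assert part.n_modules == 2
        assert len(set(part.modules[:n_per])) == 1

    def test_single_transcript_singleton(self):
        res = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"])
        part, _ = pl.trait_modules(res)
        assert part.n_modules == 1


def hypergeom_tail_by_enumeration(N, size_a, size_b, k):
    """P(overlap >= k) by enumerating all draws of size_b from N items."""
    marked = set(range(size_a))
    hits = total = 0
    for combo in itertools.combinations(range(N), size_b):
        total += 1
        if len(marked & set(combo)) >= k:
            hits += 1
    return hits / total


class TestPleiotropyOverlap:
    @staticmethod
    def _partition(groups):
        labels = {}
        for mod, members in groups.items():
            for g in members:
                labels[g] = mod
        return ModulePartition(
            modules=pd.Series(labels, dtype=int), modularity=0.0, sigma=1.0
        )

    def test_exact_small_case_one_over_120(self):
        pa = self._partition({1: ["g1", "g2", "g3"]})
        pb = self._partition({1: ["g1", "g2", "g3"]})
        out = pl.pleiotropy_overlap(pa, pb, universe_size=10)
        row = out.iloc[0]
        assert row["shared"] == 3
        assert row["p"] == pytest.approx(1 / math.comb(10, 3), rel=1e-9)
        assert row["considered"]

    def test_zero_overlap_p_one_not_considered(self):
        pa = self._partition({1: ["g1", "g2", "g3"]})
        pb = self._partition({1: ["g4", "g5", "g6"]})
        out = pl.pleiotropy_overlap(pa, pb, universe_size=12)
        row = out.iloc[0]
        assert row["p"] == pytest.approx(1.0)
        assert not row["considered"]
        assert np.isnan(row["p_bonferroni"])

    def test_matches_combinatorial_enumeration(self):
        rng = np.random.default_rng(3)
        for N in (8, 10, 12):
            size_a = int(rng.integers(2, 6))
            size_b = int(rng.integers(2, 6))
            ids = [f"g{i}" for i in range(N)]
            pa = self._partition({1: ids[:size_a]})
            shared = int(rng.integers(0, min(size_a, size_b) + 1))
            b_members = ids[:shared] + ids[size_a : size_a + size_b - shared]
            pb = self._partition({1: b_members})
            out = pl.pleiotropy_overlap(pa, pb, universe_size=N).iloc[0]
            expected = hypergeom_tail_by_enumeration(N, size_a, size_b, shared)
            assert out["p"] == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_and_considered_invariants(self):
        pa = self._partition({1: ["g1", "g2", "g3", "g4"], 2: ["g5", "g6", "g7"]})
        pb = self._partition({1: ["g1", "g2", "g3"], 2: ["g5", "g8", "g9"]})
        out = pl.pleiotropy_overlap(pa, pb, universe_size=20)
        considered = out[out["considered"]]
        assert (considered["p_bonferroni"] >= considered["p"] - 1e-12).all()
        assert considered.index.isin(out.index).all()

    def test_universe_smaller_than_module_errors(self):
        pa = self._partition({1: [f"g{i}" for i in range(6)]})
        with pytest.raises(ValueError, match="universe"):
            pl.pleiotropy_overlap(pa, pa, universe_size=5)
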