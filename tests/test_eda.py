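"""The distribution-estimation loop: selection, frequencies, updates, runs."""

import math

import numpy as np
import pytest
from scipy import stats

from edafrag.conformation import extended_conformation
from edafrag.eda import (
    EdaConfig,
    estimate_frequencies,
    init_pmfs,
    run_eda,
    select_sample_set,
    update_pmf,
)
from edafrag.energy import OracleScore
from edafrag.fixtures import FixtureSpec, make_fixture
from edafrag.sampler import ModelRecord, Pmf, SamplerConfig


def make_record(energy, model_id, provenance9=None, iteration=1, conf=None):
    return ModelRecord(
        conformation=conf or extended_conformation("ACDEFGHIK"),
        energy=energy,
        iteration=iteration,
        model_id=model_id,
        provenance9=provenance9 or {},
    )


class TestInitPmfs:
    def test_uniform_over_25(self, bench_fixture):
        pmfs = init_pmfs(bench_fixture.library.windows9)
        for pmf in pmfs:
            assert np.allclose(pmf.probs, 0.04)
            assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_fragment_window(self, rng):
        from edafrag.fragment_io import Fragment, FragmentWindow

        w = FragmentWindow(start=1, fragments=[Fragment(np.zeros((9, 3)))])
        assert init_pmfs([w])[0].probs.tolist() == [1.0]


class TestSelectSampleSet:
    def test_single_lowest(self):
        pool = [make_record(float(e), e) for e in range(1, 11)]
        out = select_sample_set(pool, 0.1)
        assert [r.model_id for r in out] == [1]

    def test_full_pool(self):
        pool = [make_record(float(e), e) for e in range(5)]
        assert len(select_sample_set(pool, 1.0)) == 5

    def test_matches_brute_force_sort(self, rng):
        energies = rng.normal(size=100)
        pool = [make_record(float(e), i) for i, e in enumerate(energies)]
        out = select_sample_set(pool, 0.1)
        expected = set(np.argsort(energies)[:10])
        assert {r.model_id for r in out} == expected

    def test_ties_broken_by_model_id(self):
        pool = [make_record(1.0, mid) for mid in (5, 2, 9, 1)]
        out = select_sample_set(pool, 0.5)
        assert [r.model_id for r in out] == [1, 2]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_sample_set([], 0.1)


class TestEstimateFrequencies:
    @pytest.fixture()
    def window(self, bench_fixture):
        return bench_fixture.library.windows9[0]

    def test_counts_with_uncovered_model(self, window):
        sample = [
            make_record(1.0, 0, {window.start: 0}),
            make_record(1.1, 1, {window.start: 0}),
            make_record(1.2, 2, {window.start: 1}),
            make_record(1.3, 3, {}),  # does not cover the window
        ]
        f = estimate_frequencies(sample, window)
        assert f[0] == pytest.approx(2 / 3)
        assert f[1] == pytest.approx(1 / 3)
        assert f[2:].sum() == 0.0

    def test_unanimous_fragment(self, window):
        sample = [make_record(1.0, i, {window.start: 3}) for i in range(4)]
        f = estimate_frequencies(sample, window)
        assert f[3] == 1.0 and f.sum() == 1.0

    def test_uniform_fallback_when_uncovered(self, window):
        sample = [make_record(1.0, 0, {})]
        f = estimate_frequencies(sample, window)
        assert np.allclose(f, 1.0 / window.n_fragments)

    def test_normalized_whenever_covered(self, window, rng):
        sample = [
            make_record(1.0, i, {window.start: int(rng.integers(window.n_fragments))})
            for i in range(10)
        ]
        assert estimate_frequencies(sample, window).sum() == pytest.approx(
            1.0, abs=1e-12
        )


class TestUpdatePmf:
    def test_pure_conservation(self, rng):
        probs = rng.dirichlet(np.ones(25))
        pmf = Pmf(1, probs)
        out = update_pmf(pmf, rng.dirichlet(np.ones(25)), k=1.0)
        assert np.array_equal(out.probs, probs)

    def test_pure_learning(self, rng):
        freqs = rng.dirichlet(np.ones(25))
        out = update_pmf(Pmf(1, np.full(25, 0.04)), freqs, k=0.0)
        assert np.array_equal(out.probs, freqs)

    def test_printed_mixture_value(self):
        """k=0.6, uniform 25-way prior, unanimous frequency on index 0."""
        freqs = np.zeros(25)
        freqs[0] = 1.0
        out = update_pmf(Pmf(1, np.full(25, 0.04)), freqs, k=0.6)
        assert out.probs[0] == pytest.approx(0.424, abs=1e-12)
        assert np.allclose(out.probs[1:], 0.024, atol=1e-12)

    def test_matches_arithmetic_oracle(self, rng):
        """Element-wise oracle computed with plain Python floats."""
        for _ in range(50):
            m = int(rng.integers(2, 30))
            p = rng.dirichlet(np.ones(m))
            f = rng.dirichlet(np.ones(m))
            k = float(rng.random())
            out = update_pmf(Pmf(1, p), f, k)
            for i in range(m):
                expected = k * float(p[i]) + (1.0 - k) * float(f[i])
                assert math.isclose(out.probs[i], expected, abs_tol=1e-12)
            assert out.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            update_pmf(Pmf(1, np.array([0.5, 0.5])), np.array([1.0]), 0.5)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            update_pmf(Pmf(1, np.array([0.5, 0.5])), np.array([0.5, 0.5]), 1.5)


@pytest.fixture(scope="module")
def small_run():
    fx = make_fixture(FixtureSpec(length=18, frags_per_window=10, seed=7))
    score = OracleScore(native_ca=fx.native_coords[:, 1, :])
    state = run_eda(
        fx.sequence,
        fx.library,
        score,
        EdaConfig(budget=80, iterations=4),
        SamplerConfig(),
        master_seed=17,
    )
    return fx, state


class TestRunEda:
    def test_pool_tagged_by_iteration(self, small_run):
        _, state = small_run
        counts = {t: 0 for t in range(1, 5)}
        for rec in state.pool:
            counts[rec.iteration] += 1
        assert counts == {1: 20, 2: 20, 3: 20, 4: 20}
        assert len({r.model_id for r in state.pool}) == 80

    def test_pmfs_stay_normalized(self, small_run):
        _, state = small_run
        for pmfs in state.pmf_history9 + [state.pmfs9]:
            for pmf in pmfs:
                assert abs(pmf.probs.sum() - 1.0) < 1e-12

    def test_iteration1_pmfs_uniform(self, small_run):
        _, state = small_run
        for pmf in state.pmf_history9[0]:
            assert np.allclose(pmf.probs, pmf.probs[0])

    def test_reproducible_given_seed(self):
        fx = make_fixture(FixtureSpec(length=18, frags_per_window=8, seed=3))
        score = OracleScore(native_ca=fx.native_coords[:, 1, :])
        cfg = EdaConfig(budget=20, iterations=2)
        a = run_eda(fx.sequence, fx.library, score, cfg, master_seed=5)
        b = run_eda(fx.sequence, fx.library, score, cfg, master_seed=5)
        assert [r.energy for r in a.pool] == [r.energy for r in b.pool]
        for pa, pb in zip(a.pmfs9, b.pmfs9):
            assert np.array_equal(pa.probs, pb.probs)

    def test_energy_improves_across_iterations(self):
        """Learned distributions shift the energy histogram downward.

        Uses a deliberately weak per-model sampler so iteration-1 models sit
        well above the landscape floor and the iteration-over-iteration
        shift is attributable to the distribution update.
        """
        fx = make_fixture(FixtureSpec(length=24, frags_per_window=15, seed=9))
        score = OracleScore(native_ca=fx.native_coords[:, 1, :])
        weak = SamplerConfig(
            sa_steps_per_window=5, ihc_restarts=1, ihc_steps_per_window=2
        )
        state = run_eda(
            fx.sequence,
            fx.library,
            score,
            EdaConfig(budget=80, iterations=4),
            weak,
            master_seed=17,
        )
        e = np.array([r.energy for r in state.pool])
        it = np.array([r.iteration for r in state.pool])
        assert e[it == 4].mean() < e[it == 1].mean()

    def test_single_iteration_keeps_uniform_sampling(self):
        fx = make_fixture(FixtureSpec(length=18, frags_per_window=8, seed=3))
        score = OracleScore(native_ca=fx.native_coords[:, 1, :])
        state = run_eda(
            fx.sequence, fx.library, score, EdaConfig(budget=10, iterations=1),
            master_seed=1,
        )
        assert len(state.pmf_history9) == 1
        for pmf in state.pmf_history9[0]:
            assert np.allclose(pmf.probs, pmf.probs[0])

    def test_indivisible_budget_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            EdaConfig(budget=10, iterations=4)

    def test_conserved_pmfs_when_k_is_one(self):
        """k=1 disables learning: every iteration samples the same uniform
        distribution, so iteration-1 and iteration-4 energies are draws from
        one distribution (two-sample test must not reject at alpha=0.01)."""
        fx = make_fixture(FixtureSpec(length=18, frags_per_window=10, seed=7))
        score = OracleScore(native_ca=fx.native_coords[:, 1, :])
        state = run_eda(
            fx.sequence,
            fx.library,
            score,
            EdaConfig(budget=120, iterations=4, conservation_rate=1.0),
            SamplerConfig(),
            master_seed=23,
        )
        for pmfs in state.pmf_history9 + [state.pmfs9]:
            for pmf in pmfs:
                assert np.allclose(pmf.probs, pmf.probs[0])
        e = np.array([r.energy for r in state.pool])
        it = np.array([r.iteration for r in state.pool])
        assert stats.mannwhitneyu(e[it == 1], e[it == 4]).pvalue > 0.01

    def test_native_fragment_mass_non_decreasing(self):
        """Monotone enrichment under a perfect funnel: with an exact native
        fragment planted per window and a noise-free oracle, the total
        probability mass on the best (lowest-RMSD) fragments never drops."""
        from edafrag import analysis

        for seed in (1, 2, 3):
            fx = make_fixture(
                FixtureSpec(
                    length=18,
                    frags_per_window=10,
                    near_native_jitter_sd=0.0,
                    seed=seed,
                )
            )
            score = OracleScore(native_ca=fx.native_coords[:, 1, :])
            state = run_eda(
                fx.sequence,
                fx.library,
                score,
                EdaConfig(budget=80, iterations=4),
                master_seed=seed,
            )
            table = analysis.fragment_native_rmsd(
                fx.library.windows9, fx.native_coords
            )
            native_idx = {s: int(np.argmin(v)) for s, v in table.items()}
            masses = []
            for pmfs in state.pmf_history9 + [state.pmfs9]:
                masses.append(
                    sum(p.probs[native_idx[p.window_start]] for p in pmfs)
                )
            assert all(b >= a - 1e-9 for a, b in zip(masses, masses[1:]))

    def test_per_iteration_sample_base(self):
        fx = make_fixture(FixtureSpec(length=18, frags_per_window=8, seed=3))
        score = OracleScore(native_ca=fx.native_coords[:, 1, :])
        state = run_eda(
            fx.sequence,
            fx.library,
            score,
            EdaConfig(budget=20, iterations=2, sample_base="iteration"),
            master_seed=2,
        )
        assert len(state.pool) == 20
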