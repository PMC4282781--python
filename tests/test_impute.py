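"""Imputation machinery: step-function inversion, bootstrap draws, limits."""

import numpy as np
import pytest

from coxsens import (
    GammaSpec,
    StepCumHaz,
    SurvivalDataset,
    bootstrap_draw,
    create_imputed_datasets,
    extreme_immediate,
    extreme_never,
    impute_record,
    invert_step_cumhaz,
    prepare_draws,
    resolve_gamma,
)
from coxsens.impute import BootstrapDraw, impute_with


@pytest.fixture
def two_jump():
    # H jumps to 0.5 at t=1 and to 1.2 at t=2
    return StepCumHaz(times=[1.0, 2.0], values=[0.5, 1.2])


def invert_by_enumeration(H, C, x, tau):
    """Independent oracle: walk the jumps and accumulate increments."""
    base = 0.0
    for t, v in zip(H.times, H.values):
        if t <= C:
            base = v
    acc = 0.0
    prev = base
    for t, v in zip(H.times, H.values):
        if t <= C or t > tau:
            continue
        acc += v - prev
        prev = v
        if acc >= x:
            return t - C
    return None


class TestInvertStepCumHaz:
    def test_lands_on_second_jump(self, two_jump):
        assert invert_step_cumhaz(two_jump, C=0.5, x=0.6, tau=3.0) == pytest.approx(1.5)

    def test_mass_exhausted_is_beyond_horizon(self, two_jump):
        assert invert_step_cumhaz(two_jump, C=0.5, x=1.5, tau=3.0) is None

    def test_vanishing_target_gives_first_jump_after_c(self, two_jump):
        assert invert_step_cumhaz(two_jump, C=0.5, x=1e-9, tau=3.0) == pytest.approx(0.5)

    def test_jump_exactly_at_c_excluded(self, two_jump):
        # increment over (1, tau] is 0.7 only; jump at t=1 never counts
        assert invert_step_cumhaz(two_jump, C=1.0, x=0.6, tau=3.0) == pytest.approx(1.0)
        assert invert_step_cumhaz(two_jump, C=1.0, x=0.8, tau=3.0) is None

    def test_horizon_cuts_off_late_jumps(self, two_jump):
        assert invert_step_cumhaz(two_jump, C=0.5, x=0.6, tau=1.5) is None

    def test_nonpositive_target_rejected(self, two_jump):
        with pytest.raises(ValueError):
            invert_step_cumhaz(two_jump, C=0.5, x=0.0, tau=3.0)

    def test_matches_enumeration_on_random_step_functions(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            k = rng.integers(1, 8)
            times = np.sort(rng.uniform(0, 3, size=k))
            times = np.unique(times)
            values = np.cumsum(rng.uniform(0.05, 1.0, size=times.size))
            H = StepCumHaz(times, values)
            C = float(rng.uniform(0, 2.5))
            x = float(rng.exponential(0.8)) + 1e-12
            tau = float(rng.uniform(C + 0.1, 4.0))
            got = invert_step_cumhaz(H, C, x, tau)
            want = invert_by_enumeration(H, C, x, tau)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


class TestBootstrapDraw:
    def test_resample_size_and_refit(self, sim5, rng):
        draw = bootstrap_draw(sim5, rng)
        assert draw.sample_idx.shape == (sim5.n,)
        assert draw.beta.shape == (2,)
        assert "" in draw.baseline

    def test_within_strata_sizes_preserved(self, sim5, rng):
        arm = (sim5.covariates[:, 0] > 0).astype(int)
        draw = bootstrap_draw(sim5, rng, sampling_strata=arm)
        for a in (0, 1):
            rows = np.flatnonzero(arm == a)
            assert np.isin(draw.sample_idx[rows], rows).all()

    def test_degenerate_single_record_resamples_itself(self, rng):
        ds = SurvivalDataset([1.0], [1], np.empty((1, 0)), [], tau=3)
        draw = bootstrap_draw(ds, rng)
        np.testing.assert_array_equal(draw.sample_idx, [0])


class TestImputeRecord:
    def test_deterministic_given_u(self, two_jump):
        ds = SurvivalDataset(
            [0.5, 1.0, 2.0], [0, 1, 1], np.zeros((3, 1)), ["z"], tau=3
        )
        draw = BootstrapDraw(0, np.array([0.0]), {"": two_jump}, np.arange(3))
        out = impute_record(ds, 0, draw, gamma_i=0.0, U=0.5)
        assert out.target == pytest.approx(np.log(2))
        assert out.gap == pytest.approx(1.5)
        assert out.imputed_time == pytest.approx(2.0)
        assert out.imputed_event == 1

    def test_large_positive_gamma_hits_first_event(self, two_jump, rng):
        ds = SurvivalDataset([0.5], [0], np.zeros((1, 1)), ["z"], tau=3)
        draw = BootstrapDraw(0, np.array([0.3]), {"": two_jump}, np.arange(1))
        for _ in range(20):
            out = impute_record(ds, 0, draw, gamma_i=50.0, rng=rng)
            assert out.imputed_time == pytest.approx(1.0)
            assert out.imputed_event == 1

    def test_large_negative_gamma_censors_at_tau(self, two_jump, rng):
        ds = SurvivalDataset([0.5], [0], np.zeros((1, 1)), ["z"], tau=3)
        draw = BootstrapDraw(0, np.array([0.3]), {"": two_jump}, np.arange(1))
        for _ in range(20):
            out = impute_record(ds, 0, draw, gamma_i=-50.0, rng=rng)
            assert out.imputed_time == pytest.approx(3.0)
            assert out.imputed_event == 0

    def test_gap_nonincreasing_in_gamma_at_fixed_u(self, two_jump):
        ds = SurvivalDataset([0.3], [0], np.zeros((1, 1)), ["z"], tau=3)
        draw = BootstrapDraw(0, np.array([0.0]), {"": two_jump}, np.arange(1))
        gaps = []
        for g in (-2.0, 0.0, 0.4, 2.0):
            out = impute_record(ds, 0, draw, gamma_i=g, U=0.55)
            gaps.append(out.gap if out.gap is not None else np.inf)
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))

    def test_event_record_rejected(self, two_jump):
        ds = SurvivalDataset([0.5], [1], np.zeros((1, 1)), ["z"], tau=3)
        draw = BootstrapDraw(0, np.array([0.0]), {"": two_jump}, np.arange(1))
        with pytest.raises(ValueError):
            impute_record(ds, 0, draw, gamma_i=0.0, U=0.5)


class TestCreateImputedDatasets:
    def test_determinism(self, sim5):
        a, _ = create_imputed_datasets(sim5, GammaSpec.constant(1.0), m=3, master_seed=5)
        b, _ = create_imputed_datasets(sim5, GammaSpec.constant(1.0), m=3, master_seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.dataset.time, y.dataset.time)
            np.testing.assert_array_equal(x.dataset.event, y.dataset.event)

    def test_observed_rows_untouched_and_imputed_exceed_censoring(self, sim5):
        imputed, draws = create_imputed_datasets(
            sim5, GammaSpec.constant(0.0), m=3, master_seed=5
        )
        keep = ~sim5.imputable_mask
        for imp in imputed:
            np.testing.assert_array_equal(imp.dataset.time[keep], sim5.time[keep])
            np.testing.assert_array_equal(imp.dataset.event[keep], sim5.event[keep])
            moved = imp.imputed
            assert np.all(imp.dataset.time[moved] > sim5.time[moved])
            assert np.all(imp.dataset.time[moved] <= sim5.tau)

    def test_imputed_times_are_bootstrap_event_times_or_tau(self, sim5):
        imputed, draws = create_imputed_datasets(
            sim5, GammaSpec.constant(0.0), m=2, master_seed=5
        )
        for imp, draw in zip(imputed, draws):
            H = draw.baseline[""]
            t = imp.dataset.time[imp.imputed]
            e = imp.dataset.event[imp.imputed]
            assert np.all(np.isin(t[e == 1], H.times))
            assert np.all(t[e == 0] == sim5.tau)

    def test_no_censoring_means_identity(self):
        ds = SurvivalDataset([1.0, 2.0], [1, 1], np.array([[0.0], [1.0]]), ["z"], tau=3)
        imputed, _ = create_imputed_datasets(ds, GammaSpec.constant(2.0), m=2, master_seed=1)
        for imp in imputed:
            np.testing.assert_array_equal(imp.dataset.time, ds.time)
            assert imp.imputed.sum() == 0

    def test_m_below_two_rejected(self, sim5):
        with pytest.raises(ValueError):
            create_imputed_datasets(sim5, GammaSpec.constant(0.0), m=1, master_seed=1)

    def test_vectorised_path_agrees_with_impute_record(self, sim5):
        draws, U = prepare_draws(sim5, 2, master_seed=9)
        gammas = resolve_gamma(GammaSpec.constant(1.5), sim5)
        imputed = impute_with(sim5, draws, U, gammas)
        rows = np.flatnonzero(sim5.imputable_mask)[:25]
        for i in rows:
            single = impute_record(sim5, int(i), draws[0], 1.5, U=float(U[i, 0]))
            assert imputed[0].dataset.time[i] == pytest.approx(single.imputed_time)
            assert imputed[0].dataset.event[i] == single.imputed_event

    def test_beyond_horizon_fraction_increases_as_gamma_decreases(self, sim5):
        draws, U = prepare_draws(sim5, 4, master_seed=9)
        fracs = []
        for g in (2.0, 0.0, -2.0):
            gammas = resolve_gamma(GammaSpec.constant(g), sim5)
            imputed = impute_with(sim5, draws, U, gammas)
            cens = np.mean([
                (imp.dataset.event[imp.imputed] == 0).mean() for imp in imputed
            ])
            fracs.append(cens)
        assert fracs[0] < fracs[1] < fracs[2]


class TestExtremes:
    def test_never_pushes_censored_to_tau(self, tiny):
        out = extreme_never(tiny)
        assert out.time[1] == tiny.tau and out.event[1] == 0
        assert out.time[0] == tiny.time[0] and out.event[0] == 1

    def test_never_respects_scope(self, tiny):
        scope = np.asarray([r == "pregnancy" for r in tiny.reason])
        out = extreme_never(tiny, scope)
        assert out.time[4] == tiny.tau
        assert out.time[1] == tiny.time[1]  # ltfu row untouched

    def test_immediate_sets_events(self, tiny):
        out = extreme_immediate(tiny)
        assert out.event[1] == 1 and out.time[1] == tiny.time[1]
        np.testing.assert_array_equal(out.event, [1, 1, 1, 1, 1, 1])

    def test_immediate_empty_scope_is_identity(self, tiny):
        out = extreme_immediate(tiny, np.zeros(tiny.n, dtype=bool))
        np.testing.assert_array_equal(out.event, tiny.event)
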