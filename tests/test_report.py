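"""HDI computation, evidence rules, posterior contrasts and the PPC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fairshare as fs
from fairshare.report import (
    condition_contrast,
    evidence_category,
    group_contrast,
    hdi,
    posterior_predict,
    ppc_correlations,
    schedule_from_dataset,
)


def exhaustive_hdi(draws, mass):
    """Independent oracle: try every window of the required size."""
    d = np.sort(draws)
    n = d.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return d[0], d[-1]
    best = min(range(n - m + 1), key=lambda i: d[i + m - 1] - d[i])
    return d[best], d[best + m - 1]


class TestHdi:
    @given(seed=st.integers(0, 9999), mass=st.sampled_from([0.5, 0.85, 0.95, 0.975]))
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_search(self, seed, mass):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 3000))
        draws = rng.standard_normal(n) ** (1 + (seed % 2))  # skew half the time
        assert hdi(draws, mass) == exhaustive_hdi(draws, mass)

    def test_full_mass_and_bad_mass(self):
        d = np.array([3.0, 1.0, 2.0])
        assert hdi(d, 1.0) == (1.0, 3.0)
        with pytest.raises(ValueError):
            hdi(d, 0.0)

    def test_arviz_agreement_on_unimodal_sample(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        d = rng.gamma(3.0, 1.0, 5000)
        lo, hi = hdi(d, 0.95)
        ref = az.hdi(d, hdi_prob=0.95)
        assert lo == pytest.approx(float(ref[0]), abs=0.05)
        assert hi == pytest.approx(float(ref[1]), abs=0.05)


class TestEvidenceCategory:
    def test_all_positive_is_meaningful(self):
        rep = evidence_category(np.random.default_rng(0).uniform(0.5, 1.5, 2000))
        assert rep.category == "meaningful" and rep.direction == "above"

    def test_symmetric_around_zero_is_none(self):
        rep = evidence_category(np.random.default_rng(1).normal(0, 1, 4000))
        assert rep.category == "none"

    def test_93_percent_mass_above_zero_is_limited(self):
        rng = np.random.default_rng(2)
        draws = np.concatenate(
            [rng.normal(1.0, 0.01, 9300), rng.normal(-1.0, 0.01, 700)]
        )
        rep = evidence_category(draws)
        assert rep.category == "limited" and rep.direction == "above"

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="draws"):
            evidence_category(np.ones(10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evidence_category(np.array([]))

    @given(shift=st.floats(0.01, 5.0), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_positive_shifts(self, shift, seed):
        rank = {"none": 0, "limited": 1, "meaningful": 2}
        rng = np.random.default_rng(seed)
        draws = rng.normal(0.5, 1.0, 3000)
        before = evidence_category(draws)
        after = evidence_category(draws + shift)
        if before.direction in ("above", "-"):
            assert rank[after.category] >= rank[before.category]


class _StubFit:
    """Fit stand-in with constant group-level posteriors (synthetic)."""

    def __init__(self, means, group, n=2000):
        self._means = means
        self.group = group
        self._n = n

    def group_level(self, family, k):
        return np.full(self._n, self._means[family][k - 1])


class TestContrastConvention:
    children = _StubFit({"alpha": [-0.190, -0.241, 3.268, 3.348]}, "children")
    adults = _StubFit({"alpha": [1.361, 1.478, 1.992, 2.077]}, "adults")

    def test_role_contrast_sums_frames(self):
        d, _ = condition_contrast(self.children, "alpha", "role")
        assert d.mean() == pytest.approx(-7.047, abs=0.01)
        d, _ = condition_contrast(self.adults, "alpha", "role")
        assert d.mean() == pytest.approx(-1.230, abs=0.01)

    def test_group_contrast_sums_frames_within_role(self):
        d, _ = group_contrast(self.children, self.adults, "alpha", "first")
        assert d.mean() == pytest.approx(-3.270, abs=0.01)
        d, _ = group_contrast(self.children, self.adults, "alpha", "third")
        assert d.mean() == pytest.approx(2.547, abs=0.01)

    def test_identical_posteriors_yield_null_contrast(self):
        flat = _StubFit({"alpha": [1.0, 1.0, 1.0, 1.0]}, "g")
        d, rep = condition_contrast(flat, "alpha", "role")
        assert np.allclose(d, 0.0) and rep.category == "none"

    def test_frame_axis_pairs_cells_correctly(self):
        stub = _StubFit({"alpha": [1.0, 2.0, 3.0, 4.0]}, "g")
        d, _ = condition_contrast(stub, "alpha", "frame")
        assert d.mean() == pytest.approx((1 + 3) - (2 + 4))

    def test_self_contrast_centers_at_zero(self, recovery_fit):
        d, _ = group_contrast(recovery_fit, recovery_fit, "alpha", "first", seed=4)
        assert abs(d.mean()) < 3 * d.std() / np.sqrt(len(d)) + 0.05


class TestPosteriorPredict:
    def test_round_trip_reproduces_participant_profile(self, recovery_fit, recovery_cohort):
        """Replicates simulated from the fitted posterior correlate strongly
        with the original data across participants in every condition."""
        rep = posterior_predict(recovery_fit, mode="means", seed=1)
        res = ppc_correlations(recovery_cohort, rep)
        # Third-party conditions attenuate (all agents near the equal split,
        # so between-participant variance is small); first-party conditions
        # should correlate strongly and every condition clearly positively.
        r = res.correlations.set_index(["role", "frame"])["r_participants"]
        assert (r >= 0.65).all()
        assert (r.loc["first"] >= 0.8).all()
        assert r.mean() >= 0.8

    def test_fixed_seed_reproducible(self, recovery_fit):
        a = posterior_predict(recovery_fit, mode="means", seed=9)
        b = posterior_predict(recovery_fit, mode="means", seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_draws_mode_returns_replicates(self, recovery_fit):
        reps = posterior_predict(recovery_fit, mode="draws", n_rep=2, seed=3)
        assert isinstance(reps, list) and len(reps) == 2
        assert not reps[0].table.equals(reps[1].table)

    def test_schedule_mismatch_rejected(self, recovery_fit):
        sched = fs.make_schedule(3, seed=0)
        with pytest.raises(ValueError, match="participants"):
            posterior_predict(recovery_fit, schedule=sched)


class TestPpcCorrelations:
    def test_identity_gives_unit_correlations(self, small_dataset):
        res = ppc_correlations(small_dataset, small_dataset)
        assert np.allclose(res.correlations["r_participants"], 1.0)
        assert np.allclose(res.correlations["r_trials"], 1.0)

    def test_participant_permutation_destroys_matching(self, two_group_dataset):
        rng = np.random.default_rng(0)
        grp = two_group_dataset.for_group("children")
        pids = grp.participants
        mapping = dict(zip(pids, rng.permutation(pids)))
        permuted = grp.table.copy()
        permuted["participant_id"] = permuted["participant_id"].map(mapping)
        permuted = permuted.sort_values(["participant_id", "block", "round"])
        res = ppc_correlations(grp, fs.ChoiceDataset(permuted))
        assert res.correlations["r_participants"].abs().mean() < 0.6

    def test_constant_choices_flagged(self, small_dataset):
        const = small_dataset.table.copy()
        const["tokens_kept"] = const["total_tokens"]
        res = ppc_correlations(
            fs.ChoiceDataset(const.copy()), fs.ChoiceDataset(const.copy())
        )
        assert res.correlations["undefined"].all()

    def test_behavioral_recovery_runs_anova(self, two_group_dataset):
        res = ppc_correlations(two_group_dataset, two_group_dataset)
        assert res.anova_selfish is not None
        assert "role:group" in set(res.anova_selfish.table["effect"])


class TestScheduleFromDataset:
    def test_rebuilds_actual_trials(self, small_dataset):
        sched = schedule_from_dataset(small_dataset)
        assert sched.n_participants == len(small_dataset.participants)
        first = small_dataset.for_participant(small_dataset.participants[0])
        rebuilt = sched.trials[0]
        assert len(rebuilt) == len(first)
        assert [t.total_tokens for t in rebuilt] == list(first.table.total_tokens)
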