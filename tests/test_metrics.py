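"""Deviation metrics and the mixed-design ANOVA against a sums-of-squares oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fairshare as fs
from fairshare.metrics import (
    aggregate,
    equal_deviation,
    mixed_anova,
    posthoc_pairwise,
    selfish_deviation,
)


class TestDeviations:
    def test_loss_frame_worked_example(self):
        assert selfish_deviation("loss", 1, 3) == pytest.approx(1 / 3)

    def test_gain_frame_follows_formula(self):
        assert selfish_deviation("gain", 1, 3) == pytest.approx(2 / 3)
        assert selfish_deviation("gain", 3, 3) == 0.0

    def test_equal_deviation_worked_example(self):
        assert equal_deviation(1, 3, 1, 3) == pytest.approx(0.75 - 1 / 3)

    def test_equal_deviation_zero_at_equal_split(self):
        assert equal_deviation(1, 1, 2, 4) == 0.0
        assert equal_deviation(3, 1, 1, 4) == 0.0

    def test_zero_budget_undefined(self):
        with pytest.raises(ZeroDivisionError):
            selfish_deviation("gain", 0, 0)

    @given(
        frame=st.sampled_from(["gain", "loss"]),
        ratio=st.sampled_from([(3, 1), (1, 1), (1, 3)]),
        ts=st.integers(0, 12),
        scale=st.integers(1, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_budget_rescaling_invariance(self, frame, ratio, ts, scale):
        assert selfish_deviation(frame, ts, 12) == pytest.approx(
            selfish_deviation(frame, ts * scale, 12 * scale)
        )
        assert equal_deviation(*ratio, ts, 12) == pytest.approx(
            equal_deviation(*ratio, ts * scale, 12 * scale)
        )

    def test_gain_selfish_complements_kept_fraction(self, small_dataset):
        from fairshare.metrics import add_deviations

        df = add_deviations(small_dataset)
        gain = df[df.frame == "gain"]
        assert np.allclose(gain.selfish_dev + gain.kept_fraction, 1.0)


class TestAggregate:
    def test_one_row_per_cell(self, small_dataset):
        summ = aggregate(small_dataset)
        assert len(summ) == 4 * len(small_dataset.participants)
        assert summ[["selfish_dev", "equal_dev"]].min().min() >= 0
        assert summ[["selfish_dev", "equal_dev"]].max().max() <= 1

    def test_missing_cell_names_participant(self, small_dataset):
        broken = small_dataset.table.query("not (participant_id == 'g-000' and role == 'third')")
        with pytest.raises(ValueError, match="g-000"):
            aggregate(fs.ChoiceDataset(broken.copy()))


def oracle_anova(y: np.ndarray, groups: np.ndarray):
    """Brute-force balanced-group mixed ANOVA from cell/marginal means.

    ``y`` is (subjects, 4) in cell order (first/gain, first/loss, third/gain,
    third/loss); groups must be balanced so weighted and unweighted marginal
    means coincide.
    """
    labels = sorted(set(groups))
    N = y.shape[0]
    cells = y.reshape(N, 2, 2)  # role x frame
    grand = cells.mean()
    subj = cells.mean(axis=(1, 2))
    g_mean = {g: subj[groups == g].mean() for g in labels}
    role_m = cells.mean(axis=2)  # (N, 2)
    frame_m = cells.mean(axis=1)

    out = {}
    ss_group = 4 * sum((groups == g).sum() * (g_mean[g] - grand) ** 2 for g in labels)
    ss_subj = 4 * sum(((subj[groups == g] - g_mean[g]) ** 2).sum() for g in labels)
    out["group"] = (ss_group, ss_subj)

    for name, marg, axis in (("role", role_m, 1), ("frame", frame_m, 2)):
        lvl = marg.mean(axis=0)  # marginal means over subjects
        ss_main = 2 * N * ((lvl - grand) ** 2).sum()
        ss_int = 0.0
        ss_err = 0.0
        for g in labels:
            sel = groups == g
            lvl_g = marg[sel].mean(axis=0)
            ss_int += 2 * sel.sum() * ((lvl_g - g_mean[g] - lvl + grand) ** 2).sum()
            resid = marg[sel] - subj[sel][:, None] - lvl_g[None, :] + g_mean[g]
            ss_err += 2 * (resid**2).sum()
        out[name] = (ss_main, ss_err)
        out[f"{name}:group"] = (ss_int, ss_err)

    # Role x frame stratum.
    cell_mean = cells.mean(axis=0)
    inter = cell_mean - role_m.mean(axis=0)[:, None] - frame_m.mean(axis=0)[None, :] + grand
    ss_rf = N * (inter**2).sum()
    ss_rfg = 0.0
    ss_err = 0.0
    for g in labels:
        sel = groups == g
        cm_g = cells[sel].mean(axis=0)
        inter_g = (
            cm_g
            - cells[sel].mean(axis=(0, 2))[:, None]
            - cells[sel].mean(axis=(0, 1))[None, :]
            + g_mean[g]
        )
        ss_rfg += sel.sum() * ((inter_g - inter) ** 2).sum()
        resid = (
            cells[sel]
            - cells[sel].mean(axis=2)[:, :, None]
            - cells[sel].mean(axis=1)[:, None, :]
            - cm_g[None, :, :]
            + cells[sel].mean(axis=(1, 2))[:, None, None]
            + cells[sel].mean(axis=(0, 2))[None, :, None]
            + cells[sel].mean(axis=(0, 1))[None, None, :]
            - g_mean[g]
        )
        ss_err += (resid**2).sum()
    out["role:frame"] = (ss_rf, ss_err)
    out["role:frame:group"] = (ss_rfg, ss_err)

    dfe = N - len(labels)
    return {
        eff: (ss / 1.0) / (err / dfe) for eff, (ss, err) in out.items()
    }


def summaries_from_matrix(y: np.ndarray, groups) -> pd.DataFrame:
    rows = []
    cells = [("first", "gain"), ("first", "loss"), ("third", "gain"), ("third", "loss")]
    for i, (g, row) in enumerate(zip(groups, y)):
        for (role, frame), v in zip(cells, row):
            rows.append(
                {
                    "participant_id": f"s{i:02d}",
                    "group": g,
                    "role": role,
                    "frame": frame,
                    "resp": v,
                }
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        y = rng.normal(size=(2 * n, 4)) + rng.normal(size=(2 * n, 1))
        groups = np.array(["a"] * n + ["b"] * n)
        res = mixed_anova(summaries_from_matrix(y, groups), "resp")
        oracle = oracle_anova(y, groups)
        for row in res.table.itertuples():
            assert row.F == pytest.approx(oracle[row.effect], abs=1e-10, rel=1e-10)

    def test_four_participant_toy(self):
        y = np.array(
            [
                [0.1, 0.2, 0.3, 0.4],
                [0.2, 0.1, 0.5, 0.6],
                [0.7, 0.8, 0.2, 0.1],
                [0.9, 0.6, 0.3, 0.2],
            ]
        )
        groups = np.array(["a", "a", "b", "b"])
        res = mixed_anova(summaries_from_matrix(y, groups), "resp")
        oracle = oracle_anova(y, groups)
        for row in res.table.itertuples():
            assert row.F == pytest.approx(oracle[row.effect], abs=1e-10)
            assert row.df1 == 1 and row.df2 == 2
            assert 0 <= row.eta_p2 <= 1

    def test_null_simulation_type_one_error_calibrated(self):
        rng = np.random.default_rng(77)
        n_rep, alpha = 400, 0.05
        rejects = {eff: 0 for eff in fs.metrics.EFFECTS} if hasattr(fs, "metrics") else {}
        from fairshare.metrics import EFFECTS

        rejects = {eff: 0 for eff in EFFECTS}
        for _ in range(n_rep):
            y = rng.normal(size=(12, 4))
            groups = np.array(["a"] * 6 + ["b"] * 6)
            res = mixed_anova(summaries_from_matrix(y, groups), "resp")
            for row in res.table.itertuples():
                rejects[row.effect] += row.p < alpha
        # 99.9% binomial band around 0.05 with n = 400.
        lo, hi = 0.05 - 3.3 * np.sqrt(0.05 * 0.95 / n_rep), 0.05 + 3.3 * np.sqrt(
            0.05 * 0.95 / n_rep
        )
        for eff, count in rejects.items():
            assert lo <= count / n_rep <= hi, (eff, count / n_rep)

    def test_degenerate_data_rejected(self):
        y = np.ones((6, 4))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="degenerate"):
            mixed_anova(summaries_from_matrix(y, groups), "resp")

    def test_eta_squared_monotone_in_F(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(8, 4))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = mixed_anova(summaries_from_matrix(y, groups), "resp").table
        # same stratum df: ordering by F must match ordering by eta_p2
        sub = res[res.effect.isin(["role", "role:group"])]
        assert (sub.sort_values("F").eta_p2.is_monotonic_increasing)


class TestPosthoc:
    def test_identical_groups_no_difference(self):
        y = np.tile(np.array([[0.2, 0.3, 0.4, 0.5]]), (8, 1))
        y = y + np.random.default_rng(1).normal(0, 0.01, size=(8, 4))
        ya = np.vstack([y[:4], y[:4]])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        ph = posthoc_pairwise(summaries_from_matrix(ya, groups), "resp")
        gc = ph[ph.contrast.str.startswith("a - b")]
        assert np.allclose(gc.estimate, 0.0, atol=1e-12)

    def test_single_group_rejected(self):
        y = np.random.default_rng(0).normal(size=(4, 4))
        with pytest.raises(ValueError):
            posthoc_pairwise(summaries_from_matrix(y, ["a"] * 4), "resp")

    def test_bonferroni_scales_p(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(10, 4))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        raw = posthoc_pairwise(summaries_from_matrix(y, groups), "resp")
        adj = posthoc_pairwise(summaries_from_matrix(y, groups), "resp", bonferroni=True)
        assert np.allclose(adj.p, np.minimum(1, raw.p * len(raw)))
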