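"""Preprocessing: missingness filter boundary, centering, lag pairing,
item diagnostics and internal consistency."""

import numpy as np
import pandas as pd
import pytest

import esmnet as en
from esmnet.preprocess import CENTERED_COLS, ITEM_COLS
from esmnet.simulate import NODES


def _mini_panel(values_by_person, family=None):
    """Panel with one item pattern per person: list of 6-vectors or None
    (missing beep), one day with consecutive beeps."""
    rows = []
    for pid, seq in values_by_person.items():
        for i, v in enumerate(seq):
            row = {"person_id": pid, "family_id": (family or {}).get(pid, pid),
                   "day": 1 + i // 10, "beep_in_day": 1 + i % 10,
                   "beep_number": i + 1, "time_min": 450.0 + 90 * (i % 10)
                   + 1440 * (i // 10)}
            for j, n in enumerate(NODES):
                row[n] = np.nan if v is None else float(v[j])
            rows.append(row)
    return pd.DataFrame(rows)


class TestMissingnessFilter:
    def test_thirty_percent_boundary_is_kept(self):
        seq = [[4] * 6] * 42 + [None] * 18
        panel = _mini_panel({"a": seq, "b": [[4] * 6] * 60})
        kept, rep = en.filter_by_missingness(panel, scheduled_beeps=60)
        assert set(kept["person_id"]) == {"a", "b"}
        assert rep.set_index("person_id").loc["a", "included"]

    def test_over_boundary_is_excluded(self):
        seq = [[4] * 6] * 41 + [None] * 19
        panel = _mini_panel({"a": seq, "b": [[4] * 6] * 60})
        kept, rep = en.filter_by_missingness(panel, scheduled_beeps=60)
        assert set(kept["person_id"]) == {"b"}

    def test_partial_beep_counts_as_missing(self):
        seq = [[4] * 6] * 60
        panel = _mini_panel({"a": seq})
        panel.loc[panel.index[:19], "down"] = np.nan   # 19 incomplete beeps
        kept, rep = en.filter_by_missingness(panel, scheduled_beeps=60)
        assert len(kept) == 0

    def test_kept_set_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        persons = {}
        for i in range(40):
            rate = rng.uniform(0, 0.6)
            persons[f"p{i:02d}"] = [
                None if rng.random() < rate else [rng.integers(1, 8)] * 6
                for _ in range(60)
            ]
        panel = _mini_panel(persons)
        kept, rep = en.filter_by_missingness(panel, scheduled_beeps=60)
        expected = {
            pid for pid, seq in persons.items()
            if (60 - sum(s is not None for s in seq)) / 60 <= 0.30
        }
        assert set(kept["person_id"]) == expected
        assert set(rep.loc[rep.included, "person_id"]) == expected

    def test_zero_observation_person_flagged(self):
        panel = _mini_panel({"a": [None] * 60, "b": [[4] * 6] * 60})
        kept, rep = en.filter_by_missingness(panel, scheduled_beeps=60)
        row = rep.set_index("person_id").loc["a"]
        assert not row["included"] and row["zero_observations"]


class TestCentering:
    def test_constant_series_centers_to_zero(self):
        panel = _mini_panel({"a": [[4] * 6] * 10, "b": [[2] * 6] * 10})
        out, means = en.person_mean_center(panel)
        assert np.allclose(out[CENTERED_COLS].to_numpy(), 0.0)
        assert np.allclose(means.loc["a"], 4.0)

    def test_two_point_series(self):
        panel = _mini_panel({"a": [[3] * 6, [5] * 6], "b": [[1] * 6, [7] * 6]})
        out, _ = en.person_mean_center(panel)
        a = out[out.person_id == "a"][CENTERED_COLS].to_numpy()
        assert np.allclose(a[0], -1.0) and np.allclose(a[1], 1.0)

    def test_translation_invariance(self, small_cohort):
        panel, _, _ = small_cohort
        shifted = panel.copy()
        pid = shifted["person_id"].iloc[0]
        mask = shifted["person_id"] == pid
        shifted.loc[mask, ITEM_COLS] = shifted.loc[mask, ITEM_COLS] + 2.0
        a, _ = en.person_mean_center(panel)
        b, _ = en.person_mean_center(shifted)
        np.testing.assert_allclose(
            a.loc[mask, CENTERED_COLS].to_numpy(),
            b.loc[mask, CENTERED_COLS].to_numpy(), atol=1e-12)

    def test_idempotence(self, small_cohort):
        panel, _, _ = small_cohort
        once, _ = en.person_mean_center(panel)
        pre_centered = panel.copy()
        pre_centered[ITEM_COLS] = once[CENTERED_COLS].to_numpy()
        twice, _ = en.person_mean_center(pre_centered)
        np.testing.assert_allclose(
            twice[CENTERED_COLS].to_numpy(),
            pre_centered[ITEM_COLS].to_numpy(), atol=1e-10)

    def test_per_person_centered_means_vanish(self, small_cohort):
        panel, _, _ = small_cohort
        out, _ = en.person_mean_center(panel)
        comp = out[en.complete_mask(out)]
        g = comp.groupby("person_id")[CENTERED_COLS].mean()
        assert np.abs(g.to_numpy()).max() < 1e-10

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            en.person_mean_center(_mini_panel({}).reindex(columns=[
                "person_id", "family_id", "day", "beep_in_day",
                "beep_number", "time_min", *NODES]))


class TestLagPairs:
    def test_ten_complete_beeps_give_nine_rows(self):
        panel = _mini_panel({"a": [[4] * 6] * 10})
        out, _ = en.person_mean_center(panel)
        design = en.build_lag_pairs(out)
        assert len(design) == 9

    def test_no_row_crosses_the_night(self):
        panel = _mini_panel({"a": [[4] * 6] * 20})   # 2 days x 10 beeps
        out, _ = en.person_mean_center(panel)
        design = en.build_lag_pairs(out)
        assert len(design) == 18
        assert (design["beep_number"] != 11).all()

    def test_row_count_matches_enumeration_oracle(self, small_cohort):
        panel, _, _ = small_cohort
        out, _ = en.person_mean_center(panel)
        design = en.build_lag_pairs(out)
        count = 0
        for _, df in panel.groupby("person_id"):
            df = df.sort_values("beep_number")
            comp = df[ITEM_COLS].notna().all(axis=1).to_numpy()
            days = df["day"].to_numpy()
            beeps = df["beep_number"].to_numpy()
            for i in range(1, len(df)):
                if (comp[i] and comp[i - 1] and beeps[i] == beeps[i - 1] + 1
                        and days[i] == days[i - 1]):
                    count += 1
        assert len(design) == count

    def test_missingness_never_increases_rows(self, small_cohort):
        panel, _, _ = small_cohort
        base, _ = en.make_lag_design(panel)
        more = en.apply_missingness(panel, 0.3, seed=0)
        fewer, _ = en.make_lag_design(more)
        assert len(fewer) <= len(base)

    def test_outcome_is_raw_and_predictor_is_centered(self):
        panel = _mini_panel({"a": [[3] * 6, [5] * 6, [4] * 6]})
        design, means = en.make_lag_design(panel)
        assert np.allclose(design["y_cheerful"], [5.0, 4.0])
        assert np.allclose(design["lag_cheerful"], [-1.0, 1.0])


class TestItemDiagnostics:
    def test_identical_groups_have_zero_differences(self, small_cohort):
        panel, _, _ = small_cohort
        ids = panel["person_id"].unique()
        # same data relabelled: duplicate persons into a mirrored group
        dup = panel.copy()
        dup["person_id"] = dup["person_id"] + "_dup"
        dup["family_id"] = dup["family_id"] + "_dup"
        both = pd.concat([panel, dup], ignore_index=True)
        assignment = {p: "A" for p in ids} | {p + "_dup": "B" for p in ids}
        d = en.item_diagnostics(both, assignment)
        assert np.allclose(d.mean_tests["difference"].to_numpy(), 0.0)
        assert np.allclose(d.sd_ratio.to_numpy(), 1.0)
        assert d.flags["sd_ratio_ok"].all()

    def test_duplicated_item_flags_correlation(self):
        rng = np.random.default_rng(3)
        persons = {f"p{i}": [list(rng.integers(1, 8, size=6)) for _ in range(30)]
                   for i in range(8)}
        panel = _mini_panel(persons)
        panel["relaxed"] = panel["cheerful"]         # two items made equal
        groups = {f"p{i}": "A" if i < 4 else "B" for i in range(8)}
        d = en.item_diagnostics(panel, groups)
        assert d.correlations.loc["cheerful", "relaxed"] == pytest.approx(1.0)
        assert not d.flags.loc["cheerful", "uncorrelated"]

    def test_sd_ratio_matches_direct_recomputation(self, small_cohort):
        cohort_panel, cohort_meta, _ = small_cohort
        assignment = cohort_meta.set_index("person_id")["true_group"].to_dict()
        d = en.item_diagnostics(cohort_panel, assignment)
        comp = cohort_panel[en.complete_mask(cohort_panel)]
        from esmnet.preprocess import _pooled_within_sd
        by_group = {}
        for g in ("Stable", "Increase"):
            ids = [p for p, lab in assignment.items() if lab == g]
            sub = comp[comp["person_id"].isin(ids)]
            by_group[g] = _pooled_within_sd(sub[ITEM_COLS], sub["person_id"])
        expected = np.maximum(by_group["Stable"], by_group["Increase"]) / \
            np.minimum(by_group["Stable"], by_group["Increase"])
        np.testing.assert_allclose(d.sd_ratio.to_numpy(), expected.to_numpy(),
                                   atol=1e-12)

    def test_label_swap_flips_difference_signs(self):
        cohort_panel, cohort_meta, _ = en.simulate_cohort(
            [en.stable_config(n_families=6), en.increase_config(n_families=6)],
            seed=9)
        assignment = cohort_meta.set_index("person_id")["true_group"].to_dict()
        swapped = {p: ("Increase" if g == "Stable" else "Stable")
                   for p, g in assignment.items()}
        a = en.item_diagnostics(cohort_panel, assignment)
        b = en.item_diagnostics(cohort_panel, swapped)
        np.testing.assert_allclose(a.mean_tests["difference"].to_numpy(),
                                   -b.mean_tests["difference"].to_numpy(),
                                   atol=1e-12)
        pd.testing.assert_frame_equal(a.flags, b.flags)

    def test_single_person_group_rejected(self):
        panel = _mini_panel({"a": [[4] * 6] * 10, "b": [[4] * 6] * 10,
                             "c": [[4] * 6] * 10})
        with pytest.raises(ValueError, match="fewer than two"):
            en.item_diagnostics(panel, {"a": "A", "b": "A", "c": "B"})


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.arange(10.0)
        table = np.column_stack([x, x])
        assert en.cronbach_alpha(table) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(4)
        table = rng.normal(size=(4000, 4))
        assert abs(en.cronbach_alpha(table)) < 0.1

    def test_closed_form_for_exact_half_correlation(self):
        # construct 4 items with *exact* pairwise sample correlation 0.5
        # from orthonormal columns: x_i = sqrt(r) f + sqrt(1-r) e_i;
        # Spearman-Brown gives alpha = k r / (1 + (k-1) r) = 2/2.5 = 0.8
        n, k, r = 64, 4, 0.5
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(n, k + 1))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        f, es = q[:, 0], q[:, 1:]
        table = np.sqrt(r) * f[:, None] + np.sqrt(1 - r) * es
        corr = np.corrcoef(table, rowvar=False)
        assert np.allclose(corr - np.eye(k), (1 - np.eye(k)) * r, atol=1e-10)
        assert en.cronbach_alpha(table) == pytest.approx(0.8, abs=1e-10)

    def test_error_paths(self):
        with pytest.raises(ValueError):
            en.cronbach_alpha(np.ones((10, 1)))
        with pytest.raises(ValueError):
            en.cronbach_alpha(np.ones((1, 4)))
        with pytest.raises(ValueError):
            en.cronbach_alpha(np.ones((10, 4)))     # zero total variance
        bad = np.random.default_rng(0).normal(size=(10, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            en.cronbach_alpha(bad)
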