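"""Symmetry decomposition, Procrustes ANOVA, and FA index tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from asymlink.procrustes import procrustes_distance, reflect
from asymlink.simulate import SyntheticConfig, make_landmarks
from asymlink.symmetry import (
    error_study,
    fa2,
    fa_scores,
    matching_decomposition,
    object_decomposition,
    procrustes_anova,
)


def wing_config(**kw):
    defaults = dict(seed=1, n_individuals=12, k=10, symmetry_mode="matching",
                    sd_individual=0.03, sd_fa=0.01, sd_digit=0.002, sd_size=0.05,
                    sd_size_fa=0.01)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def head_config(**kw):
    defaults = dict(seed=2, n_individuals=12, k=29, symmetry_mode="object",
                    sd_individual=0.03, sd_fa=0.01, sd_digit=0.002)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestMatchingDecomposition:
    def test_perfectly_symmetric_sides_coincide(self):
        cfg = wing_config(sd_fa=0, sd_digit=0, sd_image=0, sd_size_fa=0)
        dec = matching_decomposition(make_landmarks(cfg))
        scores = fa_scores(dec)
        assert scores["fa_shape"].max() < 1e-8
        assert np.abs(scores["fa2_size"]).max() < 1e-9

    def test_fa_only_data_have_no_individual_signal(self):
        cfg = wing_config(sd_individual=0, sd_fa=0.02, sd_digit=0, n_individuals=40)
        table = procrustes_anova(matching_decomposition(make_landmarks(cfg))).set_index("effect")
        assert table.loc["fluctuating_asymmetry", "SS"] > 10 * table.loc["individual", "SS"]

    def test_individual_missing_a_side_is_excluded_with_warning(self):
        ds = make_landmarks(wing_config())
        ds.configs = [c for c in ds.configs
                      if not (c.classifiers["individual"] == "ind001"
                              and c.classifiers["side"] == "left")]
        with pytest.warns(UserWarning, match="ind001"):
            dec = matching_decomposition(ds)
        assert "ind001" not in set(dec.meta["individual"])

    def test_replicate_structure_carried_through(self):
        cfg = wing_config(n_image_rep=2, n_digit_rep=2, n_individuals=5)
        dec = matching_decomposition(make_landmarks(cfg))
        counts = dec.meta.groupby(["individual", "side", "image_rep", "digit_rep"]).size()
        assert (counts == 1).all()
        assert len(dec.meta) == 5 * 2 * 2 * 2


class TestObjectDecomposition:
    def test_exactly_symmetric_configuration_has_no_asymmetry(self):
        cfg = head_config(sd_fa=0, sd_digit=0, sd_size_fa=0)
        dec = object_decomposition(make_landmarks(cfg))
        assert fa_scores(dec)["fa_shape"].max() < 1e-8

    def test_doubled_consensus_is_symmetric_under_reflect_relabel(self):
        dec = object_decomposition(make_landmarks(head_config()))
        perm = np.arange(dec.k)
        for left, right in dec.pairing:
            perm[left - 1], perm[right - 1] = right - 1, left - 1
        mirrored = reflect(dec.consensus, "y")[perm]
        assert procrustes_distance(dec.consensus, mirrored) < 1e-8

    def test_component_dimensions_sum_to_shape_dimension(self):
        dec = object_decomposition(make_landmarks(head_config()))
        sym, asym = dec.component_dims
        assert sym == asym == 2 * 13 + 3 - 2 == 27
        assert sym + asym == 2 * 29 - 4


class TestProcrustesAnova:
    def test_ss_additivity_is_exact(self):
        for cfg in (wing_config(n_digit_rep=2), head_config(n_digit_rep=2)):
            dec = (matching_decomposition if cfg.symmetry_mode == "matching"
                   else object_decomposition)(make_landmarks(cfg))
            table = procrustes_anova(dec)
            assert table["SS"].sum() == pytest.approx(table.attrs["total_SS"], rel=1e-10)
            assert np.allclose(table["SS"], table["MS"] * table["df"])

    def test_zero_fa_and_zero_error_give_zero_fa_ss(self):
        cfg = wing_config(sd_fa=0, sd_digit=0, sd_size_fa=0)
        table = procrustes_anova(matching_decomposition(make_landmarks(cfg))).set_index("effect")
        assert table.loc["fluctuating_asymmetry", "SS"] < 1e-16

    def test_goodall_df_follow_design_counts(self):
        n, k, reps = 15, 10, 2
        cfg = wing_config(n_individuals=n, k=k, n_digit_rep=reps)
        table = procrustes_anova(matching_decomposition(make_landmarks(cfg))).set_index("effect")
        d = 2 * k - 4
        assert table.loc["individual", "df"] == (n - 1) * d
        assert table.loc["fluctuating_asymmetry", "df"] == (n - 1) * d
        assert table.loc["directional_asymmetry", "df"] == d
        assert table.loc["digitizing_error", "df"] == n * 2 * (reps - 1) * d

    def test_object_mode_without_replication_omits_fa_test(self):
        table = procrustes_anova(object_decomposition(make_landmarks(head_config(n_digit_rep=1))))
        fa_row = table.set_index("effect").loc["fluctuating_asymmetry"]
        assert np.isnan(fa_row["F"]) and np.isnan(fa_row["p"])

    def test_object_mode_with_replication_tests_fa_over_error(self):
        table = procrustes_anova(
            object_decomposition(make_landmarks(head_config(n_digit_rep=2)))
        ).set_index("effect")
        assert np.isfinite(table.loc["fluctuating_asymmetry", "F"])
        assert table.loc["fluctuating_asymmetry", "p"] < 0.05  # injected FA >> error

    def test_location_effect_rows_emitted_for_grouped_ants(self):
        from asymlink.simulate import make_study

        bundle = make_study(seed=3, n_bees=(6, 3), n_aquilonia=(8, 6), n_exsecta=(5, 5),
                            nests_aquilonia=(2, 2), nests_exsecta=(2, 2))
        dec = object_decomposition(bundle.heads["F_aquilonia"])
        table = procrustes_anova(dec)
        effects = list(table["effect"])
        assert effects.index("location") < effects.index("individual") < effects.index(
            "fluctuating_asymmetry"
        )

    def test_variance_component_recovery_via_ems(self):
        # injected FA variance 4e-4 and error 4e-6 per coordinate, two
        # digitizing runs: (MS_FA - MS_err) / 2 should recover 4e-4
        cfg = wing_config(seed=7, n_individuals=200, sd_fa=0.02, sd_digit=0.002,
                          n_digit_rep=2, sd_size=0.0)
        table = procrustes_anova(matching_decomposition(make_landmarks(cfg))).set_index("effect")
        est = (table.loc["fluctuating_asymmetry", "MS"]
               - table.loc["digitizing_error", "MS"]) / 2.0
        assert est == pytest.approx(4e-4, rel=0.15)


class TestErrorStudy:
    def test_small_errors_yield_nonsignificant_verdict(self):
        # error variance 100x below FA variance; the imaging stratum
        # carries no variance of its own, so its F against digitizing
        # noise is near 1 and the error strata are nonsignificant
        cfg = wing_config(n_individuals=20, sd_fa=0.02, sd_image=0.0, sd_digit=0.002,
                          n_image_rep=2, n_digit_rep=2)
        table, verdict = error_study(matching_decomposition(make_landmarks(cfg)))
        assert verdict["errors_nonsignificant"]
        assert verdict["ms_individual_exceeds_error"]
        assert verdict["ms_fa_exceeds_error"]
        assert verdict["fa_significant"]

    def test_real_imaging_variance_is_flagged_significant(self):
        cfg = wing_config(n_individuals=20, sd_fa=0.02, sd_image=0.004, sd_digit=0.002,
                          n_image_rep=2, n_digit_rep=2)
        _, verdict = error_study(matching_decomposition(make_landmarks(cfg)))
        assert verdict["imaging_error"] == "significant"

    def test_zero_measurement_error_gives_vanishing_error_ms(self):
        cfg = wing_config(sd_digit=0, sd_image=0, n_digit_rep=2)
        table, _ = error_study(matching_decomposition(make_landmarks(cfg)))
        assert table.set_index("effect").loc["digitizing_error", "MS"] < 1e-16

    def test_null_fa_is_not_significant_against_error(self):
        cfg = wing_config(seed=13, n_individuals=30, sd_fa=0.0, sd_size_fa=0.0,
                          sd_digit=0.002, n_digit_rep=2)
        _, verdict = error_study(matching_decomposition(make_landmarks(cfg)))
        assert not verdict["fa_significant"]

    def test_without_replication_refuses(self):
        with pytest.raises(ValueError, match="repeated imaging or digitizing"):
            error_study(matching_decomposition(make_landmarks(wing_config(n_digit_rep=1))))


class TestFa2:
    def test_printed_example(self):
        assert fa2(11, 9) == pytest.approx(0.2)
        assert fa2(10, 10) == 0.0

    def test_relative_size_difference_closed_form(self):
        # R = L (1 + delta)  =>  fa2 = delta / (1 + delta / 2)
        delta = 0.01
        assert fa2(100 * (1 + delta), 100) == pytest.approx(delta / (1 + delta / 2))
        assert fa2(100 * (1 + delta), 100) == pytest.approx(0.00995, abs=5e-6)

    @given(st.floats(0.1, 1e6), st.floats(0.1, 1e6), st.floats(0.1, 1e3))
    def test_antisymmetry_and_scale_invariance(self, r, l, scale):
        assert fa2(r, l) == pytest.approx(-fa2(l, r))
        assert fa2(scale * r, scale * l) == pytest.approx(fa2(r, l), rel=1e-9)

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            fa2(0.0, 1.0)


class TestFaScores:
    def test_uniform_rescaling_leaves_fa2_unchanged(self):
        ds1 = make_landmarks(wing_config())
        ds2 = make_landmarks(wing_config())
        for c in ds2.configs:
            c.coords = c.coords * 2.0
        s1 = fa_scores(matching_decomposition(ds1))
        s2 = fa_scores(matching_decomposition(ds2))
        assert np.allclose(s1["fa2_size"], s2["fa2_size"])
        assert np.allclose(s1["fa_shape"], s2["fa_shape"], atol=1e-9)

    def test_fa_shape_invariant_to_similarity_transforms_of_inputs(self, rng):
        ds1 = make_landmarks(wing_config())
        ds2 = make_landmarks(wing_config())
        for c in ds2.configs:
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            c.coords = rng.uniform(0.5, 2.0) * c.coords @ rot.T + rng.uniform(-9, 9, 2)
        s1 = fa_scores(matching_decomposition(ds1))
        s2 = fa_scores(matching_decomposition(ds2))
        assert np.allclose(s1["fa_shape"], s2["fa_shape"], atol=1e-7)

    def test_mean_fa2_tracks_injected_size_asymmetry(self):
        # deterministic size asymmetry delta via direct size computation
        cfg = wing_config(seed=21, n_individuals=300, sd_size_fa=0.01, sd_fa=0, sd_digit=0)
        scores = fa_scores(matching_decomposition(make_landmarks(cfg)))
        assert scores["fa2_size"].std() == pytest.approx(0.01, rel=0.2)
        assert abs(scores["fa2_size"].mean()) < 0.002

    def test_directional_asymmetry_is_removed_from_fa_shape(self):
        with_da = wing_config(seed=5, n_individuals=80, sd_da=0.05, sd_fa=0.005, sd_digit=0)
        no_da = wing_config(seed=5, n_individuals=80, sd_da=0.0, sd_fa=0.005, sd_digit=0)
        s_da = fa_scores(matching_decomposition(make_landmarks(with_da)))
        s_no = fa_scores(matching_decomposition(make_landmarks(no_da)))
        # a strong common DA must not inflate individual FA scores
        assert s_da["fa_shape"].mean() < 3 * s_no["fa_shape"].mean()
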