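"""The screen statistic: baseline, effects, robust scales, classes, hit calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfscreen import (
    CONTROL_LABEL,
    ConditionProfiles,
    ScreenConfig,
    build_effect_table,
    call_hits,
    classify,
    compute_baseline,
    compute_effects,
    count_hits,
    effect_to_fc,
    estimate_expected_variation,
    ma_table,
    screen_pipeline,
)
from orfscreen.screen import HitSet

from .oracle import oracle_screen, random_screen


def _profiles(rows, conditions, genes=None):
    genes = genes or [f"G{i}" for i in range(len(rows))]
    return ConditionProfiles(
        pd.DataFrame(rows, index=genes, columns=conditions, dtype=float)
    )


class TestBaselineAndEffects:
    def test_median_odd(self):
        p = _profiles([[4.0, 6.0, 8.0]], ["A", "B", CONTROL_LABEL])
        assert compute_baseline(p).iloc[0] == 6.0

    def test_median_even_mean_of_middle_two(self):
        p = _profiles([[4.0, 6.0, 8.0, 100.0]], ["A", "B", "C", CONTROL_LABEL])
        assert compute_baseline(p).iloc[0] == 7.0

    def test_all_equal_gives_zero_effects(self):
        p = _profiles([[5.5] * 4], ["A", "B", "C", CONTROL_LABEL])
        b = compute_baseline(p)
        assert b.iloc[0] == 5.5
        assert (compute_effects(p, b).iloc[0] == 0).all()

    def test_control_exclusion_toggle(self):
        p = _profiles([[4.0, 6.0, 20.0]], ["A", "B", CONTROL_LABEL])
        assert compute_baseline(p, include_control=True).iloc[0] == 6.0
        assert compute_baseline(p, include_control=False).iloc[0] == 5.0

    def test_unit_effect_is_twofold(self):
        p = _profiles([[7.0, 6.0, 5.0]], ["A", "B", CONTROL_LABEL])
        b = pd.Series([6.0], index=p.genes)
        x = compute_effects(p, b)
        assert x.loc["G0", "A"] == 1.0
        assert effect_to_fc(x.loc["G0", "A"]) == 2.0
        assert x.loc["G0", "B"] == 0.0
        assert x.loc["G0", CONTROL_LABEL] == -1.0
        assert effect_to_fc(x.loc["G0", CONTROL_LABEL]) == 0.5

    def test_gene_universe_mismatch(self):
        p = _profiles([[1.0, 2.0]], ["A", CONTROL_LABEL])
        with pytest.raises(ValueError, match="universe"):
            compute_effects(p, pd.Series([1.0], index=["other"]))

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            compute_baseline(_profiles([[1.0]], [CONTROL_LABEL]))


class TestEffectToFC:
    @pytest.mark.parametrize("x,fc", [(1.0, 2.0), (0.0, 1.0), (-2.0, 0.25)])
    def test_known_values(self, x, fc):
        assert effect_to_fc(x) == fc

    @settings(deadline=None, derandomize=True)
    @given(x=st.floats(min_value=-30, max_value=30))
    def test_duality(self, x):
        assert effect_to_fc(x) * effect_to_fc(-x) == pytest.approx(1.0, rel=1e-12)

    def test_strictly_increasing(self):
        xs = np.linspace(-5, 5, 101)
        assert (np.diff(effect_to_fc(xs)) > 0).all()


class TestExpectedVariation:
    def test_mad_robust_to_outlier(self):
        effects = pd.DataFrame([[-0.2, -0.1, 0.0, 0.1, 0.2, 10.0]], index=["G0"])
        detected = pd.Series([True], index=["G0"])
        s = estimate_expected_variation(
            effects, detected, ScreenConfig(variance_floor=1e-6)
        )
        assert s["G0"] == pytest.approx(0.15 * 1.4826, abs=1e-12)

    def test_constant_effects_hit_floor(self):
        effects = pd.DataFrame([[0.3, 0.3, 0.3, 0.3]], index=["G0"])
        detected = pd.Series([True], index=["G0"])
        s = estimate_expected_variation(
            effects, detected, ScreenConfig(variance_floor=0.5)
        )
        assert s["G0"] == 0.5

    def test_auto_floor_quarter_of_median_scale(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (21, 9))
        vals[0] = 0.0  # degenerate gene
        effects = pd.DataFrame(vals, index=[f"G{i}" for i in range(21)])
        detected = pd.Series(True, index=effects.index)
        s = estimate_expected_variation(effects, detected, ScreenConfig())
        raw = np.median(np.abs(vals - np.median(vals, axis=1, keepdims=True)), axis=1) * 1.4826
        expected_floor = 0.25 * np.median(raw)
        assert s["G0"] == pytest.approx(expected_floor)
        assert (s >= expected_floor - 1e-12).all()

    def test_sd_estimator_monte_carlo(self):
        """On standard-normal effects the SD estimator recovers sigma = 1."""
        rng = np.random.default_rng(1)
        effects = pd.DataFrame(rng.normal(0, 1, (5, 10_000)),
                               index=[f"G{i}" for i in range(5)])
        detected = pd.Series(True, index=effects.index)
        s = estimate_expected_variation(
            effects, detected,
            ScreenConfig(variance_estimator="sd", variance_floor=1e-6),
        )
        assert np.allclose(s, 1.0, rtol=0.05)

    def test_undetected_genes_get_nan(self):
        effects = pd.DataFrame([[0.1, -0.1, 0.2], [1.0, -1.0, 0.5]],
                               index=["G0", "G1"])
        detected = pd.Series([False, True], index=["G0", "G1"])
        s = estimate_expected_variation(
            effects, detected, ScreenConfig(variance_floor=0.01)
        )
        assert np.isnan(s["G0"]) and s["G1"] > 0

    def test_too_few_conditions(self):
        effects = pd.DataFrame([[0.1, 0.2]], index=["G0"])
        with pytest.raises(ValueError, match="3 conditions"):
            estimate_expected_variation(effects, pd.Series([True], index=["G0"]))

    def test_degenerate_auto_floor_raises(self):
        effects = pd.DataFrame([[0.0, 0.0, 0.0]], index=["G0"])
        with pytest.raises(ValueError, match="floor"):
            estimate_expected_variation(effects, pd.Series([True], index=["G0"]))


class TestClassify:
    def _labels(self, baseline, zvals):
        b = pd.Series(baseline, index=[f"G{i}" for i in range(len(baseline))])
        z = pd.DataFrame({"A": zvals}, index=b.index)
        return classify(b, z)["A"]

    def test_fig_classes(self):
        labels = self._labels([6.0, 6.0, 6.0, 2.9], [1.5, -4.5, 2.5, 8.0])
        assert labels.tolist() == ["within", "outside", "suggestive", "below_detection"]

    def test_boundaries_inclusive(self):
        # |Z| exactly at a threshold stays in the lower class
        labels = self._labels([6.0, 6.0, 3.0], [2.0, -4.0, 0.0])
        assert labels.tolist() == ["within", "suggestive", "within"]


def _effect_table(rows):
    cols = ["gene", "condition", "baseline", "effect", "fc", "scale", "z",
            "detected", "label"]
    return pd.DataFrame(rows, columns=cols)


class TestCallHits:
    def test_rule_application(self):
        table = _effect_table([
            ("G1", "A", 6.0, 1.5, 2.8, 0.36, 4.2, True, "outside"),
            ("G2", "A", 6.0, 0.9, 1.9, 0.18, 5.0, True, "outside"),
            ("G3", "A", 6.0, -1.5, 0.35, 0.5, -3.0, True, "suggestive"),
            ("G4", "A", 2.5, 2.0, 4.0, np.nan, np.nan, False, "below_detection"),
            ("G5", CONTROL_LABEL, 6.0, 1.5, 2.8, 0.3, 5.0, True, "outside"),
        ])
        hitsets = call_hits(table)
        assert CONTROL_LABEL not in hitsets
        hs = hitsets["A"].table.set_index("gene")
        assert hs.loc["G1", "direction"] == "up" and hs.loc["G1", "tier"] == "hit"
        assert "G2" not in hs.index  # fold <= 2
        assert hs.loc["G3", "direction"] == "down" and hs.loc["G3", "tier"] == "suggestive"
        assert "G4" not in hs.index  # below detection

    def test_count_hits_ordering_and_partition(self):
        hitsets = {
            "B": HitSet("B", pd.DataFrame(
                {"gene": ["G1", "G2", "G3"], "direction": ["up", "down", "up"],
                 "tier": ["hit", "hit", "suggestive"]})),
            "A": HitSet("A", pd.DataFrame(
                {"gene": ["G1", "G2"], "direction": ["up", "down"],
                 "tier": ["hit", "hit"]})),
            "C": HitSet("C", pd.DataFrame(columns=["gene", "direction", "tier"])),
        }
        counts = count_hits(hitsets)
        # suggestive entries are not counted; ties break alphabetically
        assert counts["condition"].tolist() == ["A", "B", "C"]
        assert counts.loc[0].tolist() == ["A", 1, 1, 2]
        assert counts.loc[1].tolist() == ["B", 1, 1, 2]
        assert counts.loc[2].tolist() == ["C", 0, 0, 0]


class TestScreenProperties:
    def test_threshold_monotonicity(self, small_screen):
        """Raising z_hit or fold_threshold never adds a hit."""
        _, (matrix, sheet, _) = small_screen

        def hit_triples(config):
            _, hitsets, _ = screen_pipeline(matrix, sheet, config)
            return {
                (c, g, d) for c, hs in hitsets.items() for g, d in hs.signed("hit")
            }

        base = hit_triples(ScreenConfig())
        assert hit_triples(ScreenConfig(z_hit=5.0)) <= base
        assert hit_triples(ScreenConfig(fold_threshold=3.0)) <= base
        assert hit_triples(ScreenConfig(fold_threshold=3.0, z_hit=6.0)) <= base

    def test_condition_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        conds = ["A", "B", "C", "D", CONTROL_LABEL]
        p = _profiles(rng.normal(6, 2, (30, 5)), conds)
        table = build_effect_table(p)
        perm = ConditionProfiles(p.values[["C", CONTROL_LABEL, "A", "D", "B"]])
        table2 = build_effect_table(perm)
        key = ["gene", "condition"]
        merged = table.set_index(key).sort_index().join(
            table2.set_index(key).sort_index(), rsuffix="_p"
        )
        for col in ("baseline", "effect", "scale", "z"):
            a, b = merged[col], merged[f"{col}_p"]
            assert ((a == b) | (a.isna() & b.isna())).all()
        assert (merged["label"] == merged["label_p"]).all()

    def test_ma_table_consistent_with_classes(self, small_screen):
        _, (matrix, sheet, _) = small_screen
        effect_table, _, _ = screen_pipeline(matrix, sheet)
        ma = ma_table(effect_table)
        assert len(ma) == len(effect_table)
        assert (
            ma["label"].value_counts().to_dict()
            == effect_table["label"].value_counts().to_dict()
        )

    def test_ma_table_round_trip_six_decimals(self, tmp_path, small_screen):
        _, (matrix, sheet, _) = small_screen
        effect_table, _, _ = screen_pipeline(matrix, sheet)
        ma = ma_table(effect_table)
        path = tmp_path / "ma.tsv"
        ma.to_csv(path, sep="\t", index=False, float_format="%.6f")
        back = pd.read_csv(path, sep="\t")
        assert np.allclose(back["effect"], ma["effect"], atol=5e-7)
        assert np.allclose(back["baseline"], ma["baseline"], atol=5e-7)

    def test_matches_bruteforce_oracle(self):
        """Vectorized pipeline equals direct-formula evaluation, value for value."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            matrix, sheet = random_screen(rng)
            config = ScreenConfig()
            ref = oracle_screen(matrix, sheet, config)
            table, hitsets, _ = screen_pipeline(matrix, sheet, config)
            for row in table.itertuples(index=False):
                key = (row.gene, row.condition)
                assert row.baseline == ref["baseline"][row.gene]
                assert row.effect == ref["effect"][key]
                assert row.detected == ref["detected"][row.gene]
                assert row.label == ref["label"][key]
            called = {
                c: {g: (d,) for g, d in hs.signed("hit")} for c, hs in hitsets.items()
            }
            expected = {
                c: {g: (dt[0],) for g, dt in hits.items() if dt[1] == "hit"}
                for c, hits in ref["hits"].items()
            }
            assert called == expected


class TestScreenConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"fold_threshold": 1.0},
            {"z_hit": 2.0, "z_suggestive": 2.0},
            {"z_hit": -1.0},
            {"variance_estimator": "iqr"},
            {"variance_floor": -0.1},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            ScreenConfig(**kw)

    def test_log2_threshold(self):
        assert ScreenConfig().log2_fold_threshold == 1.0
        assert ScreenConfig(fold_threshold=4.0).log2_fold_threshold == 2.0
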