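"""Index formulas against independent brute-force oracles, plus the
classification schemes and their structural properties."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riverwq as wq
from riverwq.errors import (
    ClassificationError,
    ConfigurationError,
    IncompleteIndexError,
)
from riverwq.indices import CLASS_ORDER

# ---------------------------------------------------------------------------
# independent one-liner oracles (never share code with the implementation)

def oracle_mwqi(values, standards):
    aw = {c: standards[c].assigned_weight for c in standards.mwqi_set}
    total = sum(aw.values())

    def q(c):
        s, v = standards[c].permissible_limit, standards[c].ideal_value
        return ((values[c] - v) / (s - v) if v is not None else values[c] / s) * 100

    return sum(aw[c] / total * q(c) for c in standards.mwqi_set)


def oracle_hpi(values, standards):
    s = {c: standards[c].permissible_limit for c in standards.hpi_set}
    num = sum((1 / s[c]) * (values[c] / s[c] * 100) for c in s)
    return num / sum(1 / s[c] for c in s)


def oracle_ri(values, standards):
    return sum(
        standards[c].toxic_response * values[c] / standards[c].reference_value
        for c in standards.ri_set
    )


def oracle_tsi(sd, tp, chla):
    return (
        (60.0 - 14.41 * math.log(sd))
        + (14.42 * math.log(tp) + 4.15)
        + (30.6 + 9.81 * math.log(chla))
    ) / 3


def random_valid_values(rng, standards):
    values = {}
    for code, spec in standards.parameters.items():
        if code == "ph":
            values[code] = rng.uniform(1, 13)
        elif code == "sd":
            values[code] = rng.uniform(0.1, 10)
        else:
            scale = spec.permissible_limit or 100.0
            values[code] = rng.uniform(0, 3 * scale)
    return values


# ---------------------------------------------------------------------------


class TestRelativeWeights:
    def test_printed_weights_normalise_against_their_sum(self, standards):
        rw = wq.relative_weights(standards)
        assert rw["do"] == pytest.approx(2.85 / 16.95, rel=1e-12)
        assert rw["ph"] == pytest.approx(1.0 / 16.95, rel=1e-12)

    def test_weights_sum_to_one(self, standards):
        assert sum(wq.relative_weights(standards).values()) == pytest.approx(1.0)

    def test_equal_assigned_weights_give_equal_relative_weights(self, standards):
        params = {
            c: wq.ParameterSpec(c, c, "mg/l", permissible_limit=10.0, assigned_weight=1.0)
            for c in ("a", "b", "c", "d")
        }
        table = wq.StandardsTable(params, ("a", "b", "c", "d"), (), (), ())
        rw = wq.relative_weights(table)
        assert all(v == pytest.approx(0.25) for v in rw.values())

    def test_empty_mwqi_set_is_a_configuration_error(self):
        table = wq.StandardsTable({}, (), (), (), ())
        with pytest.raises(ConfigurationError):
            wq.relative_weights(table)


class TestQualityRating:
    def test_ratio_form_for_ordinary_parameters(self, standards):
        assert wq.quality_rating("tds", 740.65, standards) == pytest.approx(148.13)

    @pytest.mark.parametrize("code", ["tds", "cl", "bod", "no3"])
    def test_concentration_at_the_limit_rates_100(self, standards, code):
        s = standards[code].permissible_limit
        assert wq.quality_rating(code, s, standards) == pytest.approx(100.0)

    def test_do_anchor_points(self, standards):
        assert wq.quality_rating("do", 14.6, standards) == pytest.approx(0.0)
        assert wq.quality_rating("do", 6.0, standards) == pytest.approx(100.0)

    def test_ph_rated_against_upper_band(self, standards):
        assert wq.quality_rating("ph", 7.0, standards) == pytest.approx(0.0)
        assert wq.quality_rating("ph", 8.5, standards) == pytest.approx(100.0)
        assert wq.quality_rating("ph", 7.46, standards) == pytest.approx(
            0.46 / 1.5 * 100
        )

    def test_limit_equal_to_ideal_is_degenerate(self):
        params = {
            "ph": wq.ParameterSpec(
                "ph", "pH", "pH units", permissible_limit=7.0, ideal_value=7.0
            )
        }
        table = wq.StandardsTable(params, (), (), (), ())
        with pytest.raises(ZeroDivisionError):
            wq.quality_rating("ph", 8.0, table)


class TestMWQI:
    def test_all_parameters_at_their_limits_scores_100(self, standards):
        values = {c: standards[c].permissible_limit for c in standards.mwqi_set}
        values["ph"], values["do"] = 8.5, 6.0
        assert wq.mwqi(values, standards).value == pytest.approx(100.0)

    def test_pristine_water_scores_0(self, standards):
        values = {c: 0.0 for c in standards.mwqi_set}
        values["ph"], values["do"] = 7.0, 14.6
        assert wq.mwqi(values, standards).value == pytest.approx(0.0)

    def test_components_sum_to_value(self, standards, pre_means):
        result = wq.mwqi(pre_means, standards)
        assert sum(result.components.values()) == pytest.approx(result.value)
        assert set(result.components) == set(standards.mwqi_set)

    def test_missing_member_aborts_with_its_name(self, standards, pre_means):
        values = {c: v for c, v in pre_means.items() if c != "bod"}
        with pytest.raises(IncompleteIndexError, match="bod"):
            wq.mwqi(values, standards)


class TestHPI:
    def test_all_metals_at_their_limits_scores_100(self, standards):
        values = {c: standards[c].permissible_limit for c in standards.hpi_set}
        assert wq.hpi(values, standards).value == pytest.approx(100.0)

    def test_single_metal_at_half_limit_scores_50(self):
        params = {"cd": wq.ParameterSpec("cd", "Cadmium", "ug/l", permissible_limit=10.0)}
        table = wq.StandardsTable(params, (), ("cd",), (), ())
        assert wq.hpi({"cd": 5.0}, table).value == pytest.approx(50.0)

    def test_unit_invariance_under_common_rescaling(self, standards):
        rng = np.random.default_rng(11)
        values = random_valid_values(rng, standards)
        base = wq.hpi(values, standards).value
        config = wq.standards_to_config(standards)
        for c in standards.hpi_set:
            config["parameters"][c]["permissible_limit"] *= 1000.0
        rescaled_std = wq.load_standards(config)
        scaled_values = {c: v * 1000.0 for c, v in values.items()}
        assert wq.hpi(scaled_values, rescaled_std).value == pytest.approx(base)

    def test_missing_metal_aborts(self, standards, pre_means):
        values = {c: v for c, v in pre_means.items() if c != "ni"}
        with pytest.raises(IncompleteIndexError, match="ni"):
            wq.hpi(values, standards)


class TestEcologicalRisk:
    def test_all_metals_at_reference_gives_sum_of_toxic_responses(self, standards):
        values = {c: standards[c].reference_value for c in standards.ri_set}
        breakdown = wq.ecological_risk(values, standards)
        assert breakdown.total_risk == pytest.approx(38.0)
        assert breakdown.degree_of_contamination == pytest.approx(4.0)

    def test_cadmium_alone_dominates(self, standards):
        values = {"cd": 10.20, "pb": 0.0, "cr": 0.0, "zn": 0.0}
        breakdown = wq.ecological_risk(values, standards)
        assert breakdown.risk_factors["cd"] == pytest.approx(306.0)
        assert breakdown.total_risk == pytest.approx(306.0)

    def test_total_risk_is_the_sum_of_risk_factors(self, standards, pre_means):
        breakdown = wq.ecological_risk(pre_means, standards)
        assert breakdown.total_risk == pytest.approx(
            sum(breakdown.risk_factors.values())
        )

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(derandomize=True, max_examples=25)
    def test_strictly_increasing_in_each_metal(self, delta):
        standards = wq.load_standards()
        base = {"cd": 2.0, "pb": 10.0, "cr": 20.0, "zn": 500.0}
        base_ri = wq.ecological_risk(base, standards).total_risk
        for metal in base:
            bumped = dict(base, **{metal: base[metal] + delta})
            assert wq.ecological_risk(bumped, standards).total_risk > base_ri


class TestTSI:
    def test_unit_inputs_isolate_the_carlson_intercepts(self):
        result = wq.tsi(1.0, 1.0, 1.0)
        assert result.components == pytest.approx(
            {"sd": 60.0, "tp": 4.15, "chla": 30.6}
        )
        assert result.value == pytest.approx((60.0 + 4.15 + 30.6) / 3)

    @pytest.mark.parametrize(
        "bad", [(0.0, 1, 1), (1, -2.0, 1), (1, 1, 0.0)],
    )
    def test_nonpositive_inputs_are_a_domain_error(self, bad):
        with pytest.raises(ValueError, match="> 0"):
            wq.tsi(*bad)

    def test_decreasing_in_transparency_increasing_in_nutrients(self):
        base = wq.tsi(2.0, 30.0, 40.0).value
        assert wq.tsi(3.0, 30.0, 40.0).value < base
        assert wq.tsi(2.0, 45.0, 40.0).value > base
        assert wq.tsi(2.0, 30.0, 60.0).value > base

    def test_tsi_from_record_uses_the_registry_set(self, standards, campaign):
        rec = campaign[0]
        direct = wq.tsi(rec.values["sd"], rec.values["tp"], rec.values["chla"])
        assert wq.tsi_from(rec, standards).value == pytest.approx(direct.value)


class TestOracleEquivalence:
    """Each index matches a naively coded oracle on 1,000 random inputs."""

    def test_mwqi_hpi_ri_tsi_match_brute_force(self, standards):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            values = random_valid_values(rng, standards)
            assert wq.mwqi(values, standards).value == pytest.approx(
                oracle_mwqi(values, standards), rel=1e-9
            )
            assert wq.hpi(values, standards).value == pytest.approx(
                oracle_hpi(values, standards), rel=1e-9
            )
            assert wq.ecological_risk(values, standards).total_risk == pytest.approx(
                oracle_ri(values, standards), rel=1e-9
            )
            assert wq.tsi(
                values["sd"], max(values["tp"], 0.1), max(values["chla"], 0.1)
            ).value == pytest.approx(
                oracle_tsi(values["sd"], max(values["tp"], 0.1), max(values["chla"], 0.1)),
                rel=1e-9,
            )


class TestLinearity:
    """MWQI, HPI and RI are affine in concentrations: index of the phase-mean
    vector equals the mean of per-sample indices."""

    @pytest.mark.parametrize("func", [wq.mwqi, wq.hpi, wq.ri])
    def test_index_of_mean_equals_mean_of_index(self, standards, campaign, func):
        phase_recs = [r for r in campaign if r.phase == "lockdown"]
        per_sample = [func(r, standards).value for r in phase_recs]
        codes = set().union(*(r.values.keys() for r in phase_recs))
        mean_vector = {
            c: float(np.mean([r.values[c] for r in phase_recs])) for c in codes
        }
        assert func(mean_vector, standards).value == pytest.approx(
            float(np.mean(per_sample)), rel=1e-12
        )


class TestClassification:
    @pytest.mark.parametrize(
        "value,label",
        [
            (50.0, "excellent"),
            (50.01, "good"),
            (100.0, "good"),
            (101.33, "poor"),
            (200.0, "poor"),
            (300.0, "very poor"),
            (310.37, "unfit for drinking"),
        ],
    )
    def test_mwqi_classes(self, value, label):
        assert wq.classify_mwqi(value) == label

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "excellent"),
            (25.0, "excellent"),
            (50.0, "good"),
            (75.0, "poor"),
            (86.06, "very poor"),
            (100.0, "very poor"),
            (140.01, "unfit for drinking"),
        ],
    )
    def test_hmi_classes(self, value, label):
        assert wq.classify_hmi(value) == label

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "Practically uncontaminated"),
            (124.53, "Practically uncontaminated"),
            (150.0, "Moderately contaminated"),
            (194.91, "Moderately contaminated"),
            (300.0, "Heavily contaminated"),
            (537.45, "Heavily contaminated"),
            (600.0, "Extremely contaminated"),
        ],
    )
    def test_ri_classes(self, value, label):
        assert wq.classify_ri(value) == label

    @pytest.mark.parametrize(
        "value,label",
        [
            (29.99, "low oligotrophic"),
            (30.0, "high oligotrophic"),
            (44.89, "mesotrophic"),
            (51.89, "low eutrophic"),
            (61.99, "medium eutrophic"),
            (70.0, "high eutrophic"),
            (80.0, "very high eutrophic"),
        ],
    )
    def test_tsi_classes(self, value, label):
        assert wq.classify_tsi(value) == label

    @pytest.mark.parametrize("name", ["MWQI", "HPI", "RI", "TSI"])
    def test_partition_is_gap_free_and_ordered(self, name):
        """Every non-negative value gets exactly one label, and labels are
        monotone in the index value — so the bands partition [0, inf)."""
        classify = wq.indices.CLASSIFIERS[name]
        order = {label: i for i, label in enumerate(CLASS_ORDER[name])}
        grid = np.concatenate(
            [
                np.linspace(0, 700, 2001),
                np.array([25, 50, 75, 100, 150, 200, 300, 600]) + 1e-9,
                np.array([25, 50, 75, 100, 150, 200, 300, 600]) - 1e-9,
            ]
        )
        ranks = [order[classify(float(v))] for v in np.sort(grid)]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_nonfinite_values_are_rejected(self):
        for classify in wq.indices.CLASSIFIERS.values():
            with pytest.raises(ClassificationError):
                classify(float("nan"))

    def test_negative_values_rejected_for_nonnegative_schemes(self):
        with pytest.raises(ClassificationError):
            wq.classify_hmi(-1.0)
        with pytest.raises(ClassificationError):
            wq.classify_ri(-1.0)

    def test_index_results_carry_consistent_labels(self, standards, campaign):
        for rec in campaign[:5]:
            for func, classify in [
                (wq.mwqi, wq.classify_mwqi),
                (wq.hpi, wq.classify_hmi),
                (wq.ri, wq.classify_ri),
            ]:
                result = func(rec, standards)
                assert result.class_label == classify(result.value)
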