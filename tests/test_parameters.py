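"""Parameter loading, validation, provenance, and uncertainty sampling."""

import math

import numpy as np
import pytest

from crcscreen.parameters import (
    ConfigError,
    DistributionSpec,
    ValidationError,
    load_parameter_set,
    make_sampler,
    mortality_for_age,
    serialize_parameter_set,
)

# printed cost rows: (key, value, low, high)
TABLE_COSTS = [
    ("lr_adenoma_treat", 593.32, 444.99, 741.65),
    ("hr_adenoma_treat", 593.32, 444.99, 741.65),
    ("crc_I_treat", 11000.47, 8250.35, 13750.59),
    ("crc_II_treat", 12237.85, 9178.38, 15297.31),
    ("crc_III_treat", 13041.75, 9781.31, 16302.19),
    ("crc_IV_treat", 14225.68, 10669.26, 17782.09),
    ("crc_followup_annual", 1907.80, 1430.85, 2384.74),
    ("project_total", 141085.27, 105813.95, 176356.59),
    ("fit_unit", 2.64, 1.98, 3.29),
    ("colonoscopy_unit", 140.72, 105.54, 175.90),
    ("excision_unit", 283.36, 212.52, 354.19),
    ("pathology_unit", 28.53, 21.40, 35.66),
    ("surveillance_followup_unit", 140.72, 105.54, 175.90),
]


class TestBaseCaseFile:
    def test_headline_configuration(self, base_params):
        assert base_params.discount_rate.value == 0.05
        assert base_params.cohort_size == 100_000
        assert base_params.start_age == 50 and base_params.end_age == 75
        assert base_params.followup_horizon_years == 5

    def test_every_parameter_carries_provenance(self, base_params):
        from crcscreen.parameters import PROVENANCE_TAGS

        for path, p in base_params.iter_uncertain():
            assert p.source in PROVENANCE_TAGS, path

    @pytest.mark.parametrize("key,value,low,high", TABLE_COSTS)
    def test_cost_rows_and_quarter_bounds(self, base_params, key, value, low, high):
        p = base_params.costs.entries[key]
        assert p.value == value and p.spec.low == low and p.spec.high == high
        assert p.spec.family == "gamma"
        assert abs(p.spec.low / p.value - 0.75) < 1e-3
        # the high bound of the cheapest item is printed with coarser rounding
        assert abs(p.spec.high / p.value - 1.25) < 5e-3

    def test_missing_required_key_names_it(self, base_params):
        text = serialize_parameter_set(base_params)
        broken = text.replace("death:", "death_renamed:")
        with pytest.raises(ConfigError, match="utilities.death"):
            load_parameter_set(broken)

    def test_round_trip_is_semantically_identical(self, base_params):
        again = load_parameter_set(serialize_parameter_set(base_params))
        a = dict(base_params.iter_uncertain())
        b = dict(again.iter_uncertain())
        assert a.keys() == b.keys()
        for path in a:
            assert a[path].value == b[path].value, path
            assert a[path].spec == b[path].spec, path
            assert a[path].source == b[path].source, path
        assert again.mortality.bands == base_params.mortality.bands
        for sid in base_params.strategies:
            assert again.strategies[sid].modality == base_params.strategies[sid].modality
            assert again.strategies[sid].interval_years == base_params.strategies[sid].interval_years

    def test_colonoscopy_specificity_is_perfect(self, base_params):
        assert base_params.tech["colonoscopy"].specificity.value == 1.0
        assert base_params.tech["colonoscopy"].miss_rate.value == pytest.approx(0.1939)

    def test_bad_yaml_and_bad_schema(self):
        with pytest.raises(ConfigError):
            load_parameter_set(": not : valid : yaml [")
        with pytest.raises(ConfigError, match="schema"):
            load_parameter_set("schema: 99")


class TestValidation:
    def test_prevalence_must_sum_below_one(self, params):
        params.set_value("prevalence.lr_adenoma", 0.7)
        params.set_value("prevalence.hr_adenoma", 0.4)
        with pytest.raises(ValidationError, match="prevalence"):
            params.validate()

    def test_combined_exit_probability_guard(self, params):
        params.set_value("transitions.natural_history.ud_III_to_ud_IV", 0.9)
        params.set_value("transitions.crc_mortality.crc_III", 0.3)
        with pytest.raises(ValidationError, match="ud_III"):
            params.validate()

    def test_path_addressing(self, params):
        p = params.get_parameter("tech.FIT.sensitivity.hr_adenoma")
        assert 0 < p.value < 1
        params.set_value("tech.FIT.sensitivity.hr_adenoma", 0.5)
        assert params.get_parameter("tech.FIT.sensitivity.hr_adenoma").value == 0.5
        with pytest.raises(KeyError):
            params.get_parameter("tech.FIT.sensitivity.nonexistent")
        with pytest.raises(KeyError):
            params.get_parameter("no.such.path")


class TestMortalityTable:
    @pytest.mark.parametrize(
        "age,expected",
        [(52, 0.0042), (40, 0.0018), (44, 0.0018), (74, 0.0306), (75, 0.0306), (90, 0.0306)],
    )
    def test_band_lookup_and_carry_forward(self, base_params, age, expected):
        assert mortality_for_age(base_params.mortality, age) == expected

    def test_age_below_coverage_is_an_error(self, base_params):
        with pytest.raises(ValueError, match="below"):
            mortality_for_age(base_params.mortality, 39)


class TestSamplers:
    def test_point_spec_is_constant(self):
        s = make_sampler(DistributionSpec("point", 0.25, 0.25, 0.25), seed=0)
        assert s() == 0.25
        assert np.all(s(100) == 0.25)

    def test_gamma_moment_recovery(self):
        spec = DistributionSpec("gamma", 593.32, 444.99, 741.65)
        draws = make_sampler(spec, seed=42)(100_000)
        se = spec.sd / math.sqrt(draws.size)
        assert abs(draws.mean() - 593.32) < 3 * se
        assert abs(draws.mean() - 593.32) / 593.32 < 0.01
        assert np.all(draws > 0)

    def test_beta_moment_recovery_and_support(self):
        spec = DistributionSpec("beta", 0.25, 0.1875, 0.3125)
        draws = make_sampler(spec, seed=7)(100_000)
        assert np.all((draws > 0) & (draws < 1))
        se = spec.sd / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.25) < 3 * se
        assert abs(draws.mean() - 0.25) / 0.25 < 0.01

    def test_beta_mean_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            make_sampler(DistributionSpec("beta", 1.0, 0.75, 1.0), seed=0)

    def test_same_seed_reproduces_stream(self):
        spec = DistributionSpec("gamma", 100.0, 75.0, 125.0)
        a = make_sampler(spec, seed=3)(50)
        b = make_sampler(spec, seed=3)(50)
        assert np.array_equal(a, b)

    def test_moment_recovery_across_base_case_specs(self, base_params):
        """Every sampled spec in the packaged file recovers its mean at 1e5 draws."""
        checked = 0
        for path, p in base_params.iter_uncertain():
            if p.spec.family == "point" or p.spec.sd == 0:
                continue
            draws = make_sampler(p.spec, seed=churn(path))(100_000)
            se = p.spec.sd / math.sqrt(draws.size)
            assert abs(draws.mean() - p.spec.mean) < 3 * se, path
            checked += 1
        assert checked > 30


def churn(text: str) -> int:
    """Stable small seed from a parameter path."""
    return sum(ord(ch) * (i + 1) for i, ch in enumerate(text)) % (2**31)
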