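"""Deterministic dose/risk arithmetic: published-value examples, independent
scalar-arithmetic oracles, domain errors, and structural invariants."""

import dataclasses
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import beachrisk as br
from conftest import assert_printed

BEACHES_EF = 3 * 8 / 28489


@pytest.mark.parametrize(
    ("frequency", "duration", "averaging_time", "expected"),
    [
        (3, 8, 28489, 0.000842),  # cancer averaging time (~78-y lifetime)
        (3, 8, 365, 0.0658),      # one-year (non-cancer) averaging time
        (12, 8, 28489, 0.00337),
    ],
)
def test_exposure_factor_published_values(frequency, duration, averaging_time,
                                          expected):
    assert_printed(br.exposure_factor(frequency, duration, averaging_time),
                   expected)


def test_exposure_factor_zero_frequency_is_zero_exposure():
    assert br.exposure_factor(0, 8, 28489) == 0.0


@pytest.mark.parametrize(
    ("args", "message"),
    [
        ((-1, 8, 28489), "frequency"),
        ((3, -8, 28489), "duration"),
        ((3, 8, 0), "averaging_time"),
        ((3, 8, -365), "averaging_time"),
    ],
)
def test_exposure_factor_domain_errors(args, message):
    with pytest.raises(ValueError, match=message):
        br.exposure_factor(*args)


class TestDoseExamples:
    """Each route's dose x slope chain against the published point risks and
    an independent inline-arithmetic oracle."""

    def test_oral_weathered_oil(self, beaches):
        dose = br.dose_oral(4.40, beaches.profile, beaches.tox)
        assert dose == pytest.approx(4.40 * 1000 * 0.5 * BEACHES_EF * 1e-6 / 34.8)
        assert_printed(dose * 0.73, 3.89e-8)

    def test_oral_sediment_independent_chain(self, beaches):
        risk = br.dose_oral(1.46, beaches.profile, beaches.tox) * 0.73
        oracle = 1.46 * 1000 * 0.5 * BEACHES_EF * 1e-6 / 34.8 * 0.73
        assert risk == pytest.approx(oracle, rel=1e-12)
        assert_printed(risk, 1.29e-8)

    def test_oral_zero_concentration(self, beaches):
        assert br.dose_oral(0.0, beaches.profile, beaches.tox) == 0.0

    def test_dermal_weathered_oil(self, beaches):
        dose = br.dose_dermal(4.40, beaches.profile, beaches.tox)
        assert_printed(dose * 1.46, 3.52e-7)

    def test_dermal_tar_independent_chain(self, beaches):
        risk = br.dose_dermal(0.62, beaches.profile, beaches.tox) * 1.46
        oracle = 0.62 * 12582 * 18 * 0.01 * BEACHES_EF * 1e-6 / 34.8 * 1.46
        assert risk == pytest.approx(oracle, rel=1e-12)
        assert_printed(risk, 4.96e-8)

    def test_dermal_zero_absorption(self, beaches):
        tox = dataclasses.replace(beaches.tox, abs_dermal=0.0)
        assert br.dose_dermal(4.40, beaches.profile, tox) == 0.0

    def test_inhalation_weathered_oil(self, beaches):
        dose = br.dose_inhalation(4.40, beaches.profile, beaches.tox)
        oracle = 4.40 / 1.24e9 * 9.62 * 3 * BEACHES_EF / 34.8
        assert dose == pytest.approx(oracle, rel=1e-12)
        assert_printed(dose * 0.31, 7.69e-13)

    def test_inhalation_sediment_independent_chain(self, beaches):
        risk = br.dose_inhalation(1.46, beaches.profile, beaches.tox) * 0.31
        assert_printed(risk, 2.55e-13)

    def test_inhalation_zero_exposure_time(self, beaches):
        profile = dataclasses.replace(beaches.profile, exposure_time=0.0)
        assert br.dose_inhalation(4.40, profile, beaches.tox) == 0.0

    def test_negative_concentration_rejected(self, beaches):
        for fn in (br.dose_oral, br.dose_dermal, br.dose_inhalation):
            with pytest.raises(ValueError, match="concentration"):
                fn(-1.0, beaches.profile, beaches.tox)


def test_profile_rejects_nonpositive_core_parameters(beaches):
    for field in ("body_weight", "averaging_time", "particulate_emission_factor"):
        with pytest.raises(ValueError, match=field):
            dataclasses.replace(beaches.profile, **{field: 0.0})


def test_route_risk_is_plain_product():
    assert br.route_risk(5.323e-8, 0.73) == pytest.approx(3.886e-8, rel=1e-3)
    assert br.route_risk(0.0, 123.0) == 0.0


def test_route_risk_uncapped_but_warns_above_credibility_threshold():
    with pytest.warns(UserWarning, match="not credible"):
        assert br.route_risk(1.0, 1.46) == 1.46


def test_route_risk_rejects_negative_inputs():
    with pytest.raises(ValueError):
        br.route_risk(-1e-9, 0.73)
    with pytest.raises(ValueError):
        br.route_risk(1e-9, -0.73)


class TestRiskTable:
    def test_beaches_totals(self, beaches_table):
        assert_printed(beaches_table.route_totals["oral"], 5.73e-8)
        assert_printed(beaches_table.route_totals["dermal"], 5.19e-7)
        assert_printed(beaches_table.route_totals["inhalation"], 1.13e-12)
        assert_printed(beaches_table.grand_total, 5.76e-7)

    def test_additivity_against_bruteforce_scalar_oracle(self, beaches, beaches_table):
        """Margins equal sums of nine independently recomputed cells."""
        p, tox = beaches.profile, beaches.tox
        ef = BEACHES_EF
        conc = {m.medium: m.concentration for m in beaches.media}
        cells = {}
        for medium, c in conc.items():
            cells[(medium, "oral")] = c * 1000 * 0.5 * ef * 1e-6 / 34.8 * 0.73
            cells[(medium, "dermal")] = c * 12582 * 18 * 0.01 * ef * 1e-6 / 34.8 * 1.46
            cells[(medium, "inhalation")] = c / 1.24e9 * 9.62 * 3 * ef / 34.8 * 0.31
        assert p.body_weight == 34.8 and tox.slope_oral == 0.73
        for key, expected in cells.items():
            assert beaches_table.cells[key] == pytest.approx(expected, rel=1e-9)
        for route in br.ROUTES:
            total = sum(cells[(m, route)] for m in conc)
            assert beaches_table.route_totals[route] == pytest.approx(total, rel=1e-9)
        assert beaches_table.grand_total == pytest.approx(
            sum(cells.values()), rel=1e-9)

    def test_zero_concentrations_give_zero_table(self, beaches):
        media = [br.MediumConcentration(m, 0.0) for m in br.MEDIA]
        table = br.risk_table(media, beaches.profile, beaches.tox)
        assert all(v == 0.0 for v in table.cells.values())
        assert table.grand_total == 0.0

    def test_duplicate_medium_rejected(self, beaches):
        media = [br.MediumConcentration("tar", 0.5),
                 br.MediumConcentration("tar", 0.7)]
        with pytest.raises(ValueError, match="duplicate"):
            br.risk_table(media, beaches.profile, beaches.tox)

    def test_empty_media_rejected(self, beaches):
        with pytest.raises(ValueError, match="non-empty"):
            br.risk_table([], beaches.profile, beaches.tox)

    def test_unknown_medium_rejected(self):
        with pytest.raises(ValueError, match="medium"):
            br.MediumConcentration("dune", 1.0)

    def test_to_frame_layout(self, beaches_table):
        frame = beaches_table.to_frame()
        assert list(frame.columns) == ["oral", "dermal", "inhalation", "total"]
        assert frame.loc["total", "total"] == pytest.approx(
            beaches_table.grand_total)


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_risk_is_linear_in_concentration(scale, beaches):
    """Doubling (or any scaling of) C scales every cell by the same factor."""
    base = br.risk_table(list(beaches.media), beaches.profile, beaches.tox)
    scaled_media = [br.MediumConcentration(m.medium, m.concentration * scale)
                    for m in beaches.media]
    scaled = br.risk_table(scaled_media, beaches.profile, beaches.tox)
    for key, value in base.cells.items():
        assert scaled.cells[key] == pytest.approx(value * scale, rel=1e-12)


@given(bw_lo=st.floats(min_value=5, max_value=100),
       bump=st.floats(min_value=0.1, max_value=100))
def test_risk_strictly_decreasing_in_body_weight(bw_lo, bump, beaches):
    light = dataclasses.replace(beaches.profile, body_weight=bw_lo)
    heavy = dataclasses.replace(beaches.profile, body_weight=bw_lo + bump)
    for fn in (br.dose_oral, br.dose_dermal, br.dose_inhalation):
        assert fn(4.40, light, beaches.tox) > fn(4.40, heavy, beaches.tox)


@given(f=st.floats(min_value=0.01, max_value=366),
       ed=st.floats(min_value=0.01, max_value=78),
       at=st.floats(min_value=365, max_value=40000))
def test_exposure_factor_recovers_frequency(f, ed, at):
    """EF * AT / ED = F to within floating-point round-off."""
    ef = br.exposure_factor(f, ed, at)
    assert ef * at / ed == pytest.approx(f, rel=1e-12)


def test_exposure_factor_override_wins(literature):
    assert br.resolved_exposure_factor(literature.profile) == 0.002948
    plain = dataclasses.replace(literature.profile, exposure_factor_override=None)
    assert br.resolved_exposure_factor(plain) == pytest.approx(12 * 8 / 28489)
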