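import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmburden import (
    AGE_GROUP_LABELS,
    DisabilityWeight,
    DisabilityWeightSet,
    IncidenceTable,
    LifeTable,
    RunConfig,
    TransitionTable,
    compute_burden,
    compute_yld,
    compute_yll,
    sensitivity_duration,
    simulate_cohort,
)
from dmburden.engine import CohortTrace


def flat_life_table(rle=10.0):
    rows = [
        {"sex": s, "age": a, "rle_years": rle}
        for s in ("male", "female")
        for a in range(0, 131)
    ]
    return LifeTable(pd.DataFrame(rows))


def hand_trace(new_dthdm=None, horizon=100, start_age=56):
    """A minimal trace: unit mass parked in Dep, optional death pulses."""
    occ = np.zeros((horizon + 1, 14))
    occ[:, 5] = 1.0
    nd = np.zeros(horizon + 1)
    if new_dthdm:
        for j, m in new_dthdm.items():
            nd[j] = m
    return CohortTrace(
        sex="male", start_group="55-59", occupancy=occ, new_ci=np.zeros(horizon + 1),
        new_dthdm=nd, new_dthoth=np.zeros(horizon + 1),
        ages=start_age + np.arange(horizon + 1),
    )


class TestYld:
    def test_uncomplicated_annuity_closed_form(self, table, dw):
        """With no deaths and no complications, 100 cycles at 5% discount
        give 0.334 x 20.8404 = 6.9607 YLD per member (start-boundary
        discounting, the annuity-due)."""
        cfg = RunConfig(discount_timing="start", max_age=None)
        tr = simulate_cohort("male", "30-34", TransitionTable(table.df * 0.0), cfg)
        unc, comp = compute_yld(tr, dw, cfg)
        annuity = (1 - 1.05 ** -100) / (1 - 1 / 1.05) / 1.05 ** 0  # due, 100 terms
        assert unc == pytest.approx(0.334 * annuity, abs=1e-9)
        assert round(unc, 4) == 6.9607
        assert comp == 0.0

    def test_linear_in_disability_weight(self, table, config):
        tr = simulate_cohort("male", "50-54", table, config)
        small = DisabilityWeightSet(DisabilityWeight(0.1), DisabilityWeight(0.2))
        big = DisabilityWeightSet(DisabilityWeight(0.2), DisabilityWeight(0.4))
        assert compute_yld(tr, big, config) == pytest.approx(
            tuple(2 * x for x in compute_yld(tr, small, config))
        )

    def test_undiscounted_yld_equals_weighted_person_years(self, table):
        """At zero discount with no complication flow, YLD per member is the
        disability weight times the person-years alive in the trace."""
        cfg = RunConfig(discount_rate=0.0, max_age=None)
        df = table.df.copy()
        df.loc[:, ["di_ci", "dep_ci"]] = 0.0
        tr = simulate_cohort("male", "60-64", TransitionTable(df), cfg)
        unc, comp = compute_yld(tr, DisabilityWeightSet(), cfg)
        person_years = tr.alive_mass[1:].sum()
        assert comp == 0.0
        assert unc == pytest.approx(0.334 * person_years, abs=1e-9)


class TestYll:
    def test_only_diabetes_deaths_count(self, config):
        tr = hand_trace()
        tr.new_dthoth[:] = 0.01
        assert compute_yll(tr, flat_life_table(), config) == 0.0

    def test_simple_death_at_entry(self):
        cfg = RunConfig(yll_method="simple")
        assert compute_yll(hand_trace({0: 1.0}), flat_life_table(10.0), cfg) == pytest.approx(10.0)

    def test_annuitized_residual_life(self):
        """One death at entry against a residual expectancy of 10 years at a
        5% rate is worth (1 - 1.05^-10)/0.05 = 7.72173 discounted years."""
        cfg = RunConfig(yll_method="annuitized")
        v = compute_yll(hand_trace({0: 1.0}), flat_life_table(10.0), cfg)
        assert v == pytest.approx((1 - 1.05 ** -10) / 0.05, abs=1e-12)
        assert round(v, 5) == 7.72173

    def test_later_deaths_are_discounted(self):
        cfg = RunConfig(yll_method="simple")
        v = compute_yll(hand_trace({4: 1.0}), flat_life_table(10.0), cfg)
        assert v == pytest.approx(10.0 * 1.05 ** -4)


class TestBurden:
    def test_daly_is_yll_plus_yld_everywhere(self, burden_result):
        df = burden_result.by_group
        assert np.allclose(df["daly"], df["yll"] + df["yld_total"], atol=1e-9)
        assert np.allclose(
            df["daly_per_100k"],
            df["yll_per_100k"] + df["yld_total_per_100k"],
            atol=1e-9,
        )

    def test_halving_incidence_rate_halves_per_100k(self, table, incidence, dw, life_table, config):
        res = compute_burden(table, incidence, dw, life_table, config)
        doubled = IncidenceTable(incidence.df.assign(ir=incidence.df["ir"] / 2))
        res2 = compute_burden(table, doubled, dw, life_table, config)
        # populations are rounded to whole persons, hence the loose rtol
        assert np.allclose(
            res2.by_group["daly_per_100k"], res.by_group["daly_per_100k"] / 2, rtol=1e-4
        )

    def test_collapsed_interval_gives_equal_bounds(self, burden_result, table, incidence, dw, life_table, config):
        res = compute_burden(table, incidence, dw, life_table, config)  # point-only weights
        df = res.by_group
        assert np.allclose(df["daly_lower_per_100k"], df["daly_per_100k"])
        assert np.allclose(df["daly_upper_per_100k"], df["daly_per_100k"])

    @given(
        lo=st.floats(0.05, 0.33), hi=st.floats(0.34, 0.55),
        clo=st.floats(0.56, 0.66), chi=st.floats(0.67, 0.95),
    )
    def test_bounds_bracket_point_for_random_intervals(self, table, config, lo, hi, clo, chi):
        dws = DisabilityWeightSet(
            DisabilityWeight(0.334, lo, hi), DisabilityWeight(0.663, clo, chi)
        )
        tr = simulate_cohort("female", "60-64", table, config)
        point = sum(compute_yld(tr, dws, config, "point"))
        lower = sum(compute_yld(tr, dws, config, "lower"))
        upper = sum(compute_yld(tr, dws, config, "upper"))
        assert lower <= point <= upper

    def test_burden_peaks_match_published_ordering(self, burden_result):
        """Per-100,000 YLD peaks at 55-59 (men) / 65-69 (women); complicated
        YLD at 60-64 (men) / 65-69 (women); YLL at 60-64 in both sexes."""
        expected = {
            ("male", "yld_total_per_100k"): "55-59",
            ("female", "yld_total_per_100k"): "65-69",
            ("male", "yld_comp_per_100k"): "60-64",
            ("female", "yld_comp_per_100k"): "65-69",
            ("male", "yll_per_100k"): "60-64",
            ("female", "yll_per_100k"): "60-64",
        }
        for (sex, col), peak in expected.items():
            sub = burden_result.by_group[burden_result.by_group["sex"] == sex]
            assert sub.loc[sub[col].idxmax(), "age_group"] == peak, (sex, col)


class TestDurationSensitivity:
    def test_fixed_tables_are_invariant_to_the_assumption(self, table, incidence, dw, life_table, config):
        out = sensitivity_duration(table, incidence, dw, life_table, config)
        assert np.allclose(out["min_daly"], out["max_daly"])
        assert np.allclose(out["min_daly"], out["median_daly"])
        diff = (out["max_daly"] - out["min_daly"]).abs().max()
        assert diff <= 10.0

    def test_no_complication_flow_gives_identical_runs(self, table, incidence, dw, life_table, config):
        df = table.df.copy()
        df.loc[:, ["di_ci", "dep_ci"]] = 0.0
        out = sensitivity_duration(TransitionTable(df), incidence, dw, life_table, config)
        assert np.allclose(out["min_daly"], out["max_daly"])

    def test_records_level_sensitivity_moves_only_old_groups(self, life_table, dw):
        """Re-deriving the table under the three timing assumptions moves
        DALYs only where reverse-diagnosed over-60 complication cases exist,
        by small amounts in either direction."""
        from dmburden.burden import sensitivity_duration_from_records
        from dmburden.synthetic import default_profile
        from dmburden import generate_population

        prof = default_profile(n_per_cell=1200, frac_reverse=0.10)
        frame = generate_population(prof, seed=21, as_frame=True)
        cfg = RunConfig()
        out = sensitivity_duration_from_records(
            frame, prof.default_index_year, dw, life_table, cfg
        )
        diffs = (out["max_daly"] - out["min_daly"]).abs()
        young = diffs[out["age_group"].isin(AGE_GROUP_LABELS[:4])]
        old = diffs[~out["age_group"].isin(AGE_GROUP_LABELS[:4])]
        assert old.max() > 0.0
        # reverse cases live at 60+; younger groups move only through
        # smoothing pools that straddle the age-60 boundary
        assert young.max() < old.max()
        assert diffs.max() < 200.0
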