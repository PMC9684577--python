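import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from iopcorr.cohort import Cohort, EyeRecord
from iopcorr.corrections import (
    FORMULA_IDS,
    REGISTRY,
    correct,
    correct_cohort,
    get_formula,
)
from iopcorr.errors import (
    DependencyError,
    InsufficientDataError,
    NonPhysiologicalIOPWarning,
    NumericError,
)


def rec(gat=15.0, cct=545.0, r=7.8, age=40.0, dct=17.0):
    return EyeRecord("S1", age=age, cct_um=cct, iop_gat=gat, iop_dct=dct, r_mm=r)


class TestRegistry:
    def test_all_ids_present(self):
        assert set(REGISTRY) == set(FORMULA_IDS)

    def test_unknown_id(self):
        with pytest.raises(KeyError, match="unknown formula"):
            get_formula("nope")

    def test_unknown_param_rejected(self):
        with pytest.raises(NumericError, match="unknown parameter"):
            get_formula("foster", {"slop": 1.0})


class TestExamples:
    """Hand-derived spot values for each formula."""

    def test_doughty_reference_thickness(self):
        assert correct("doughty", rec(gat=15.0, cct=545.0)) == pytest.approx(15.0)

    def test_kohlhaas(self):
        # delta = -0.0423*525 + 23.28 = 1.0725
        assert correct("kohlhaas", rec(gat=15.0, cct=525.0)) == pytest.approx(16.0725)

    def test_foster(self):
        assert correct("foster", rec(gat=15.50)) == pytest.approx(22.24)

    def test_ehlers(self):
        # 15 + 0.071*(520-510)
        assert correct("ehlers", rec(gat=15.0, cct=510.0)) == pytest.approx(15.71)

    def test_srodka_reference_geometry(self):
        # multiplier = 1 at CCT 550 um / R 7.8 mm, so result is the
        # quadratic calibration -1.61 + 0.94*g + 0.011*g^2 at g=15.5
        assert correct("srodka", rec(gat=15.5, cct=550.0, r=7.8)) == pytest.approx(
            15.60275, abs=1e-9
        )

    def test_chihara_collapses_to_offset(self):
        assert correct("chihara", rec(gat=15.5, cct=550.0, r=7.8)) == pytest.approx(
            19.65, abs=1e-3
        )

    def test_elsheikh_identity_defaults(self):
        assert correct("elsheikh2009", rec(gat=17.0)) == pytest.approx(17.0)
        assert correct("elsheikh2011", rec(gat=17.0)) == pytest.approx(17.0)

    def test_shimmyo_linear(self):
        # delta = (550-532)/18 = 1.0
        assert correct("shimmyo", rec(gat=15.0, cct=532.0)) == pytest.approx(16.0)

    def test_shimmyo_r(self):
        expected = 16.0 + 0.8 * (7.6 - 7.848837)
        assert correct("shimmyo_r", rec(gat=15.0, cct=532.0, r=7.6)) == pytest.approx(
            expected
        )

    def test_shimmyo_variants(self):
        g, cct = 15.0, 532.0
        base = (550 - cct) / 18.0
        power = correct("shimmyo", rec(gat=g, cct=cct), overrides={"variant": "power"})
        assert power == pytest.approx(g + base * 18 ** (0.005 * g))
        literal = correct(
            "shimmyo", rec(gat=g, cct=cct), overrides={"variant": "literal"}
        )
        assert literal == pytest.approx(g + (550 - cct) * 18 ** (0.005 * g))


class TestFixedPoints:
    """Identity at each formula's reference geometry."""

    @pytest.mark.parametrize(
        "formula,kwargs",
        [
            ("doughty", dict(cct=545.0)),
            ("ehlers", dict(cct=520.0)),
            ("shimmyo", dict(cct=550.0)),
            ("shimmyo_r", dict(cct=550.0, r=7.848837)),
        ],
    )
    def test_affine_fixed_points(self, formula, kwargs):
        for g in (10.0, 15.0, 22.0):
            assert correct(formula, rec(gat=g, **kwargs)) == pytest.approx(g, abs=1e-9)

    def test_srodka_fixed_point(self):
        # at reference geometry the multiplier is 1, so the fixed point g*
        # solves -1.61 + 0.94 g + 0.011 g^2 = g
        def f(g):
            return correct("srodka", rec(gat=g, cct=550.0, r=7.8)) - g

        g_star = optimize.brentq(f, 5.0, 30.0)
        assert f(g_star) == pytest.approx(0.0, abs=1e-9)
        # closed-form root of 0.011 g^2 - 0.06 g - 1.61 = 0
        expected = (0.06 + math.sqrt(0.06 ** 2 + 4 * 0.011 * 1.61)) / (2 * 0.011)
        assert g_star == pytest.approx(expected, abs=1e-6)


class TestMonotonicity:
    @pytest.mark.parametrize("formula", ["kohlhaas", "doughty", "ehlers", "shimmyo"])
    def test_decreasing_in_cct(self, formula):
        ccts = np.linspace(400.0, 700.0, 31)
        vals = [correct(formula, rec(gat=15.0, cct=c)) for c in ccts]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @given(st.floats(min_value=5.0, max_value=40.0),
           st.floats(min_value=0.1, max_value=5.0))
    def test_foster_slope(self, g, dg):
        lo = correct("foster", rec(gat=g))
        hi = correct("foster", rec(gat=g + dg))
        assert hi - lo == pytest.approx(1.08 * dg, rel=1e-9)


class TestChiharaProperty:
    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(min_value=5.0, max_value=40.0),
        st.floats(min_value=350.0, max_value=750.0),
        st.floats(min_value=5.0, max_value=11.0),
    )
    def test_offset_bound_over_validity_box(self, g, cct, r):
        # under the mm-unit reading the structural denominator term is ~2e-7
        assert abs(correct("chihara", rec(gat=g, cct=cct, r=r)) - (g + 4.15)) < 1e-3

    def test_um_variant_differs(self):
        mm = correct("chihara", rec(gat=15.5, cct=550.0, r=7.8))
        um = correct("chihara", rec(gat=15.5, cct=550.0, r=7.8),
                     overrides={"units": "um"})
        # micrometre reading has a ~1000x larger structural fraction
        assert um < mm
        assert (mm - um) > 1e-4


class TestErrors:
    def test_missing_radius(self):
        r = EyeRecord("S1", 40.0, 545.0, 15.0, 17.0)  # no curvature
        for formula in ("srodka", "chihara", "shimmyo_r"):
            with pytest.raises(DependencyError, match=formula):
                correct(formula, r)

    def test_nonpositive_elsheikh_factor(self):
        with pytest.raises(NumericError, match="positive"):
            correct("elsheikh2009", rec(), overrides={"a_iop": (-1.0,)})

    def test_nonphysiological_warning(self):
        # huge positive CCT correction downward: ehlers at very thick cornea
        with pytest.warns(NonPhysiologicalIOPWarning):
            correct("ehlers", rec(gat=1.0, cct=750.0))

    def test_record_not_mutated(self, record):
        before = (record.iop_gat, record.cct_um)
        correct("kohlhaas", record)
        assert (record.iop_gat, record.cct_um) == before


class TestCorrectCohort:
    def test_matches_per_record(self, small_cohort):
        for formula in FORMULA_IDS:
            series = correct_cohort(formula, small_cohort)
            assert len(series) == len(small_cohort)
            for i, r in enumerate(small_cohort):
                assert series[i] == pytest.approx(correct(formula, r), rel=1e-12)

    def test_doughty_identity_cohort(self):
        recs = [EyeRecord(f"S{i}", 40.0, 545.0, 14.0 + i, 17.0) for i in range(4)]
        cohort = Cohort(records=recs)
        np.testing.assert_allclose(
            correct_cohort("doughty", cohort), cohort.iop_gat
        )

    def test_foster_elementwise(self, small_cohort):
        np.testing.assert_allclose(
            correct_cohort("foster", small_cohort),
            1.08 * small_cohort.iop_gat + 5.5,
        )

    def test_empty_cohort(self):
        with pytest.raises(InsufficientDataError):
            correct_cohort("foster", Cohort(records=[]))

    def test_mean_linearity_affine_formulas(self, default_cohort_1k):
        # formulas affine in CCT at fixed GAT: mean correction equals the
        # correction of the mean
        cohort = default_cohort_1k
        gbar, cbar = cohort.iop_gat.mean(), cohort.cct_um.mean()
        for formula, delta_at in [
            ("kohlhaas", lambda c: -0.0423 * c + 23.28),
            ("doughty", lambda c: 25.0 * (545.0 - c) / 545.0),
            ("ehlers", lambda c: 0.071 * (520.0 - c)),
            ("shimmyo", lambda c: (550.0 - c) / 18.0),
        ]:
            series = correct_cohort(formula, cohort)
            assert (series - cohort.iop_gat).mean() == pytest.approx(
                delta_at(cbar), abs=1e-9
            )
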