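"""perturbation_sim: knockdown sweeps, yield ratios, RVmax, overexpression."""

from __future__ import annotations

import numpy as np
import pytest

from debranch.constraints import ConstraintSet, ExpressionRecord, KineticsRecord
from debranch.errors import ParameterError
from debranch.perturb import (
    rvmax_ratio,
    simulate_knockdown,
    sweep_overexpression,
    yield_improvement,
)
from debranch.synth import TOY_CS5_ALIASES

from .conftest import build_model


@pytest.fixture(scope="module")
def kd_curve(toy_model, cs5):
    return simulate_knockdown(
        toy_model, cs5, targets=["DMATT", "GRTT"],
        product_rxn="EX_CS_OH", biomass_rxn="BIOMASS_toy",
    )


class TestKnockdown:
    def test_factor_one_row_is_baseline_with_unit_fold_change(self, kd_curve):
        row = kd_curve.frame[kd_curve.frame.factor == 1.0].iloc[0]
        assert row.fold_change == 1.0
        assert row.flux_product == pytest.approx(kd_curve.baseline["EX_CS_OH"])
        assert row.status == "baseline"

    def test_factors_are_increasing_powers_of_two(self, kd_curve):
        factors = kd_curve.frame.factor.to_numpy()
        assert (np.diff(factors) > 0).all()
        assert factors[0] == 1.0 and factors[-1] == 256.0
        assert np.allclose(np.log2(factors), np.round(np.log2(factors)))

    def test_product_flux_non_decreasing_under_debranching(self, kd_curve):
        flux = kd_curve.frame[kd_curve.frame.status != "infeasible"].flux_product
        assert (np.diff(flux.to_numpy()) >= -1e-8).all()

    def test_biomass_declines_with_inhibition(self, kd_curve):
        bio = kd_curve.frame.flux_biomass.to_numpy()
        assert (np.diff(bio) <= 1e-8).all()
        assert bio[0] == pytest.approx(1.706, rel=1e-6)

    def test_group_cap_respected_in_every_row(self, toy_model, cs5, kd_curve):
        """Capped consumption never exceeds Δ x supply-route flux."""
        cap = cs5.group_caps[0]
        # re-solve a mid-sweep row and check the inequality on raw fluxes
        from debranch.lp import ObjectiveSpec, optimize_multi

        cset = cs5.copy()
        value = cset.fixed.pop("BIOMASS_toy")
        cset.bounds["BIOMASS_toy"] = (0.0, value)
        base = kd_curve.baseline
        for t in ("DMATT", "GRTT"):
            cset.bounds[t] = (-abs(base[t]) / 16, abs(base[t]) / 16)
        state = optimize_multi(
            toy_model, cset, ObjectiveSpec.lexicographic("BIOMASS_toy", "EX_CS_OH")
        )
        consumed = sum(max(state[r], 0.0) for r in cap.consumers)
        produced = sum(max(state[r], 0.0) for r in cap.producers)
        assert consumed <= cap.delta * produced + 1e-6

    def test_full_knockout_kills_biomass(self, toy_model, cs5):
        """Zero bounds on the ispA pair: growth impossible, product remains."""
        from debranch.lp import ObjectiveSpec, optimize_multi

        cset = cs5.copy()
        value = cset.fixed.pop("BIOMASS_toy")
        cset.bounds["BIOMASS_toy"] = (0.0, value)
        cset.bounds["DMATT"] = (0.0, 0.0)
        cset.bounds["GRTT"] = (0.0, 0.0)
        state = optimize_multi(
            toy_model, cset, ObjectiveSpec.lexicographic("BIOMASS_toy", "EX_CS_OH")
        )
        assert state.optimal
        assert state["BIOMASS_toy"] == pytest.approx(0.0, abs=1e-9)
        assert state["EX_CS_OH"] > 0

    def test_degenerate_zero_baseline_reported(self):
        model = build_model(
            {
                "SRC": ({"a_c": 1}, 0, 10),
                "MAIN": ({"a_c": -1, "b_c": 1}, 0, 1000),
                "SIDE": ({"a_c": -1, "d_c": 1}, 0, 1000),
                "EX_D": ({"d_c": -1}, 0, 1000),
                "EX_B": ({"b_c": -1}, 0, 1000),
            },
            objective="EX_B",
        )
        with pytest.warns(UserWarning, match="degenerate"):
            curve = simulate_knockdown(
                model, None, targets=["SIDE"], product_rxn="EX_B",
                biomass_rxn="EX_B", factors=[1, 2],
            )
        assert curve.degenerate

    def test_infeasible_factor_rows_flagged_and_sweep_continues(self, toy_model,
                                                                cs5):
        # biomass stays hard-fixed at 1.706: halving the ispA pair makes the
        # FPP demand unreachable, every k > 1 must be flagged infeasible
        from debranch.lp import ObjectiveSpec

        curve = simulate_knockdown(
            toy_model, cs5, targets=["DMATT", "GRTT"],
            product_rxn="EX_CS_OH", biomass_rxn="EX_CS_OH",  # leave fix alone
            factors=[1, 4, 256],
            objective=ObjectiveSpec.single("EX_CS_OH"),
        )
        assert list(curve.frame.status) == ["baseline", "infeasible", "infeasible"]

    def test_unknown_target_rejected(self, toy_model, cs5):
        with pytest.raises(ParameterError):
            simulate_knockdown(toy_model, cs5, ["NOPE"], "EX_CS_OH", "BIOMASS_toy")


class TestYieldImprovement:
    def test_ratio_arithmetic(self, kd_curve):
        table = yield_improvement(kd_curve)
        base = kd_curve.frame.iloc[0].flux_product
        k16 = kd_curve.frame[kd_curve.frame.factor == 16.0].iloc[0].flux_product
        row = table[table.factor == 16.0].iloc[0]
        assert row.ratio == pytest.approx(k16 / base, rel=1e-12)
        assert table.attrs["argmax_factor"] == 256.0

    def test_printed_example_arithmetic(self):
        """baseline 0.0023, knockdown 0.0060 → ratio ≈ 2.609."""
        assert 0.0060 / 0.0023 == pytest.approx(2.609, abs=5e-4)

    def test_flat_curve_gives_unit_ratios(self, toy_model, cs5):
        curve = simulate_knockdown(
            toy_model, cs5, targets=["NUDX_DMAP"],  # baseline flux 0 branch
            product_rxn="EX_CS_OH", biomass_rxn="BIOMASS_toy", factors=[1],
        )
        table = yield_improvement(curve)
        assert (table.ratio.dropna() == 1.0).all()

    def test_zero_baseline_yields_sentinel(self):
        model = build_model(
            {
                "SRC": ({"a_c": 1}, 0, 10),
                "MAIN": ({"a_c": -1, "b_c": 1}, 0, 1000),
                "EX_B": ({"b_c": -1}, 0, 1000),
                "DEAD": ({"a_c": -1, "z_c": 1}, 0, 1000),
                "EX_Z": ({"z_c": -1}, 0, 0),
            },
            objective="EX_B",
        )
        with pytest.warns(UserWarning):
            curve = simulate_knockdown(
                model, None, ["MAIN"], product_rxn="EX_Z", biomass_rxn="EX_B",
                factors=[1, 2],
            )
            table = yield_improvement(curve)
        assert table.ratio.isna().all()


class TestRvmax:
    def test_equal_kinetics_and_expression_give_unity(self):
        k = KineticsRecord("g1", "R1", 2.0, 0.5)
        e = ExpressionRecord("g1", "baseline", 40.0)
        assert rvmax_ratio(k, k, e, e) == 1.0

    def test_hand_case(self):
        """kcat=(4,2), EXP=(3,6) → (4·3)/(2·6) = 1.0."""
        k1, k2 = KineticsRecord("a", "A", 4.0, 1.0), KineticsRecord("b", "B", 2.0, 1.0)
        e1 = ExpressionRecord("a", "c", 3.0)
        e2 = ExpressionRecord("b", "c", 6.0)
        assert rvmax_ratio(k1, k2, e1, e2) == pytest.approx(1.0, abs=1e-12)

    def test_zero_numerator_and_zero_denominator(self):
        k1, k2 = KineticsRecord("a", "A", 4.0, 1.0), KineticsRecord("b", "B", 2.0, 1.0)
        assert rvmax_ratio(k1, k2, ExpressionRecord("a", "c", 0.0),
                           ExpressionRecord("b", "c", 6.0)) == 0.0
        with pytest.raises(ParameterError):
            rvmax_ratio(k1, k2, ExpressionRecord("a", "c", 3.0),
                        ExpressionRecord("b", "c", 0.0))


@pytest.fixture(scope="module")
def ox_surface(toy_model, cs5):
    cset = cs5.copy()
    cset.bounds["ADH2"] = (-2.0, 2.0)
    cset.bounds["ALDH1"] = (-0.5, 0.5)
    return sweep_overexpression(
        toy_model, cset, "ADH2", "ALDH1", product_rxn="EX_CS_acid", rvmax=4.0
    )


class TestOverexpression:
    def test_unit_cell_reproduces_baseline_capacity(self, ox_surface):
        cell = ox_surface.grid[(ox_surface.grid.n1 == 1) & (ox_surface.grid.n2 == 1)]
        assert cell.product_flux.iloc[0] == pytest.approx(0.5, abs=1e-8)

    def test_surface_monotone_in_each_axis(self, ox_surface):
        grid = ox_surface.grid.pivot(index="n1", columns="n2",
                                     values="product_flux")
        assert (grid.diff(axis=0).fillna(0) >= -1e-8).to_numpy().all()
        assert (grid.diff(axis=1).fillna(0) >= -1e-8).to_numpy().all()

    def test_f1_only_flat_f2_only_rises_to_next_bottleneck(self, ox_surface):
        f1 = ox_surface.f1_only().product_flux.to_numpy()
        assert f1 == pytest.approx([0.5] * len(f1), abs=1e-8)
        f2 = ox_surface.f2_only().product_flux.to_numpy()
        # strictly increasing until the alcohol step's 2.0 cap binds
        assert f2[:3] == pytest.approx([0.5, 1.0, 2.0], abs=1e-8)
        assert (np.diff(f2[:3]) > 0).all()
        assert f2[3:] == pytest.approx([2.0] * len(f2[3:]), abs=1e-8)

    def test_joint_dominates_single_axis_sweeps(self, ox_surface):
        joint = ox_surface.joint().set_index("n1").product_flux
        f1 = ox_surface.f1_only().set_index("n1").product_flux
        f2 = ox_surface.f2_only().set_index("n2").product_flux
        for n in ox_surface.n_grid:
            assert joint[n] >= max(f1[n], f2[n]) - 1e-8

    def test_sweep_deterministic(self, toy_model, cs5):
        cset = cs5.copy()
        cset.bounds["ADH2"] = (-2.0, 2.0)
        cset.bounds["ALDH1"] = (-0.5, 0.5)
        a = sweep_overexpression(toy_model, cset, "ADH2", "ALDH1",
                                 product_rxn="EX_CS_acid", n_grid=[1, 4])
        b = sweep_overexpression(toy_model, cset, "ADH2", "ALDH1",
                                 product_rxn="EX_CS_acid", n_grid=[1, 4])
        assert (a.grid.product_flux == b.grid.product_flux).all()

    def test_empty_grid_rejected(self, toy_model, cs5):
        with pytest.raises(ParameterError):
            sweep_overexpression(toy_model, cs5, "ADH2", "ALDH1",
                                 product_rxn="EX_CS_acid", n_grid=[])

    def test_modes_select_slices(self, toy_model, cs5):
        cset = cs5.copy()
        cset.bounds["ADH2"] = (-2.0, 2.0)
        cset.bounds["ALDH1"] = (-0.5, 0.5)
        only = sweep_overexpression(toy_model, cset, "ADH2", "ALDH1",
                                    product_rxn="EX_CS_acid", n_grid=[1, 2, 4],
                                    mode="f2_only")
        assert len(only.grid) == 3 and (only.grid.n1 == 1).all()
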