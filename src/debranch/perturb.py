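"""In-silico interventions: graded knockdown and overexpression sweeps.

**Knockdown** emulates sRNA silencing of a branch enzyme: the targeted
reactions' bounds are divided by an inhibition factor k (2-fold … 256-fold
by default) starting from their baseline fluxes, and the network is
re-optimized at each level with a multi-objective solve (biomass first,
product second).  Fold-reduction rather than subtraction reflects that
silencing reduces enzyme amount, hence capacity, proportionally; for
reversible targets both directions are scaled toward zero.

**Overexpression** sweeps the capacity bounds of the two dehydrogenase
steps (f1 = alcohol dehydrogenase, f2 = aldehyde dehydrogenase) as n·f1
and n·f2 over a scaling grid.  The baseline capacities derive from
kinetics × expression, which fixes their initial max-rate ratio
``RVmax = (kcat1·EXP1)/(kcat2·EXP2)``; the ratio is released during the
sweep to explore the broader landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cobra import Model

from .compare import flux_sum
from .constraints import ConstraintSet, ExpressionRecord, KineticsRecord
from .errors import ParameterError
from .lp import FluxState, ObjectiveSpec, baseline_flux, optimize_multi

__all__ = [
    "KnockdownCurve",
    "OverexpressionSurface",
    "simulate_knockdown",
    "yield_improvement",
    "rvmax_ratio",
    "sweep_overexpression",
    "DEFAULT_FACTORS",
    "DEFAULT_N_GRID",
]

DEFAULT_FACTORS = (1, 2, 4, 8, 16, 32, 64, 128, 256)
DEFAULT_N_GRID = (1, 2, 4, 8, 16, 32)


@dataclass
class KnockdownCurve:
    """Result of a graded-knockdown sweep.

    ``frame`` columns: factor, bound_cap (per-target magnitude cap
    baseline/k), flux_product (the product's secretion flux),
    flux_product_total (production flux-sum of the product
    metabolite — the alternative "total flux" reading), flux_biomass,
    fold_change (vs the factor-1 baseline), status.
    """

    frame: pd.DataFrame
    baseline: FluxState
    targets: tuple[str, ...]
    product_rxn: str
    biomass_rxn: str
    degenerate: bool = False  # baseline target flux was ~0

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class OverexpressionSurface:
    """Product flux per (n1·f1, n2·f2) capacity cell.

    ``grid`` columns: n1, n2, ub_f1, ub_f2, product_flux, status.  The
    three reported curves are the f1-only row, the f2-only column and the
    joint diagonal of this grid.
    """

    grid: pd.DataFrame
    f1: str
    f2: str
    f1_base: float
    f2_base: float
    n_grid: tuple[float, ...]
    product_rxn: str
    mode: str = "both"
    rvmax: float | None = None

    def _curve(self, fixed: str) -> pd.DataFrame:
        if fixed == "f1_only":
            sub = self.grid[self.grid["n2"] == 1]
            return sub.sort_values("n1").reset_index(drop=True)
        if fixed == "f2_only":
            sub = self.grid[self.grid["n1"] == 1]
            return sub.sort_values("n2").reset_index(drop=True)
        sub = self.grid[self.grid["n1"] == self.grid["n2"]]
        return sub.sort_values("n1").reset_index(drop=True)

    def f1_only(self) -> pd.DataFrame:
        return self._curve("f1_only")

    def f2_only(self) -> pd.DataFrame:
        return self._curve("f2_only")

    def joint(self) -> pd.DataFrame:
        return self._curve("joint")

    def to_tsv(self, path: str | Path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)


def simulate_knockdown(
    model: Model,
    constraints: ConstraintSet | None,
    targets: Sequence[str],
    product_rxn: str,
    biomass_rxn: str,
    factors: Sequence[float] = DEFAULT_FACTORS,
    objective: ObjectiveSpec | None = None,
) -> KnockdownCurve:
    """Graded fold-knockdown of ``targets`` starting from the baseline flux.

    The baseline is the deterministic biomass-maximizing distribution under
    ``constraints``; at each factor k the targets' bounds are capped at
    |baseline flux| / k (both directions for reversible targets) and the
    multi-objective problem (default: lexicographic biomass then product)
    is re-solved.  The factor-1 row *is* the baseline, so its fold-change
    is exactly 1.  Infeasible factors are flagged and the sweep continues.

    If the constraint set fixes the biomass flux, the fixation is relaxed
    to an upper bound during the sweep (a perturbed strain may grow more
    slowly than measured, and "maximize biomass" must stay meaningful).
    """
    factors = sorted(set(float(f) for f in factors))
    if any(f <= 0 for f in factors):
        raise ParameterError("knockdown factors must be positive")
    if 1.0 not in factors:
        factors = [1.0] + factors
    missing = [t for t in targets if t not in model.reactions]
    if missing:
        raise ParameterError(f"knockdown targets not in model: {missing}")

    base = baseline_flux(model, constraints, objective=biomass_rxn)
    base_product = base[product_rxn]
    base_values = {t: base[t] for t in targets}
    degenerate = all(abs(v) < 1e-9 for v in base_values.values())
    if degenerate:
        warnings.warn(
            f"baseline flux through {tuple(targets)} is ~0; knockdown is "
            "degenerate (bounds pinned at 0 for every factor)"
        )

    sweep_base = (constraints or ConstraintSet()).copy()
    if biomass_rxn in sweep_base.fixed:
        fixed_value = sweep_base.fixed.pop(biomass_rxn)
        sweep_base.bounds[biomass_rxn] = (0.0, fixed_value)
    if objective is None:
        objective = ObjectiveSpec.lexicographic(biomass_rxn, product_rxn)

    product_met = _single_boundary_metabolite(model, product_rxn)
    rows = []
    for k in factors:
        if k == 1.0:
            rows.append(
                {
                    "factor": 1.0,
                    "bound_cap": max(abs(v) for v in base_values.values()),
                    "flux_product": base_product,
                    "flux_product_total": float(flux_sum(model, base.fluxes, product_met)),
                    "flux_biomass": base[biomass_rxn],
                    "fold_change": 1.0 if base_product > 0 else np.nan,
                    "status": "baseline",
                }
            )
            continue
        cset = sweep_base.copy()
        for t, v in base_values.items():
            cap = abs(v) / k
            cset.bounds[t] = (-cap, cap)  # intersected with model bounds
        state = optimize_multi(model, cset, objective)
        if not state.optimal:
            rows.append(
                {
                    "factor": k, "bound_cap": np.nan, "flux_product": np.nan,
                    "flux_product_total": np.nan, "flux_biomass": np.nan,
                    "fold_change": np.nan, "status": state.status,
                }
            )
            continue
        flux_cs = state[product_rxn]
        rows.append(
            {
                "factor": k,
                "bound_cap": max(abs(v) for v in base_values.values()) / k,
                "flux_product": flux_cs,
                "flux_product_total": float(flux_sum(model, state.fluxes, product_met)),
                "flux_biomass": state[biomass_rxn],
                "fold_change": flux_cs / base_product if base_product > 0 else np.nan,
                "status": "optimal",
            }
        )
    frame = pd.DataFrame(rows)
    return KnockdownCurve(
        frame=frame, baseline=base, targets=tuple(targets),
        product_rxn=product_rxn, biomass_rxn=biomass_rxn, degenerate=degenerate,
    )


def _single_boundary_metabolite(model: Model, rxn_id: str) -> str:
    rxn = model.reactions.get_by_id(rxn_id)
    mets = list(rxn.metabolites)
    if len(mets) != 1:
        raise ParameterError(
            f"product reaction {rxn_id!r} is not a single-metabolite exchange"
        )
    return mets[0].id


def yield_improvement(curve: KnockdownCurve) -> pd.DataFrame:
    """Yield-improvement ratios vs the uninhibited baseline.

    Returns a frame (factor, ratio) with attrs ``max_ratio`` and
    ``argmax_factor``.  A zero baseline makes the ratio undefined: every
    ratio is the NaN sentinel and a warning is emitted (no division).
    """
    base = curve.frame.loc[curve.frame["factor"] == 1.0, "flux_product"]
    baseline = float(base.iloc[0])
    out = curve.frame[["factor"]].copy()
    if baseline <= 0:
        warnings.warn("baseline product flux is 0; yield ratios undefined")
        out["ratio"] = np.nan
        out.attrs["max_ratio"] = np.nan
        out.attrs["argmax_factor"] = np.nan
        return out
    out["ratio"] = curve.frame["flux_product"] / baseline
    valid = out.dropna(subset=["ratio"])
    best = valid.loc[valid["ratio"].idxmax()]
    out.attrs["max_ratio"] = float(best["ratio"])
    out.attrs["argmax_factor"] = float(best["factor"])
    return out


def rvmax_ratio(
    kin1: KineticsRecord,
    kin2: KineticsRecord,
    expr1: ExpressionRecord,
    expr2: ExpressionRecord,
) -> float:
    """Initial max-rate ratio RVmax = (kcat1·EXP1) / (kcat2·EXP2).

    The θ and unit-conversion factors cancel, so the ratio only needs kcat
    and the measured expression levels.
    """
    denom = kin2.kcat * expr2.tpm
    if denom == 0:
        raise ParameterError("RVmax undefined: kcat2·EXP2 = 0")
    return (kin1.kcat * expr1.tpm) / denom


def sweep_overexpression(
    model: Model,
    constraints: ConstraintSet | None,
    f1: str,
    f2: str,
    product_rxn: str,
    n_grid: Sequence[float] = DEFAULT_N_GRID,
    mode: str = "both",
    objective: ObjectiveSpec | str | None = None,
    f1_base: float | None = None,
    f2_base: float | None = None,
    rvmax: float | None = None,
) -> OverexpressionSurface:
    """n-fold capacity sweep of the two dehydrogenase steps.

    Base capacities default to the constraint set's Vmax bound on each
    reaction (falling back to the model bound); each cell re-solves with
    upper bounds n1·f1_base and n2·f2_base.  ``mode`` selects the f1-only
    row, the f2-only column, or the full grid (the joint curve is its
    diagonal).  The surface is non-decreasing along each axis because each
    step only relaxes an upper bound.
    """
    n_grid = tuple(float(n) for n in n_grid)
    if not n_grid:
        raise ParameterError("overexpression grid must be non-empty")
    if any(n <= 0 for n in n_grid):
        raise ParameterError("scaling factors must be positive")
    if mode not in ("f1_only", "f2_only", "both"):
        raise ParameterError(f"unknown sweep mode {mode!r}")

    cset0 = (constraints or ConstraintSet()).copy()

    def _base(rxn_id: str, given: float | None) -> float:
        if given is not None:
            value = given
        elif rxn_id in cset0.bounds:
            value = cset0.bounds[rxn_id][1]
        else:
            value = model.reactions.get_by_id(rxn_id).upper_bound
        if not (np.isfinite(value) and value > 0):
            raise ParameterError(
                f"base bound for {rxn_id!r} must be finite and positive, got {value}"
            )
        return float(value)

    b1, b2 = _base(f1, f1_base), _base(f2, f2_base)
    if objective is None:
        objective = ObjectiveSpec.single(product_rxn)
    if isinstance(objective, str):
        objective = ObjectiveSpec.single(objective)

    if mode == "f1_only":
        cells = [(n, 1.0) for n in n_grid]
    elif mode == "f2_only":
        cells = [(1.0, n) for n in n_grid]
    else:
        cells = [(n1, n2) for n1 in n_grid for n2 in n_grid]

    rows = []
    for n1, n2 in cells:
        cset = cset0.copy()
        cset.bounds[f1] = (-n1 * b1, n1 * b1)
        cset.bounds[f2] = (-n2 * b2, n2 * b2)
        state = optimize_multi(model, cset, objective) if objective.mode != "single" \
            else _single_solve(model, cset, objective)
        rows.append(
            {
                "n1": n1, "n2": n2, "ub_f1": n1 * b1, "ub_f2": n2 * b2,
                "product_flux": state[product_rxn] if state.optimal else np.nan,
                "status": state.status,
            }
        )
    return OverexpressionSurface(
        grid=pd.DataFrame(rows), f1=f1, f2=f2, f1_base=b1, f2_base=b2,
        n_grid=n_grid, product_rxn=product_rxn, mode=mode, rvmax=rvmax,
    )


def _single_solve(model: Model, cset: ConstraintSet, objective: ObjectiveSpec) -> FluxState:
    from .lp import fba

    return fba(model, cset, objective)
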