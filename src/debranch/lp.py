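"""Linear-programming core: FBA, reproducible baseline flux, FVA,
multi-objective optimization and feasible-region sampling.

Everything is plain LP solved through COBRApy's optlang/GLPK stack; the
module's own contributions are the scoping of a :class:`ConstraintSet`
around each solve, a deterministic baseline-flux rule (parsimonious FBA
plus a min–max tie-break that picks a unique point on the degenerate
minimum-total-flux face), and the two multi-objective modes used for the
knockdown simulations.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cobra import Model
from cobra.flux_analysis import flux_variability_analysis, pfba
from cobra.sampling import ACHRSampler
from cobra.util import fix_objective_as_constraint

from .constraints import ConstraintSet
from .errors import InfeasibleError, NormalizationError, ParameterError, UnboundedError

__all__ = [
    "FluxState",
    "FvaResult",
    "SamplingEnsemble",
    "ObjectiveSpec",
    "fba",
    "baseline_flux",
    "fva",
    "sample_fluxes",
    "optimize_multi",
]

FEASIBILITY_TOL = 1e-9
REPORT_TOL = 1e-6


@dataclass
class FluxState:
    """One flux distribution: v (mmol/gDW/hr), objective value and status."""

    fluxes: pd.Series
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn: str) -> float:
        return float(self.fluxes[rxn])

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path: str | Path) -> None:
        frame = self.fluxes.rename("flux").rename_axis("reaction").reset_index()
        frame.to_csv(path, sep="\t", index=False)


@dataclass
class FvaResult:
    """Per-reaction [min, max] flux at a stated fraction of the optimum."""

    frame: pd.DataFrame  # index: reaction id; columns: minimum, maximum
    fraction: float

    def interval(self, rxn: str) -> tuple[float, float]:
        row = self.frame.loc[rxn]
        return float(row["minimum"]), float(row["maximum"])

    def width(self, rxn: str) -> float:
        lo, hi = self.interval(rxn)
        return hi - lo

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("reaction").reset_index().to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SamplingEnsemble:
    """n_samples x n_reactions matrix of steady-state flux points."""

    samples: pd.DataFrame
    seed: int
    thinning: int
    n_warmup: int = 0
    method: str = "achr"

    @property
    def n(self) -> int:
        return len(self.samples)

    def column(self, rxn: str) -> np.ndarray:
        return self.samples[rxn].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


@dataclass
class ObjectiveSpec:
    """single | weighted | lexicographic objective over reaction terms.

    ``terms`` are (reaction_id, weight) in weighted/single mode, and
    (reaction_id, priority) in lexicographic mode — lower priority number
    optimized first; order of equal priorities follows list order.
    """

    mode: str = "single"
    terms: list[tuple[str, float]] = field(default_factory=list)
    slack: float = 0.999  # lexicographic: retain this fraction of each optimum

    def __post_init__(self) -> None:
        if self.mode not in ("single", "weighted", "lexicographic"):
            raise ParameterError(f"unknown objective mode {self.mode!r}")
        if self.mode == "lexicographic":
            priorities = [p for _, p in self.terms]
            if len(set(priorities)) != len(priorities):
                raise ParameterError("lexicographic priorities must be unique")
        for _, w in self.terms:
            if not np.isfinite(w):
                raise ParameterError("objective weights must be finite")

    @classmethod
    def single(cls, rxn: str) -> "ObjectiveSpec":
        return cls(mode="single", terms=[(rxn, 1.0)])

    @classmethod
    def lexicographic(cls, *rxns: str, slack: float = 0.999) -> "ObjectiveSpec":
        return cls(
            mode="lexicographic",
            terms=[(r, float(i)) for i, r in enumerate(rxns)],
            slack=slack,
        )

    @classmethod
    def weighted(cls, terms: dict[str, float]) -> "ObjectiveSpec":
        return cls(mode="weighted", terms=list(terms.items()))


@contextlib.contextmanager
def constrained(model: Model, constraints: ConstraintSet | None):
    """Scope a constraint set onto a model; restores state on exit."""
    with model:
        if constraints is not None:
            constraints.apply(model)
        yield model


def _state_from(model: Model) -> FluxState:
    solution = model.optimize()
    if solution.status == "optimal":
        return FluxState(solution.fluxes.copy(), float(solution.objective_value), "optimal")
    status = "unbounded" if "unbounded" in str(solution.status) else "infeasible"
    return FluxState(pd.Series(dtype=float), None, status)


def fba(
    model: Model,
    constraints: ConstraintSet | None = None,
    objective: ObjectiveSpec | str | None = None,
) -> FluxState:
    """Flux balance analysis: maximize the objective over S·v = 0, lb <= v <= ub.

    Returns a :class:`FluxState` whose status is ``infeasible`` or
    ``unbounded`` (with no fluxes) instead of raising, so sweeps can skim
    over degenerate rows.
    """
    if isinstance(objective, str):
        objective = ObjectiveSpec.single(objective)
    if objective is not None and objective.mode != "single":
        return optimize_multi(model, constraints, objective)
    with constrained(model, constraints) as scoped:
        if objective is not None:
            rxn, weight = objective.terms[0]
            scoped.objective = {scoped.reactions.get_by_id(rxn): weight}
            scoped.objective_direction = "max"
        return _state_from(scoped)


def baseline_flux(
    model: Model,
    constraints: ConstraintSet | None = None,
    objective: ObjectiveSpec | str | None = None,
) -> FluxState:
    """Deterministic baseline distribution at the FBA optimum.

    Three LP stages: (1) fix the objective at its FBA maximum; (2) minimize
    total absolute flux (parsimonious FBA); (3) center the solution on the
    minimum-total-flux face: compute each reaction's flux range on that
    face and return the L1 projection of the per-reaction midpoints back
    onto it.  Stage 3 is a pure-LP tie-break that picks a reproducible,
    solver-order-independent point when the parsimonious face is degenerate
    (e.g. two symmetric parallel paths split 50/50 instead of an arbitrary
    vertex).
    """
    probe = fba(model, constraints, objective)
    if not probe.optimal:
        raise InfeasibleError(f"baseline FBA not optimal: status {probe.status}")
    if isinstance(objective, str):
        objective = ObjectiveSpec.single(objective)
    with constrained(model, constraints) as scoped:
        if objective is not None and objective.mode == "single":
            rxn, weight = objective.terms[0]
            scoped.objective = {scoped.reactions.get_by_id(rxn): weight}
            scoped.objective_direction = "max"
        pfba_solution = pfba(scoped)
        total = sum(abs(v) for v in pfba_solution.fluxes)
        # stage 3: pin objective and total flux, center on the optimal face
        fix_objective_as_constraint(scoped, fraction=1.0)
        prob = scoped.problem
        flux_sum_expr = 0
        for rxn in scoped.reactions:
            flux_sum_expr = flux_sum_expr + rxn.forward_variable + rxn.reverse_variable
        scoped.add_cons_vars(
            [prob.Constraint(flux_sum_expr, ub=total + FEASIBILITY_TOL,
                             name="baseline_total_flux")]
        )
        midpoints: dict[str, float] = {}
        for rxn in scoped.reactions:
            span = []
            for direction in ("min", "max"):
                scoped.objective = prob.Objective(rxn.flux_expression,
                                                  direction=direction)
                span.append(scoped.slim_optimize())
            midpoints[rxn.id] = 0.5 * (span[0] + span[1])
        # L1 projection of the midpoint vector onto the face
        devs, cons = [], []
        for rxn in scoped.reactions:
            d = prob.Variable(f"baseline_dev_{rxn.id}", lb=0)
            devs.append(d)
            m = midpoints[rxn.id]
            cons.append(prob.Constraint(rxn.flux_expression - d, ub=m,
                                        name=f"baseline_dev_hi_{rxn.id}"))
            cons.append(prob.Constraint(rxn.flux_expression + d, lb=m,
                                        name=f"baseline_dev_lo_{rxn.id}"))
        scoped.add_cons_vars(devs + cons)
        scoped.objective = prob.Objective(sum(devs), direction="min")
        solution = scoped.optimize()
        if solution.status != "optimal":  # pragma: no cover - degenerate guard
            return FluxState(pfba_solution.fluxes.copy(), probe.objective_value, "optimal")
        return FluxState(solution.fluxes.copy(), probe.objective_value, "optimal")


def fva(
    model: Model,
    constraints: ConstraintSet | None = None,
    fraction_of_optimum: float = 1.0,
    objective: ObjectiveSpec | str | None = None,
    reactions: list[str] | None = None,
) -> FvaResult:
    """Per-reaction flux range subject to objective >= fraction × optimum."""
    if not (0 <= fraction_of_optimum <= 1):
        raise ParameterError(
            f"fraction_of_optimum must lie in [0, 1], got {fraction_of_optimum}"
        )
    with constrained(model, constraints) as scoped:
        if isinstance(objective, str):
            objective = ObjectiveSpec.single(objective)
        if objective is not None and objective.mode == "single":
            rxn, weight = objective.terms[0]
            scoped.objective = {scoped.reactions.get_by_id(rxn): weight}
            scoped.objective_direction = "max"
        probe = scoped.slim_optimize()
        if probe is None or np.isnan(probe):
            raise InfeasibleError(
                "FVA: base FBA infeasible under the supplied constraint set"
            )
        frame = flux_variability_analysis(
            scoped,
            reaction_list=reactions,
            fraction_of_optimum=fraction_of_optimum,
            processes=1,
        )
    return FvaResult(frame=frame, fraction=fraction_of_optimum)


def sample_fluxes(
    model: Model,
    constraints: ConstraintSet | None = None,
    n: int = 1000,
    seed: int = 0,
    thinning: int = 100,
) -> SamplingEnsemble:
    """Seeded coordinate hit-and-run sampling of the flux polytope.

    Warmup points are FVA extreme solutions (the ACHR construction);
    identical (model, constraints, n, seed, thinning) yield bitwise
    identical ensembles.  Requires a bounded region: every bound must be
    finite after constraint application.
    """
    if n <= 0:
        raise ParameterError(f"sample count must be positive, got {n}")
    with constrained(model, constraints) as scoped:
        for rxn in scoped.reactions:
            if not np.isfinite(rxn.lower_bound) or not np.isfinite(rxn.upper_bound):
                raise UnboundedError(
                    f"reaction {rxn.id!r} has an infinite bound; tighten bounds "
                    "before sampling"
                )
        sampler = ACHRSampler(scoped, thinning=thinning, seed=seed)
        samples = sampler.sample(n)
        n_warmup = int(sampler.n_warmup)
    return SamplingEnsemble(
        samples=samples, seed=seed, thinning=thinning, n_warmup=n_warmup
    )


def optimize_multi(
    model: Model,
    constraints: ConstraintSet | None = None,
    objective: ObjectiveSpec | None = None,
) -> FluxState:
    """Weighted or lexicographic multi-objective FBA.

    * weighted — maximize Σ wᵢ·(vᵢ / optᵢ), each term normalized by its
      standalone optimum (zero standalone optimum → NormalizationError);
    * lexicographic — optimize terms in priority order, clamping each at
      ``slack`` × its optimum before moving on; the returned objective value
      is the last term's optimum.
    """
    if objective is None or len(objective.terms) < 1:
        raise ParameterError("optimize_multi requires an objective with terms")
    if objective.mode == "single":
        return fba(model, constraints, objective)

    if objective.mode == "weighted":
        opts: dict[str, float] = {}
        for rxn, _ in objective.terms:
            st = fba(model, constraints, ObjectiveSpec.single(rxn))
            if not st.optimal:
                raise InfeasibleError(f"standalone optimum for {rxn!r}: {st.status}")
            opts[rxn] = st.objective_value
            if abs(st.objective_value) < FEASIBILITY_TOL:
                raise NormalizationError(
                    f"standalone optimum of {rxn!r} is 0; weighted normalization "
                    "undefined — use lexicographic mode or drop the term"
                )
        with constrained(model, constraints) as scoped:
            scoped.objective = {
                scoped.reactions.get_by_id(rxn): w / opts[rxn]
                for rxn, w in objective.terms
            }
            scoped.objective_direction = "max"
            return _state_from(scoped)

    # lexicographic
    ordered = sorted(objective.terms, key=lambda t: t[1])
    with constrained(model, constraints) as scoped:
        state: FluxState | None = None
        for i, (rxn, _priority) in enumerate(ordered):
            scoped.objective = {scoped.reactions.get_by_id(rxn): 1.0}
            scoped.objective_direction = "max"
            state = _state_from(scoped)
            if not state.optimal:
                return state
            if i < len(ordered) - 1:
                opt = state.objective_value
                floor = opt - (1.0 - objective.slack) * abs(opt) - FEASIBILITY_TOL
                scoped.reactions.get_by_id(rxn).lower_bound = max(
                    scoped.reactions.get_by_id(rxn).lower_bound, floor
                )
        assert state is not None
        return state
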