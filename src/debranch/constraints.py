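"""Bespoke constraint set for the debranching workflow.

Three constraint families beyond plain flux bounds:

* **expression-scaled Vmax bounds** — the capacity of an enzymatic reaction
  is capped at ``Vmax = kcat * 3600 * theta * TPM`` (kcat in 1/s, the 3600
  converts to 1/hr, ``theta`` maps transcript abundance to enzyme amount in
  mmol/gDW so Vmax lands in mmol/gDW/hr);
* **flux-ratio pins** — ``v_A : v_B = a : b`` enforced as the linear
  equality ``b*v_A - a*v_B = 0`` (used to pin the MVA:MEP split measured by
  transcriptomics, 6461:1 in the reference strain);
* **Δ-scaled group caps** — the summed consumption flux of a precursor
  must not exceed ``Δ`` times its summed production-route flux,
  ``Σ F_out <= Δ · Σ F_in`` with ``Δ ∈ (0,1]``.  Consumption/production is
  measured as the precursor-directed positive part of each reaction's flux
  via the solver's forward/reverse split variables, so reversible reactions
  only count when actually flowing toward the pool.

:func:`cs5_preset` bundles the printed reference-strain condition: glucose
uptake capped at 20 mmol/gDW/hr, biomass fixed at 1.706, chrysanthemol
secretion floored at 0.0023, the 6461:1 MVA:MEP ratio pin and the Δ=0.4
DMAPP group cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml
from cobra import Model

from .errors import (
    ConfigurationError,
    ExpressionLookupError,
    ParameterError,
)

__all__ = [
    "KineticsRecord",
    "ExpressionRecord",
    "VmaxSpec",
    "RatioPin",
    "GroupCap",
    "ConstraintSet",
    "vmax_bound",
    "ratio_pin",
    "group_cap",
    "cs5_preset",
    "calibrate_theta",
    "read_kinetics_table",
    "read_expression_table",
    "DEFAULT_THETA",
    "CS5_DEFAULT_IDS",
]

#: Default transcript-to-enzyme weighting factor (mmol gDW^-1 per TPM unit).
DEFAULT_THETA = 1e-5

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class KineticsRecord:
    """Enzyme kinetics for one gene/reaction pair.

    kcat in 1/s, Km in mM; ``source`` tags the provenance (literature or a
    kcat/Km predictor's output table).
    """

    gene: str
    reaction: str
    kcat: float
    km: float
    source: str = "predicted"

    def __post_init__(self) -> None:
        if not self.kcat > 0:
            raise ParameterError(f"kcat must be > 0, got {self.kcat}")
        if not self.km > 0:
            raise ParameterError(f"Km must be > 0, got {self.km}")


@dataclass(frozen=True)
class ExpressionRecord:
    """Transcript abundance (TPM) of one gene under one condition."""

    gene: str
    condition: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ParameterError(f"TPM must be >= 0, got {self.tpm}")


@dataclass(frozen=True)
class VmaxSpec:
    """Derived capacity bound for one reaction: Vmax = kcat*3600*theta*TPM."""

    reaction: str
    theta: float
    etotal: float
    vmax: float


def vmax_bound(
    kin: KineticsRecord, expr: ExpressionRecord, theta: float = DEFAULT_THETA
) -> VmaxSpec:
    """Expression-scaled capacity bound for ``kin.reaction``.

    ``Etotal = theta * TPM`` (mmol/gDW) and ``Vmax = kcat * 3600 * Etotal``
    (mmol/gDW/hr); the 1/s -> 1/hr conversion is applied exactly once here.
    """
    if not theta > 0:
        raise ParameterError(f"theta must be > 0, got {theta}")
    etotal = theta * expr.tpm
    vmax = kin.kcat * SECONDS_PER_HOUR * etotal
    return VmaxSpec(reaction=kin.reaction, theta=theta, etotal=etotal, vmax=vmax)


def calibrate_theta(
    kin: KineticsRecord, expr: ExpressionRecord, reference_flux: float
) -> float:
    """Global theta such that the reference reaction's Vmax equals a flux."""
    if reference_flux <= 0:
        raise ParameterError("reference flux must be > 0")
    if expr.tpm <= 0:
        raise ParameterError("cannot calibrate theta against TPM = 0")
    return reference_flux / (kin.kcat * SECONDS_PER_HOUR * expr.tpm)


@dataclass(frozen=True)
class RatioPin:
    """Pin v_A : v_B = a : b, enforced as b*v_A - a*v_B = 0."""

    rxn_a: str
    rxn_b: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ParameterError(
                f"ratio terms must be positive, got {self.a}:{self.b}"
            )


def ratio_pin(rxn_a: str, rxn_b: str, a: float, b: float) -> RatioPin:
    return RatioPin(rxn_a, rxn_b, float(a), float(b))


@dataclass(frozen=True)
class GroupCap:
    """Σ consumption(F_out) <= Δ · Σ production(F_in), Δ ∈ (0,1].

    ``metabolite`` orients reversible members: a reaction counts toward
    consumption (production) only for the flux direction that actually
    drains (feeds) that metabolite.  With ``metabolite=None`` the forward
    direction of every member is counted.
    """

    consumers: tuple[str, ...]
    producers: tuple[str, ...]
    delta: float
    metabolite: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.delta <= 1):
            raise ParameterError(f"delta must lie in (0, 1], got {self.delta}")
        if not self.consumers or not self.producers:
            raise ParameterError("consumer and producer sets must be non-empty")
        if set(self.consumers) & set(self.producers):
            raise ParameterError("consumer and producer sets must be disjoint")


def group_cap(
    consumers: list[str] | tuple[str, ...],
    producers: list[str] | tuple[str, ...],
    delta: float,
    metabolite: str | None = None,
) -> GroupCap:
    return GroupCap(tuple(consumers), tuple(producers), float(delta), metabolite)


@dataclass
class ConstraintSet:
    """Bound overrides, fixed fluxes, ratio pins and group caps.

    ``bounds`` are *intersected* with the model's (capacity caps can only
    tighten, never re-open a closed direction); ``fixed`` values override
    both bounds exactly.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    ratios: list[RatioPin] = field(default_factory=list)
    group_caps: list[GroupCap] = field(default_factory=list)

    def with_bound(self, rxn: str, lb: float, ub: float) -> "ConstraintSet":
        new = dict(self.bounds)
        new[rxn] = (lb, ub)
        return replace(self, bounds=new)

    def with_fixed(self, rxn: str, value: float) -> "ConstraintSet":
        new = dict(self.fixed)
        new[rxn] = value
        return replace(self, fixed=new)

    def add_vmax(self, spec: VmaxSpec) -> "ConstraintSet":
        """Cap the reaction's capacity at ±Vmax (intersected with model bounds)."""
        return self.with_bound(spec.reaction, -spec.vmax, spec.vmax)

    def copy(self) -> "ConstraintSet":
        return ConstraintSet(
            bounds=dict(self.bounds),
            fixed=dict(self.fixed),
            ratios=list(self.ratios),
            group_caps=list(self.group_caps),
        )

    # -- application -------------------------------------------------------

    def check_ids(self, model: Model) -> None:
        referenced = (
            set(self.bounds)
            | set(self.fixed)
            | {r.rxn_a for r in self.ratios}
            | {r.rxn_b for r in self.ratios}
            | {rid for cap in self.group_caps for rid in cap.consumers + cap.producers}
        )
        missing = sorted(rid for rid in referenced if rid not in model.reactions)
        if missing:
            raise ConfigurationError(
                f"constraint set references unknown reactions: {missing}; "
                f"candidates include {[r.id for r in model.reactions[:20]]}"
            )

    def apply(self, model: Model) -> None:
        """Mutate ``model`` in place; call inside ``with model:`` to scope."""
        self.check_ids(model)
        for rid, (lb, ub) in self.bounds.items():
            rxn = model.reactions.get_by_id(rid)
            new_lb = max(rxn.lower_bound, lb)
            new_ub = min(rxn.upper_bound, ub)
            if new_lb > new_ub:
                raise ConfigurationError(
                    f"bound override on {rid!r} empties its interval: "
                    f"[{new_lb}, {new_ub}]"
                )
            rxn.bounds = (new_lb, new_ub)
        for rid, value in self.fixed.items():
            model.reactions.get_by_id(rid).bounds = (value, value)
        to_add = []
        for i, pin in enumerate(self.ratios):
            va = model.reactions.get_by_id(pin.rxn_a).flux_expression
            vb = model.reactions.get_by_id(pin.rxn_b).flux_expression
            to_add.append(
                model.problem.Constraint(
                    pin.b * va - pin.a * vb, lb=0, ub=0,
                    name=f"ratio_pin_{i}_{pin.rxn_a}_{pin.rxn_b}",
                )
            )
        for i, cap in enumerate(self.group_caps):
            expr = 0
            for rid in cap.consumers:
                expr = expr + _directed_part(model, rid, cap.metabolite, consuming=True)
            for rid in cap.producers:
                expr = expr - cap.delta * _directed_part(
                    model, rid, cap.metabolite, consuming=False
                )
            to_add.append(
                model.problem.Constraint(expr, ub=0, name=f"group_cap_{i}")
            )
        if to_add:
            model.add_cons_vars(to_add)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bounds": {r: [lb, ub] for r, (lb, ub) in self.bounds.items()},
            "fixed": dict(self.fixed),
            "ratios": [
                {"rxn_a": p.rxn_a, "rxn_b": p.rxn_b, "a": p.a, "b": p.b}
                for p in self.ratios
            ],
            "group_caps": [
                {
                    "consumers": list(c.consumers),
                    "producers": list(c.producers),
                    "delta": c.delta,
                    "metabolite": c.metabolite,
                }
                for c in self.group_caps
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ConstraintSet":
        return cls(
            bounds={r: (float(v[0]), float(v[1])) for r, v in data.get("bounds", {}).items()},
            fixed={r: float(v) for r, v in data.get("fixed", {}).items()},
            ratios=[
                RatioPin(d["rxn_a"], d["rxn_b"], float(d["a"]), float(d["b"]))
                for d in data.get("ratios", [])
            ],
            group_caps=[
                GroupCap(
                    tuple(d["consumers"]), tuple(d["producers"]),
                    float(d["delta"]), d.get("metabolite"),
                )
                for d in data.get("group_caps", [])
            ],
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstraintSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _directed_part(model: Model, rid: str, metabolite: str | None, consuming: bool):
    """LP expression for the pool-directed positive part of a reaction flux.

    Uses the solver's forward/reverse split variables.  For a reaction with
    stoichiometric coefficient ``c`` on the focal metabolite, consumption
    happens in the forward direction when ``c < 0`` and in the reverse
    direction when ``c > 0`` (and vice versa for production).  Members that
    do not touch the metabolite itself (upstream supply-route steps counted
    as pathway flux) contribute their forward flux.
    """
    rxn = model.reactions.get_by_id(rid)
    if metabolite is None:
        return rxn.forward_variable
    met = model.metabolites.get_by_id(metabolite)
    coeff = rxn.metabolites.get(met)
    if coeff is None:
        return rxn.forward_variable
    forward_consumes = coeff < 0
    if consuming == forward_consumes:
        return rxn.forward_variable
    return rxn.reverse_variable


#: Reaction/metabolite ids the CS5 preset expects; every entry can be
#: re-pointed through the ``aliases`` argument of :func:`cs5_preset`.
CS5_DEFAULT_IDS = {
    "glucose_exchange": "EX_glc__D_e",
    "biomass": "BIOMASS_Ec_iJO1366_WT_53p95M",
    "product_secretion": "EX_CS_OH",
    "mva_terminal": "DPMVD",
    "mep_terminal": "CDPMEK",
    "dmapp": "dmapp_c",
    "isomerase": "IDI",
    "supply_routes": None,  # optional: explicit producer-route reaction ids
}

CS5_GLUCOSE_UPTAKE = 20.0
CS5_BIOMASS_FLUX = 1.706
CS5_PRODUCT_FLOOR = 0.0023
CS5_RATIO = (6461.0, 1.0)
CS5_DELTA = 0.4


def cs5_preset(model: Model, aliases: dict[str, str] | None = None) -> ConstraintSet:
    """The printed reference-strain condition as a :class:`ConstraintSet`.

    Five records: glucose uptake capped at 20 mmol/gDW/hr, biomass fixed at
    1.706, chrysanthemol secretion floored at 0.0023, MVA:MEP ratio pinned
    at 6461:1 (terminal reactions DPMVD:CDPMEK), and the Δ=0.4 group cap on
    DMAPP consumption.

    The cap's producer side is the *supply-route* flux (both precursor
    pathways' reactions; the pool's "initial production rate"), and its
    consumer side is every terminal consumer of the DMAPP pool except the
    IPP isomerase — a Δ<1 cap between the full producer and consumer sets
    of one metabolite is unsatisfiable at steady state, where the two sums
    coincide.  Supply-route membership can be overridden through
    ``aliases["supply_routes"]`` (comma-separated reaction ids).
    """
    ids = dict(CS5_DEFAULT_IDS)
    if aliases:
        ids.update(aliases)
    required = [
        "glucose_exchange", "biomass", "product_secretion",
        "mva_terminal", "mep_terminal",
    ]
    missing = [k for k in required if ids[k] not in model.reactions]
    if missing:
        raise ConfigurationError(
            "cs5_preset: model lacks reactions for roles "
            f"{missing} (ids {[ids[k] for k in missing]}); pass aliases. "
            f"Model reactions: {[r.id for r in model.reactions][:30]}"
        )
    if ids["dmapp"] not in model.metabolites:
        raise ConfigurationError(
            f"cs5_preset: metabolite {ids['dmapp']!r} not in model; pass aliases"
        )

    dmapp = model.metabolites.get_by_id(ids["dmapp"])
    if ids.get("supply_routes"):
        producers = tuple(str(ids["supply_routes"]).split(","))
    else:
        # default supply routes: reactions feeding DMAPP plus their pathway
        # predecessors one step upstream, i.e. both terminal steps.
        producers = (ids["mep_terminal"], ids["mva_terminal"])
    consumers = tuple(
        sorted(
            rxn.id
            for rxn in dmapp.reactions
            if rxn.metabolites[dmapp] < 0
            and rxn.id not in producers
            and rxn.id != ids.get("isomerase")
        )
    )
    if not consumers:
        raise ConfigurationError("cs5_preset: no DMAPP-consuming reactions found")

    cset = ConstraintSet(
        bounds={
            ids["glucose_exchange"]: (-CS5_GLUCOSE_UPTAKE, math.inf),
            ids["product_secretion"]: (CS5_PRODUCT_FLOOR, math.inf),
        },
        fixed={ids["biomass"]: CS5_BIOMASS_FLUX},
        ratios=[RatioPin(ids["mva_terminal"], ids["mep_terminal"], *CS5_RATIO)],
        group_caps=[
            GroupCap(consumers, producers, CS5_DELTA, metabolite=ids["dmapp"])
        ],
    )
    cset.check_ids(model)
    return cset


# -- table IO ---------------------------------------------------------------

def read_kinetics_table(path: str | Path) -> pd.DataFrame:
    """TSV with header gene, reaction, kcat_per_s, Km_mM[, source]."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene", "reaction", "kcat_per_s", "Km_mM"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"kinetics table missing columns {sorted(missing)}")
    if "source" not in frame.columns:
        frame["source"] = "predicted"
    return frame


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with header gene, condition, TPM."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "TPM"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"expression table missing columns {sorted(missing)}")
    return frame


def kinetics_records(frame: pd.DataFrame) -> list[KineticsRecord]:
    return [
        KineticsRecord(
            gene=row.gene, reaction=row.reaction,
            kcat=float(row.kcat_per_s), km=float(row.Km_mM),
            source=getattr(row, "source", "predicted"),
        )
        for row in frame.itertuples(index=False)
    ]


def lookup_tpm(expression: pd.DataFrame, gene: str, condition: str) -> float:
    hit = expression[(expression["gene"] == gene) & (expression["condition"] == condition)]
    if hit.empty:
        raise ExpressionLookupError(
            f"no TPM for gene {gene!r} under condition {condition!r}"
        )
    return float(hit["TPM"].iloc[0])
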