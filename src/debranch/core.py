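"""Model container, readers/writers, pathway extension and consistency checks.

The in-memory model is a :class:`cobra.Model` (BiGG-style identifier
conventions: lowercase metabolite ids with a ``_c``/``_e`` compartment
suffix, reversibility encoded purely by ``lb < 0``).  This module adds the
workflow-specific plumbing around it:

* :func:`read_model` / :func:`write_model` — SBML Level 3 and the community
  constraint-based JSON dialect, with invariant checks on read;
* :func:`extend_model` — append heterologous reactions declared in a
  tab-separated :class:`PathwayExtension` table, auto-creating metabolites;
* :func:`apply_gene_map` — rewrite gene ids in gene rules from an ortholog
  mapping table filtered by match score;
* :func:`validate_model` — per-reaction elemental balance report (a
  lightweight stand-in for a full model QC suite).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import cobra
import cobra.io
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .errors import ConflictError, FormatError, ModelValidationError

__all__ = [
    "PathwayExtension",
    "GeneIdMap",
    "ValidationReport",
    "parse_stoichiometry",
    "read_model",
    "write_model",
    "extend_model",
    "apply_gene_map",
    "validate_model",
]

_ARROWS = ("<=>", "<->", "=>", "->")

EXTENSION_COLUMNS = [
    "reaction_id",
    "name",
    "stoichiometry",
    "lb",
    "ub",
    "gene_rule",
    "new_metabolites",
    "replace",
    "notes",
]


def parse_stoichiometry(expr: str) -> dict[str, float]:
    """Parse an ``aA + bB -> cC`` (or ``<=>``) string into {met_id: coeff}.

    Coefficients may be integers, decimals or rationals (``1/2``); omitted
    coefficients default to 1.  Negative coefficients mark consumption.
    One side may be empty (exchange / sink reactions).
    """
    expr = expr.strip()
    arrow = next((a for a in _ARROWS if a in expr), None)
    if arrow is None:
        raise FormatError(f"no reaction arrow in stoichiometry string: {expr!r}")
    left, right = expr.split(arrow, 1)
    stoich: dict[str, float] = {}

    def _add(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise FormatError(f"empty term in stoichiometry string: {expr!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(Fraction(parts[0]))
                except (ValueError, ZeroDivisionError) as exc:
                    raise FormatError(f"bad coefficient {parts[0]!r} in {expr!r}") from exc
                met = parts[1]
            else:
                raise FormatError(f"cannot parse term {term!r} in {expr!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    _add(left, -1)
    _add(right, +1)
    if not stoich:
        raise FormatError(f"stoichiometry string declares no metabolites: {expr!r}")
    return stoich


@dataclass
class PathwayExtension:
    """Rows of heterologous reactions to graft onto a model.

    ``frame`` columns: reaction_id, name, stoichiometry (string grammar of
    :func:`parse_stoichiometry`), lb, ub, gene_rule, new_metabolites
    (optional ``id=FORMULA`` pairs separated by ``;`` declaring elemental
    formulas for metabolites the extension introduces), replace (bool),
    notes (free-text provenance).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in EXTENSION_COLUMNS:
            if col not in self.frame.columns:
                default: object = "" if col != "replace" else False
                if col in ("lb", "ub"):
                    raise FormatError(f"extension table missing column {col!r}")
                self.frame[col] = default
        self.frame = self.frame[EXTENSION_COLUMNS].copy()
        self.frame["replace"] = self.frame["replace"].map(
            lambda x: str(x).strip().lower() in ("true", "1", "yes")
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayExtension":
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        frame["lb"] = frame["lb"].astype(float)
        frame["ub"] = frame["ub"].astype(float)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def concat(self, other: "PathwayExtension") -> "PathwayExtension":
        return PathwayExtension(
            pd.concat([self.frame, other.frame], ignore_index=True)
        )


@dataclass
class GeneIdMap:
    """Template-gene -> target-gene mapping with a numeric match score.

    The score plays the role of an alignment E-value: rows with
    ``score >= threshold`` are discarded before application.  After
    filtering, one target per template id is kept (best = lowest score).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"template_id", "target_id", "score"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"gene map missing columns: {sorted(missing)}")
        self.frame = self.frame.copy()
        self.frame["score"] = self.frame["score"].astype(float)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneIdMap":
        return cls(pd.read_csv(path, sep="\t"))

    def filtered(self, threshold: float = 1e-5) -> dict[str, str]:
        keep = self.frame[self.frame["score"] < threshold]
        keep = keep.sort_values("score").drop_duplicates("template_id", keep="first")
        return dict(zip(keep["template_id"], keep["target_id"]))


@dataclass
class ValidationReport:
    """Elemental-imbalance report; an empty ``imbalances`` list is a pass."""

    imbalances: list[tuple[str, dict[str, float]]]
    skipped: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.imbalances

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction": rid, "imbalance": ";".join(f"{k}:{v:g}" for k, v in imb.items())}
            for rid, imb in self.imbalances
        ]
        return pd.DataFrame(rows, columns=["reaction", "imbalance"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_invariants(model: Model) -> None:
    seen: set[str] = set()
    for met in model.metabolites:
        if met.id in seen:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        seen.add(met.id)
        if not met.compartment:
            raise ModelValidationError(f"metabolite {met.id!r} has no compartment")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has lb {rxn.lower_bound} > ub {rxn.upper_bound}"
            )
        if not rxn.metabolites:
            raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")


def read_model(path: str | Path, format: str | None = None) -> Model:
    """Load a model from SBML (``.xml``) or constraint-based JSON (``.json``).

    Raises :class:`FormatError` on parse failure and
    :class:`ModelValidationError` when the parsed model violates the basic
    invariants (unique ids, lb <= ub, non-empty stoichiometry).
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    try:
        if fmt == "json":
            model = cobra.io.load_json_model(str(path))
        elif fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise FormatError(f"unknown model format {fmt!r}")
    except FileNotFoundError:
        raise
    except (ModelValidationError, FormatError):
        raise
    except ValueError as exc:
        # cobra enforces lb <= ub at construction time
        if "bound" in str(exc):
            raise ModelValidationError(str(exc)) from exc
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    except Exception as exc:  # cobra raises a mix of IO/parse exceptions
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    _check_invariants(model)
    return model


def write_model(model: Model, path: str | Path, format: str | None = None) -> None:
    """Write ``model`` to SBML or JSON; the file re-reads to an equal model."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    if fmt == "json":
        cobra.io.save_json_model(model, str(path))
    elif fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise FormatError(f"unknown model format {fmt!r}")


def _compartment_from_id(met_id: str) -> str:
    if "_" in met_id:
        return met_id.rsplit("_", 1)[1]
    return "c"


def extend_model(model: Model, extension: PathwayExtension) -> Model:
    """Return a copy of ``model`` with the extension's reactions appended.

    Metabolites referenced but not present are created with the compartment
    read off their id suffix; elemental formulas for new metabolites may be
    declared in the ``new_metabolites`` column.  Re-declaring an existing
    reaction id without the replace flag raises :class:`ConflictError`.
    """
    out = model.copy()
    for row in extension.frame.itertuples(index=False):
        rid = row.reaction_id
        if rid in out.reactions:
            if not row.replace:
                raise ConflictError(
                    f"extension re-declares reaction {rid!r} without replace flag"
                )
            out.remove_reactions([out.reactions.get_by_id(rid)])
        formulas: dict[str, str] = {}
        if row.new_metabolites:
            for pair in str(row.new_metabolites).split(";"):
                pair = pair.strip()
                if not pair:
                    continue
                mid, _, formula = pair.partition("=")
                formulas[mid.strip()] = formula.strip()
        stoich = parse_stoichiometry(row.stoichiometry)
        if float(row.lb) > float(row.ub):
            raise ModelValidationError(
                f"extension row {rid!r} has lb {row.lb} > ub {row.ub}"
            )
        rxn = Reaction(rid, name=row.name or rid,
                       lower_bound=float(row.lb), upper_bound=float(row.ub))
        mets: dict[Metabolite, float] = {}
        for mid, coeff in stoich.items():
            if mid in out.metabolites:
                met = out.metabolites.get_by_id(mid)
            else:
                met = Metabolite(
                    mid,
                    compartment=_compartment_from_id(mid),
                    formula=formulas.get(mid) or None,
                )
            mets[met] = coeff
        rxn.add_metabolites(mets)
        if row.gene_rule:
            rxn.gene_reaction_rule = str(row.gene_rule)
        out.add_reactions([rxn])
    return out


_GENE_TOKEN = re.compile(r"\b[\w.\-]+\b")


def apply_gene_map(
    model: Model, gene_map: GeneIdMap, score_threshold: float = 1e-5
) -> tuple[Model, pd.DataFrame]:
    """Rewrite gene ids inside gene rules using a filtered ortholog map.

    Returns the rewritten model copy and a report frame with one row per
    gene id encountered in the rules, its mapped id (or itself), and a
    ``mapped`` flag.  Unmapped ids are retained verbatim — a warning-level
    outcome, never an error.
    """
    mapping = gene_map.filtered(score_threshold)
    out = model.copy()
    seen: dict[str, bool] = {}

    def _sub(match: re.Match[str]) -> str:
        token = match.group(0)
        if token in ("and", "or", "AND", "OR"):
            return token
        seen[token] = token in mapping
        return mapping.get(token, token)

    for rxn in out.reactions:
        rule = rxn.gene_reaction_rule
        if rule:
            rxn.gene_reaction_rule = _GENE_TOKEN.sub(_sub, rule)
    report = pd.DataFrame(
        [
            {"gene_id": g, "mapped": m, "target_id": mapping.get(g, g)}
            for g, m in sorted(seen.items())
        ],
        columns=["gene_id", "mapped", "target_id"],
    )
    return out, report


def validate_model(
    model: Model,
    biomass_ids: tuple[str, ...] = (),
    atol: float = 1e-9,
) -> ValidationReport:
    """Per-reaction elemental balance check.

    Exchange (boundary) reactions and biomass pseudo-reactions are skipped,
    as are reactions involving a metabolite without a declared formula
    (listed under ``skipped``).  Every other reaction is checked element by
    element; a non-empty report means the model is not mass balanced.
    """
    imbalances: list[tuple[str, dict[str, float]]] = []
    skipped: list[str] = []
    for rxn in model.reactions:
        if rxn.boundary:
            continue
        if rxn.id in biomass_ids or rxn.id.upper().startswith("BIOMASS"):
            continue
        if any(not met.formula for met in rxn.metabolites):
            skipped.append(rxn.id)
            continue
        balance = rxn.check_mass_balance()
        balance = {
            elem: val for elem, val in balance.items()
            if isinstance(val, (int, float)) and not math.isclose(val, 0.0, abs_tol=atol)
        }
        if balance:
            imbalances.append((rxn.id, balance))
    return ValidationReport(imbalances=imbalances, skipped=skipped)
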