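"""Branch-point screening of competing precursor consumers.

Two views of the competition for a shared substrate (DMAPP in the
chrysanthemate system):

* **capacity ranking** — each consumer's expression-scaled Vmax
  (kcat·3600·θ·TPM); enzymes catalyzing several reactions (the ispA-like
  prenyltransferase pair) are aggregated by summing their reactions' Vmax;
* **catalytic-rate proportions (PRate)** — the Michaelis–Menten rate share
  of each competing enzyme at substrate concentration [s],

  ``PRate_j([s]) = (kcat_j / (Km_j + [s])) / Σ_i kcat_i / (Km_i + [s])``,

  evaluated over a logarithmic [s] grid.  As [s] → 0 the shares converge
  to kcat/Km (catalytic-efficiency) proportions, as [s] → ∞ to kcat
  proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cobra import Model

from .constraints import (
    DEFAULT_THETA,
    KineticsRecord,
    lookup_tpm,
    vmax_bound,
    ExpressionRecord,
)
from .errors import ConfigurationError, ParameterError

__all__ = ["BranchReport", "prate", "rank_branches", "substrate_consumers",
           "DEFAULT_S_GRID"]

#: Default substrate-concentration grid: 1e-3 .. 1e2 mM, 6 log-spaced points.
DEFAULT_S_GRID = tuple(np.logspace(-3, 2, 6))


def prate(kinetics: Sequence[KineticsRecord], s: float) -> np.ndarray:
    """Catalytic-rate proportions of competing enzymes at [s] (mM).

    Component i is ``(kcat_i/(Km_i+s)) / Σ_j kcat_j/(Km_j+s)``; the vector
    sums to 1.
    """
    if len(kinetics) == 0:
        raise ParameterError("prate requires at least one kinetics record")
    if s < 0:
        raise ParameterError(f"substrate concentration must be >= 0, got {s}")
    rates = np.array([k.kcat / (k.km + s) for k in kinetics], dtype=float)
    return rates / rates.sum()


def substrate_consumers(model: Model, substrate: str) -> list[str]:
    """Reactions able to drain ``substrate`` (forward with negative
    coefficient, or reverse with positive coefficient), excluding exchanges."""
    if substrate not in model.metabolites:
        raise ConfigurationError(f"metabolite {substrate!r} not in model")
    met = model.metabolites.get_by_id(substrate)
    out = []
    for rxn in met.reactions:
        if rxn.boundary:
            continue
        coeff = rxn.metabolites[met]
        if (coeff < 0 and rxn.upper_bound > 0) or (coeff > 0 and rxn.lower_bound < 0):
            out.append(rxn.id)
    return sorted(out)


@dataclass
class BranchReport:
    """Per-consumer capacities and rate shares for one substrate.

    ``frame`` has one row per known consumer reaction: reaction, gene,
    vmax (mmol/gDW/hr), gene_vmax (summed over the gene's reactions), rank
    (1 = largest gene_vmax; ties broken by lexicographic reaction id) and
    one ``prate@<s>`` column per grid point.  Consumers marked unknown are
    excluded from the PRate normalization and listed separately.
    """

    substrate: str
    frame: pd.DataFrame
    s_grid: tuple[float, ...]
    unknown: list[str] = field(default_factory=list)
    theta: float = DEFAULT_THETA
    condition: str = "baseline"

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def top_reaction(self) -> str:
        return str(self.frame.loc[self.frame["rank"] == 1, "reaction"].iloc[0])

    @property
    def top_gene(self) -> str:
        return str(self.frame.loc[self.frame["rank"] == 1, "gene"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "substrate": self.substrate,
                    "top_gene": self.top_gene,
                    "top_reaction": self.top_reaction,
                    "n_consumers": self.n,
                    "unknown": self.unknown,
                    "s_grid_mM": list(self.s_grid),
                    "theta": self.theta,
                    "condition": self.condition,
                },
                indent=2,
            )
        )


def rank_branches(
    model: Model,
    substrate: str,
    kinetics: pd.DataFrame,
    expression: pd.DataFrame,
    condition: str = "baseline",
    theta: float = DEFAULT_THETA,
    s_grid: Sequence[float] | None = None,
    unknown: Sequence[str] = (),
) -> BranchReport:
    """Rank every consumer of ``substrate`` by expression-scaled Vmax.

    Every consumer must either have a kinetics row (matched on reaction id)
    or be listed in ``unknown``; unknown consumers are reported but take no
    part in ranking or PRate normalization.
    """
    s_grid = tuple(s_grid) if s_grid is not None else DEFAULT_S_GRID
    consumers = substrate_consumers(model, substrate)
    kin_by_rxn = {row.reaction: row for row in kinetics.itertuples(index=False)}
    missing = [r for r in consumers if r not in kin_by_rxn and r not in set(unknown)]
    if missing:
        raise ConfigurationError(
            f"consumers of {substrate!r} lack kinetics rows and are not marked "
            f"unknown: {missing}"
        )
    known = [r for r in consumers if r in kin_by_rxn]
    records: list[KineticsRecord] = []
    rows = []
    gene_vmax: dict[str, float] = {}
    # gene-level capacity aggregates every reaction of the gene present in
    # the kinetics table, not only the substrate-consuming ones
    for row in kinetics.itertuples(index=False):
        tpm = lookup_tpm(expression, row.gene, condition)
        spec = vmax_bound(
            KineticsRecord(row.gene, row.reaction, float(row.kcat_per_s),
                           float(row.Km_mM)),
            ExpressionRecord(row.gene, condition, tpm),
            theta,
        )
        gene_vmax[row.gene] = gene_vmax.get(row.gene, 0.0) + spec.vmax

    for rid in known:
        kin_row = kin_by_rxn[rid]
        rec = KineticsRecord(kin_row.gene, rid, float(kin_row.kcat_per_s),
                             float(kin_row.Km_mM))
        records.append(rec)
        tpm = lookup_tpm(expression, rec.gene, condition)
        spec = vmax_bound(rec, ExpressionRecord(rec.gene, condition, tpm), theta)
        rows.append(
            {"reaction": rid, "gene": rec.gene, "vmax": spec.vmax,
             "gene_vmax": gene_vmax[rec.gene]}
        )
    frame = pd.DataFrame(rows, columns=["reaction", "gene", "vmax", "gene_vmax"])
    if frame.empty:
        raise ConfigurationError(f"no known consumers of {substrate!r}")
    order = frame.sort_values(
        ["gene_vmax", "reaction"], ascending=[False, True], kind="stable"
    ).index
    ranks = pd.Series(range(1, len(frame) + 1), index=order)
    frame["rank"] = ranks
    for s in s_grid:
        frame[f"prate@{s:g}"] = prate(records, float(s))
    frame = frame.sort_values("rank").reset_index(drop=True)
    return BranchReport(
        substrate=substrate, frame=frame, s_grid=s_grid,
        unknown=sorted(set(unknown) & set(consumers)), theta=theta,
        condition=condition,
    )
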