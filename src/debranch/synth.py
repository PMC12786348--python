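"""Synthetic toy network with known ground truth.

The generator emulates, at desk scale, an engineered *E. coli* chassis for
chrysanthemic-acid production: glucose uptake, a lumped central carbon
core, the native MEP route and a heterologous MVA route to the C5 prenyl
pool (IPP/DMAPP), competing DMAPP consumers — an ispA-like
prenyltransferase pair (DMATT: DMAPP+IPP→GPP, GRTT: GPP+IPP→FPP), a
phosphatase shunt to DMAP, and the chrysanthemol route (CDS + a Nudix
hydrolase) — followed by the two dehydrogenase steps to the acid, with
exchange reactions for every secreted byproduct.

Bookkeeping elemental formulas of the form ``(CH2O)_n`` track carbon-unit
conservation exactly, so every internal reaction passes the elemental
balance check without carrying cofactors.  The biomass pseudo-reaction
drains acetyl-CoA and the GRTT product (FPP), which makes a full knockout
of the ispA-like pair lethal while graded knockdown stays viable — the
essentiality structure the knockdown simulations rely on.

Ground truth (kinetics, expression, the planted dominant consumer) is
recorded alongside the model; the kinetics/expression table generators
apply seeded multiplicative log-normal noise around the true values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .constraints import DEFAULT_THETA, SECONDS_PER_HOUR
from .core import PathwayExtension, extend_model
from .errors import GenerationError, ParameterError

__all__ = [
    "ToySpec",
    "GroundTruth",
    "make_toy_model",
    "make_wild_type",
    "mva_pathway_extension",
    "chrysanthemol_pathway_extension",
    "acid_pathway_extension",
    "make_kinetics_table",
    "make_expression_table",
    "TOY_CS5_ALIASES",
]

BIG = 1000.0

#: Alias map re-pointing the reference-strain preset at the toy's ids.
TOY_CS5_ALIASES = {
    "biomass": "BIOMASS_toy",
    # both precursor routes, two lumped steps each: the DMAPP pool's
    # supply-pathway flux (its "initial production rate").
    "supply_routes": "DXS_L,CDPMEK,HMGS_L,DPMVD",
}


@dataclass(frozen=True)
class ToySpec:
    """Generator settings; the defaults are the study conditions.

    ``dominance`` is the ratio of the planted dominant consumer's kcat·TPM
    capacity to the largest competing consumer; ``biomass_fpp_quota`` is
    the stoichiometric FPP demand per unit biomass flux (makes branch
    knockout lethal); ``adh_vmax``/``aldh_vmax`` are the dehydrogenase
    capacities (mmol/gDW/hr) implied by the true kinetics and expression
    at ``theta``, with the aldehyde step the binding one.
    """

    seed: int = 0
    dominance: float = 5.0
    delta: float = 0.4
    biomass_fpp_quota: float = 0.1
    biomass_accoa_quota: float = 2.0
    glucose_uptake: float = 20.0
    adh_vmax: float = 2.0
    aldh_vmax: float = 0.5
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if self.dominance < 1:
            raise ParameterError("dominance factor must be >= 1")
        if self.biomass_fpp_quota <= 0:
            raise ParameterError("biomass FPP quota must be > 0")


@dataclass
class GroundTruth:
    """True parameters planted by the generator."""

    theta: float
    kcat: dict[str, float]  # gene -> 1/s
    km: dict[str, float]  # gene -> mM
    tpm: dict[str, float]  # gene -> baseline TPM
    gene_reactions: dict[str, list[str]]
    dominant_gene: str
    dominant_reactions: list[str]
    substrate: str = "dmapp_c"
    consumers: list[str] = field(default_factory=list)
    supply_routes: list[str] = field(default_factory=list)
    product_secretion: str = "EX_CS_OH"
    acid_secretion: str = "EX_CS_acid"
    biomass: str = "BIOMASS_toy"
    knockdown_targets: list[str] = field(default_factory=lambda: ["DMATT", "GRTT"])
    f1: str = "ADH2"
    f2: str = "ALDH1"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# -- network definition -----------------------------------------------------

def _unit_formula(n: int) -> str:
    return f"C{n}H{2 * n}O{n}"


_METS = {
    # id: carbon units
    "glc__D_e": 6, "glc__D_c": 6, "pyr_c": 3, "g3p_c": 3, "accoa_c": 2,
    "waste_c": 1, "dxp_c": 5, "ipp_c": 5, "dmapp_c": 5, "gpp_c": 10,
    "fpp_c": 15, "dmap_c": 5, "ger_c": 10, "far_c": 15,
}

# wild-type reactions: (id, name, stoichiometry, lb, ub, gene rule)
_WT_REACTIONS = [
    ("EX_glc__D_e", "glucose exchange", "glc__D_e <=>", -BIG, BIG, ""),
    ("GLCt", "glucose transport", "glc__D_e -> glc__D_c", 0, BIG, "ptsG"),
    ("GLYC", "lumped glycolysis", "glc__D_c -> 2 pyr_c", 0, BIG, "pfkA and fbaA"),
    ("TPI", "triose shuttle", "pyr_c <=> g3p_c", -BIG, BIG, "tpiA"),
    ("PDH", "lumped pyruvate dehydrogenase", "pyr_c -> accoa_c + waste_c",
     0, BIG, "aceE"),
    ("DXS_L", "lumped MEP upper route", "pyr_c + g3p_c -> dxp_c + waste_c",
     0, BIG, "dxs"),
    ("CDPMEK", "lumped MEP lower route", "dxp_c -> dmapp_c", 0, BIG, "ispE"),
    ("IDI", "isopentenyl diphosphate isomerase", "dmapp_c -> ipp_c", 0, BIG, "idi"),
    ("DMATT", "dimethylallyl transferase", "dmapp_c + ipp_c -> gpp_c",
     0, BIG, "ispA"),
    ("GRTT", "geranyl transferase", "gpp_c + ipp_c -> fpp_c", 0, BIG, "ispA"),
    ("NUDX_DMAP", "DMAPP phosphatase shunt", "dmapp_c -> dmap_c", 0, BIG, "nudB"),
    ("GOH", "geraniol shunt", "gpp_c -> ger_c", 0, BIG, ""),
    ("FOH", "farnesol shunt", "fpp_c -> far_c", 0, BIG, ""),
    ("EX_waste", "carbon overflow sink", "waste_c ->", 0, BIG, ""),
    ("EX_DMAP", "DMAP secretion", "dmap_c ->", 0, BIG, ""),
    ("EX_ger", "geraniol secretion", "ger_c ->", 0, BIG, ""),
    ("EX_far", "farnesol secretion", "far_c ->", 0, BIG, ""),
]


def make_wild_type(spec: ToySpec | None = None) -> Model:
    """Toy analogue of the unengineered host: MEP route only, no product."""
    spec = spec or ToySpec()
    model = Model("toy_wt")
    mets = {
        mid: Metabolite(mid, name=mid, formula=_unit_formula(n),
                        compartment=mid.rsplit("_", 1)[1])
        for mid, n in _METS.items()
    }
    from .core import parse_stoichiometry

    for rid, name, stoich, lb, ub, rule in _WT_REACTIONS:
        rxn = Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites(
            {mets[m]: c for m, c in parse_stoichiometry(stoich).items()}
        )
        if rule:
            rxn.gene_reaction_rule = rule
        model.add_reactions([rxn])
    biomass = Reaction("BIOMASS_toy", name="biomass pseudo-reaction",
                       lower_bound=0, upper_bound=BIG)
    biomass.add_metabolites(
        {
            mets["accoa_c"]: -spec.biomass_accoa_quota,
            mets["fpp_c"]: -spec.biomass_fpp_quota,
        }
    )
    model.add_reactions([biomass])
    model.reactions.EX_glc__D_e.lower_bound = -spec.glucose_uptake
    model.objective = "BIOMASS_toy"
    return model


def mva_pathway_extension() -> PathwayExtension:
    """Heterologous mevalonate route: acetyl-CoA -> MVA -> DMAPP (lumped)."""
    return PathwayExtension(
        pd.DataFrame(
            [
                {
                    "reaction_id": "HMGS_L", "name": "lumped MVA upper route",
                    "stoichiometry": "3 accoa_c -> mva_c", "lb": 0.0, "ub": BIG,
                    "gene_rule": "mvaS", "new_metabolites": "mva_c=C6H12O6",
                    "notes": "heterologous MVA pathway, upper lump",
                },
                {
                    "reaction_id": "DPMVD", "name": "lumped MVA lower route",
                    "stoichiometry": "mva_c -> dmapp_c + waste_c",
                    "lb": 0.0, "ub": BIG, "gene_rule": "mvaD",
                    "new_metabolites": "",
                    "notes": "heterologous MVA pathway, decarboxylase lump",
                },
            ]
        )
    )


def chrysanthemol_pathway_extension() -> PathwayExtension:
    """CDS condensation of two DMAPP + Nudix hydrolysis to chrysanthemol."""
    return PathwayExtension(
        pd.DataFrame(
            [
                {
                    "reaction_id": "CDS", "name": "chrysanthemyl diphosphate synthase",
                    "stoichiometry": "2 dmapp_c -> cdp_chr_c", "lb": 0.0, "ub": BIG,
                    "gene_rule": "cds", "new_metabolites": "cdp_chr_c=C10H20O10",
                    "notes": "head-to-middle condensation of two DMAPP units",
                },
                {
                    "reaction_id": "NUDX1", "name": "chrysanthemyl diphosphate hydrolase",
                    "stoichiometry": "cdp_chr_c -> crtol_c", "lb": 0.0, "ub": BIG,
                    "gene_rule": "nudix1", "new_metabolites": "crtol_c=C10H20O10",
                    "notes": "Nudix hydrolase to chrysanthemol",
                },
                {
                    "reaction_id": "EX_CS_OH", "name": "chrysanthemol secretion",
                    "stoichiometry": "crtol_c ->", "lb": 0.0, "ub": BIG,
                    "gene_rule": "", "new_metabolites": "",
                    "notes": "product exchange",
                },
            ]
        )
    )


def acid_pathway_extension() -> PathwayExtension:
    """Dehydrogenase tail: chrysanthemol -> chrysanthemal -> chrysanthemic acid."""
    return PathwayExtension(
        pd.DataFrame(
            [
                {
                    "reaction_id": "ADH2", "name": "alcohol dehydrogenase step",
                    "stoichiometry": "crtol_c -> crtal_c", "lb": 0.0, "ub": BIG,
                    "gene_rule": "adh2", "new_metabolites": "crtal_c=C10H20O10",
                    "notes": "oxidation to chrysanthemal",
                },
                {
                    "reaction_id": "ALDH1", "name": "aldehyde dehydrogenase step",
                    "stoichiometry": "crtal_c -> crta_c", "lb": 0.0, "ub": BIG,
                    "gene_rule": "aldh1", "new_metabolites": "crta_c=C10H20O10",
                    "notes": "oxidation to chrysanthemic acid",
                },
                {
                    "reaction_id": "EX_CS_acid", "name": "chrysanthemic acid secretion",
                    "stoichiometry": "crta_c ->", "lb": 0.0, "ub": BIG,
                    "gene_rule": "", "new_metabolites": "",
                    "notes": "product exchange",
                },
            ]
        )
    )


def _ground_truth(spec: ToySpec) -> GroundTruth:
    kcat = {
        "ispA": 30.0, "idi": 4.0, "cds": 5.0, "nudB": 2.0,
        "nudix1": 5.0, "adh2": 1.0, "aldh1": 0.5,
    }
    km = {
        "ispA": 0.05, "idi": 0.2, "cds": 0.1, "nudB": 1.0,
        "nudix1": 0.2, "adh2": 0.3, "aldh1": 0.4,
    }
    tpm = {"idi": 250.0, "cds": 300.0, "nudB": 200.0, "nudix1": 300.0}
    # plant the dominant consumer: kcat*TPM = dominance x the best competitor
    best_other = max(kcat[g] * tpm[g] for g in ("idi", "cds", "nudB"))
    tpm["ispA"] = spec.dominance * best_other / kcat["ispA"]
    # dehydrogenase expression back-solved from the declared capacities
    tpm["adh2"] = spec.adh_vmax / (kcat["adh2"] * SECONDS_PER_HOUR * spec.theta)
    tpm["aldh1"] = spec.aldh_vmax / (kcat["aldh1"] * SECONDS_PER_HOUR * spec.theta)
    return GroundTruth(
        theta=spec.theta,
        kcat=kcat,
        km=km,
        tpm=tpm,
        gene_reactions={
            "ispA": ["DMATT", "GRTT"], "idi": ["IDI"], "cds": ["CDS"],
            "nudB": ["NUDX_DMAP"], "nudix1": ["NUDX1"],
            "adh2": ["ADH2"], "aldh1": ["ALDH1"],
        },
        dominant_gene="ispA",
        dominant_reactions=["DMATT", "GRTT"],
        consumers=["CDS", "DMATT", "IDI", "NUDX_DMAP"],
        supply_routes=["DXS_L", "CDPMEK", "HMGS_L", "DPMVD"],
    )


def make_toy_model(spec: ToySpec | None = None) -> tuple[Model, GroundTruth]:
    """Full engineered toy (MVA + chrysanthemol + acid modules) + ground truth.

    Built by extending the wild-type model with the three pathway-extension
    tables, exactly as a user model would be.  Raises
    :class:`GenerationError` if the generated model is infeasible or fails
    the elemental balance check — never returns a broken fixture silently.
    """
    spec = spec or ToySpec()
    model = make_wild_type(spec)
    for ext in (
        mva_pathway_extension(),
        chrysanthemol_pathway_extension(),
        acid_pathway_extension(),
    ):
        model = extend_model(model, ext)
    model.id = "toy_cs"
    model.objective = "BIOMASS_toy"
    gt = _ground_truth(spec)

    from .core import validate_model

    report = validate_model(model)
    if not report.passed:
        raise GenerationError(f"toy model is not mass balanced: {report.imbalances}")
    growth = model.slim_optimize()
    if growth is None or not growth > 1e-6:
        raise GenerationError("toy model infeasible or zero biomass at defaults")
    return model, gt


# -- tables -----------------------------------------------------------------

def make_kinetics_table(
    model: Model,
    ground_truth: GroundTruth,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Kinetics table (gene, reaction, kcat_per_s, Km_mM, source).

    Multiplicative log-normal noise ``exp(N(0, noise_sd))`` around the true
    kcat and Km, independently per row and parameter; ``noise_sd=0``
    reproduces the planted values exactly.
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(ground_truth.kcat):
        for rxn in ground_truth.gene_reactions[gene]:
            if rxn not in model.reactions:
                continue
            kcat = ground_truth.kcat[gene] * float(np.exp(rng.normal(0, noise_sd)))
            km = ground_truth.km[gene] * float(np.exp(rng.normal(0, noise_sd)))
            rows.append(
                {
                    "gene": gene, "reaction": rxn,
                    "kcat_per_s": kcat, "Km_mM": km, "source": "predicted",
                }
            )
    return pd.DataFrame(rows, columns=["gene", "reaction", "kcat_per_s", "Km_mM", "source"])


def make_expression_table(
    ground_truth: GroundTruth,
    condition_effects: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression table (gene, condition, TPM).

    Always contains a ``baseline`` condition.  ``condition_effects`` maps
    extra condition names to per-gene positive multipliers (genes absent
    from a map keep multiplier 1.0) — e.g. an sRNA-silenced condition with
    multiplier 0.1223 on the ispA analogue emulates an 87.77% measured
    knockdown.  TPM = true x exp(N(0, noise_sd)) x effect, with the noise
    redrawn per condition.
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    effects = {"baseline": {}}
    for cond, mults in (condition_effects or {}).items():
        for gene, mult in mults.items():
            if mult <= 0:
                raise ParameterError(
                    f"condition effect for {gene!r} in {cond!r} must be > 0"
                )
        effects[cond] = dict(mults)
    rng = np.random.default_rng(seed)
    rows = []
    for cond in effects:
        for gene in sorted(ground_truth.tpm):
            noise = float(np.exp(rng.normal(0, noise_sd)))
            tpm = ground_truth.tpm[gene] * noise * effects[cond].get(gene, 1.0)
            rows.append({"gene": gene, "condition": cond, "TPM": tpm})
    return pd.DataFrame(rows, columns=["gene", "condition", "TPM"])
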