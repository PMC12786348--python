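"""End-to-end orchestration: config validation, staged runs, the demo.

A run is described by a YAML/dict config naming the input artifacts and
the stage parameters; :func:`run_pipeline` executes the requested stages
(validate → baseline → branch → knockdown → overexpress → compare) and
writes machine-readable TSV/JSON reports plus a manifest (package
versions, seeds, config hash, input digests) sufficient to re-run the
pipeline bit-identically.  :func:`demo` generates the synthetic fixtures
first and then runs the identical pipeline on them.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import cobra
import pandas as pd
import yaml

from . import __version__
from .branch import rank_branches
from .compare import flux_sum, fva_jaccard, sampling_volcano
from .constraints import (
    ConstraintSet,
    ExpressionRecord,
    KineticsRecord,
    cs5_preset,
    lookup_tpm,
    read_expression_table,
    read_kinetics_table,
    vmax_bound,
)
from .core import (
    GeneIdMap,
    PathwayExtension,
    apply_gene_map,
    extend_model,
    read_model,
    validate_model,
    write_model,
)
from .errors import ConfigurationError
from .lp import baseline_flux, fva, sample_fluxes
from .perturb import (
    DEFAULT_FACTORS,
    DEFAULT_N_GRID,
    rvmax_ratio,
    simulate_knockdown,
    sweep_overexpression,
    yield_improvement,
)
from .synth import (
    TOY_CS5_ALIASES,
    ToySpec,
    acid_pathway_extension,
    chrysanthemol_pathway_extension,
    make_expression_table,
    make_kinetics_table,
    make_toy_model,
    make_wild_type,
    mva_pathway_extension,
)

__all__ = ["validate_config", "run_pipeline", "demo", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("validate", "baseline", "branch", "knockdown", "overexpress",
                  "compare")


def validate_config(config: dict) -> None:
    """Schema check with field paths; raises before any compute."""
    errors: list[str] = []

    def need(path: str, ok: bool) -> None:
        if not ok:
            errors.append(path)

    need("model", isinstance(config.get("model"), str))
    for key in ("model", "kinetics", "expression", "gene_map", "constraints"):
        value = config.get(key)
        if isinstance(value, str) and not Path(value).exists():
            errors.append(f"{key}: path does not exist: {value}")
    for i, ext in enumerate(config.get("extensions", []) or []):
        if not Path(ext).exists():
            errors.append(f"extensions[{i}]: path does not exist: {ext}")
    preset = config.get("preset")
    if preset is not None and preset not in ("cs5",):
        errors.append(f"preset: unknown preset {preset!r}; available: ['cs5']")
    stages = config.get("stages", list(DEFAULT_STAGES))
    for i, stage in enumerate(stages):
        if stage not in DEFAULT_STAGES:
            errors.append(f"stages[{i}]: unknown stage {stage!r}")
    sampler = config.get("sampler", {})
    if not isinstance(sampler.get("seed", 0), int):
        errors.append("sampler.seed: must be an integer")
    if errors:
        raise ConfigurationError("invalid config: " + "; ".join(errors))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", DEFAULT_STAGES))
    aliases = config.get("aliases") or {}
    condition = config.get("condition", "baseline")
    theta = float(config.get("theta", 1e-5))

    model = read_model(config["model"])
    for ext_path in config.get("extensions", []) or []:
        model = extend_model(model, PathwayExtension.from_tsv(ext_path))
    if config.get("gene_map"):
        model, gene_report = apply_gene_map(model, GeneIdMap.from_tsv(config["gene_map"]))
        gene_report.to_csv(outdir / "gene_map_report.tsv", sep="\t", index=False)
    write_model(model, outdir / "model_final.json")

    kinetics = read_kinetics_table(config["kinetics"]) if config.get("kinetics") else None
    expression = (
        read_expression_table(config["expression"]) if config.get("expression") else None
    )

    cset = ConstraintSet()
    if config.get("preset") == "cs5":
        cset = cs5_preset(model, aliases=aliases)
    elif config.get("constraints"):
        cset = ConstraintSet.from_yaml(config["constraints"])
    cset.to_yaml(outdir / "constraints.yaml")

    biomass = aliases.get("biomass", config.get("biomass", "BIOMASS_toy"))
    product = config.get("product_secretion", "EX_CS_OH")
    substrate = config.get("substrate", "dmapp_c")

    if "validate" in stages:
        validate_model(model).to_tsv(outdir / "validation.tsv")

    base_state = None
    if "baseline" in stages:
        base_state = baseline_flux(model, cset, objective=biomass)
        base_state.to_tsv(outdir / "baseline_flux.tsv")

    if "branch" in stages:
        if kinetics is None or expression is None:
            raise ConfigurationError("branch stage needs kinetics and expression tables")
        report = rank_branches(
            model, substrate, kinetics, expression, condition=condition, theta=theta
        )
        report.to_tsv(outdir / "branch_report.tsv")
        report.summary_json(outdir / "branch_summary.json")

    if "knockdown" in stages:
        kd_cfg = config.get("knockdown", {})
        curve = simulate_knockdown(
            model, cset,
            targets=kd_cfg.get("targets", ["DMATT", "GRTT"]),
            product_rxn=product, biomass_rxn=biomass,
            factors=kd_cfg.get("factors", list(DEFAULT_FACTORS)),
        )
        curve.to_tsv(outdir / "knockdown.tsv")
        yi = yield_improvement(curve)
        yi.to_csv(outdir / "yield_improvement.tsv", sep="\t", index=False)
        try:
            from .plots import plot_knockdown

            plot_knockdown(curve, outdir / "knockdown.png")
        except Exception:  # pragma: no cover - plotting is best-effort
            pass

    if "overexpress" in stages:
        ox = config.get("overexpression", {})
        f1, f2 = ox.get("f1", "ADH2"), ox.get("f2", "ALDH1")
        acid = ox.get("product", config.get("acid_secretion", "EX_CS_acid"))
        ox_cset = cset.copy()
        rvmax = None
        if kinetics is not None and expression is not None:
            recs = {r.reaction: r for r in (
                KineticsRecord(row.gene, row.reaction, float(row.kcat_per_s),
                               float(row.Km_mM))
                for row in kinetics.itertuples(index=False)
            )}
            if f1 in recs and f2 in recs:
                e1 = ExpressionRecord(recs[f1].gene, condition,
                                      lookup_tpm(expression, recs[f1].gene, condition))
                e2 = ExpressionRecord(recs[f2].gene, condition,
                                      lookup_tpm(expression, recs[f2].gene, condition))
                ox_cset = ox_cset.add_vmax(vmax_bound(recs[f1], e1, theta))
                ox_cset = ox_cset.add_vmax(vmax_bound(recs[f2], e2, theta))
                rvmax = rvmax_ratio(recs[f1], recs[f2], e1, e2)
        surface = sweep_overexpression(
            model, ox_cset, f1, f2, product_rxn=acid,
            n_grid=ox.get("n_grid", list(DEFAULT_N_GRID)), rvmax=rvmax,
        )
        surface.to_tsv(outdir / "overexpression.tsv")
        try:
            from .plots import plot_overexpression

            plot_overexpression(surface, outdir / "overexpression.png")
        except Exception:  # pragma: no cover
            pass

    if "compare" in stages:
        cmp_cfg = config.get("compare", {})
        other_path = cmp_cfg.get("model")
        if other_path:
            other = read_model(other_path)
            sampler = config.get("sampler", {})
            n = int(sampler.get("n", 500))
            seed = int(sampler.get("seed", 0))
            thinning = int(sampler.get("thinning", 100))
            fraction = float(cmp_cfg.get("fraction", 1.0))
            fva_a = fva(other, fraction_of_optimum=fraction)
            fva_b = fva(model, fraction_of_optimum=fraction)
            jac = fva_jaccard(fva_a, fva_b)
            jac.to_csv(outdir / "fva_jaccard.tsv", sep="\t", index=False)
            ens_a = sample_fluxes(other, n=n, seed=seed, thinning=thinning)
            ens_b = sample_fluxes(model, n=n, seed=seed + 1, thinning=thinning)
            volcano = sampling_volcano(ens_a, ens_b)
            volcano.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
            rows = []
            for met in cmp_cfg.get("metabolites", ["ger_c", "far_c"]):
                for label, mdl, ens in (("a", other, ens_a), ("b", model, ens_b)):
                    if met in mdl.metabolites:
                        phi = flux_sum(mdl, ens, met)
                        rows.append(
                            {"metabolite": met, "model": label,
                             "mean_flux_sum": float(phi.mean()),
                             "sd_flux_sum": float(phi.std())}
                        )
            pd.DataFrame(rows).to_csv(outdir / "flux_sums.tsv", sep="\t", index=False)

    manifest = {
        "debranch_version": __version__,
        "cobra_version": cobra.__version__,
        "python": platform.python_version(),
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": {
            key: _sha256(Path(config[key]))
            for key in ("model", "kinetics", "expression", "gene_map", "constraints")
            if isinstance(config.get(key), str)
        },
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def demo(outdir: str | Path, seed: int = 1) -> dict:
    """Self-contained demo: generate toy fixtures, run the full pipeline.

    Writes inputs under ``<outdir>/inputs`` and reports under
    ``<outdir>/reports``; on failure a FAILED marker file is left next to
    whatever partial outputs exist.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    reports = outdir / "reports"
    inputs.mkdir(parents=True, exist_ok=True)
    reports.mkdir(parents=True, exist_ok=True)
    try:
        spec = ToySpec(seed=seed)
        wt = make_wild_type(spec)
        write_model(wt, inputs / "toy_wt.json")
        _, gt = make_toy_model(spec)
        gt.to_json(inputs / "ground_truth.json")
        mva_pathway_extension().to_tsv(inputs / "ext_mva.tsv")
        chrysanthemol_pathway_extension().to_tsv(inputs / "ext_chrysanthemol.tsv")
        acid_pathway_extension().to_tsv(inputs / "ext_acid.tsv")
        make_kinetics_table(make_toy_model(spec)[0], gt, noise_sd=0.2,
                            seed=seed).to_csv(inputs / "kinetics.tsv", sep="\t",
                                              index=False)
        make_expression_table(
            gt, condition_effects={"ispA_silenced": {"ispA": 0.1223}},
            noise_sd=0.2, seed=seed,
        ).to_csv(inputs / "expression.tsv", sep="\t", index=False)

        config = {
            "model": str(inputs / "toy_wt.json"),
            "extensions": [
                str(inputs / "ext_mva.tsv"),
                str(inputs / "ext_chrysanthemol.tsv"),
                str(inputs / "ext_acid.tsv"),
            ],
            "kinetics": str(inputs / "kinetics.tsv"),
            "expression": str(inputs / "expression.tsv"),
            "preset": "cs5",
            "aliases": dict(TOY_CS5_ALIASES),
            "condition": "baseline",
            "substrate": "dmapp_c",
            "product_secretion": "EX_CS_OH",
            "acid_secretion": "EX_CS_acid",
            "knockdown": {"targets": ["DMATT", "GRTT"]},
            "overexpression": {"f1": "ADH2", "f2": "ALDH1"},
            "sampler": {"n": 200, "seed": seed, "thinning": 50},
            "compare": {"model": str(inputs / "toy_wt.json"),
                        "metabolites": ["ger_c", "far_c"]},
            "stages": list(DEFAULT_STAGES),
        }
        (inputs / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
        return run_pipeline(config, reports)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
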