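"""Comparative analytics between two constrained models.

* :func:`fva_jaccard` — per-reaction Jaccard index of FVA intervals,
  sorted ascending so the most-changed reactions come first;
* :func:`sampling_volcano` — differential-flux volcano from two sampling
  ensembles (rank-based two-sample test, log2 fold change of absolute
  sample means with an ε pseudo-flux);
* :func:`flux_sum` — production turnover of a metabolite,
  Φ = Σ_j max(S_ij·v_j, 0), per flux vector or per sample.

The volcano's p-values are descriptive (they scale with the sample count,
which is recorded in the result's attrs) and no multiplicity correction is
applied; the default thresholds p < 1e-8 and |log2FC| > 1 are the ones
drawn on the reference figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model
from scipy import stats

from .lp import FluxState, FvaResult, SamplingEnsemble

__all__ = [
    "ComparisonReport",
    "fva_jaccard",
    "interval_jaccard",
    "sampling_volcano",
    "flux_sum",
]

DEGENERATE_TOL = 1e-9


def interval_jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Jaccard index of two closed intervals under length measure.

    Two identical single points → 1; a single point inside an interval of
    positive length contributes intersection length 0 → 0.
    """
    (a1, a2), (b1, b2) = a, b
    len_a, len_b = a2 - a1, b2 - b1
    if len_a <= DEGENERATE_TOL and len_b <= DEGENERATE_TOL:
        return 1.0 if abs(a1 - b1) <= DEGENERATE_TOL else 0.0
    inter = max(0.0, min(a2, b2) - max(a1, b1))
    union = len_a + len_b - inter
    return inter / union if union > 0 else 0.0


def fva_jaccard(fva_a: FvaResult, fva_b: FvaResult) -> pd.DataFrame:
    """Sorted per-reaction Jaccard table over the shared reaction set.

    Ascending order: the most-changed reactions (smallest overlap) first.
    Reactions present in only one result are listed in the frame's attrs
    (``only_a`` / ``only_b``), not scored.
    """
    shared = fva_a.frame.index.intersection(fva_b.frame.index)
    rows = [
        {
            "reaction": rid,
            "jaccard": interval_jaccard(fva_a.interval(rid), fva_b.interval(rid)),
        }
        for rid in shared
    ]
    out = pd.DataFrame(rows, columns=["reaction", "jaccard"])
    out = out.sort_values(["jaccard", "reaction"], kind="stable").reset_index(drop=True)
    out.attrs["only_a"] = sorted(set(fva_a.frame.index) - set(shared))
    out.attrs["only_b"] = sorted(set(fva_b.frame.index) - set(shared))
    out.attrs["fraction_a"] = fva_a.fraction
    out.attrs["fraction_b"] = fva_b.fraction
    return out


def sampling_volcano(
    ensemble_a: SamplingEnsemble | pd.DataFrame,
    ensemble_b: SamplingEnsemble | pd.DataFrame,
    p_threshold: float = 1e-8,
    fc_threshold: float = 1.0,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Differential-flux volcano between two sampling ensembles.

    Per shared reaction: ``log2fc = log2((|mean_b|+ε)/(|mean_a|+ε))``, p
    from a two-sided Mann–Whitney rank test, and ``significant`` exactly
    when p < p_threshold and |log2fc| > fc_threshold.  Reactions whose mean
    flips sign between models are flagged ``sign_flip`` (ratio semantics
    break for them); zero-variance-in-both columns get p = 1 and a
    ``zero_variance`` flag.
    """
    a = ensemble_a.samples if isinstance(ensemble_a, SamplingEnsemble) else ensemble_a
    b = ensemble_b.samples if isinstance(ensemble_b, SamplingEnsemble) else ensemble_b
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each ensemble needs at least 2 samples")
    shared = [c for c in a.columns if c in set(b.columns)]
    rows = []
    for rid in shared:
        xa, xb = a[rid].to_numpy(float), b[rid].to_numpy(float)
        ma, mb = float(xa.mean()), float(xb.mean())
        log2fc = float(np.log2((abs(mb) + epsilon) / (abs(ma) + epsilon)))
        sign_flip = (abs(ma) > epsilon and abs(mb) > epsilon and np.sign(ma) != np.sign(mb))
        zero_var = float(xa.std()) == 0.0 and float(xb.std()) == 0.0
        if zero_var:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            if np.isnan(p):
                p, zero_var = 1.0, True
        rows.append(
            {
                "reaction": rid, "mean_a": ma, "mean_b": mb, "log2fc": log2fc,
                "p_value": p, "sign_flip": sign_flip, "zero_variance": zero_var,
                "significant": (p < p_threshold) and (abs(log2fc) > fc_threshold),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs.update(
        {
            "p_threshold": p_threshold, "fc_threshold": fc_threshold,
            "epsilon": epsilon, "test": "mann-whitney-u two-sided",
            "n_a": len(a), "n_b": len(b),
        }
    )
    return out


def flux_sum(
    model: Model,
    fluxes: FluxState | pd.Series | pd.DataFrame | SamplingEnsemble,
    metabolite: str,
):
    """Production flux-sum Φ = Σ_j max(S_ij·v_j, 0) of one metabolite.

    Accepts a single flux vector (returns a float) or a sampling ensemble /
    sample frame (returns a per-sample numpy array).  A metabolite with no
    producing terms yields 0 with a warning.
    """
    met = model.metabolites.get_by_id(metabolite)
    terms = [(rxn.id, coeff) for rxn, coeff in
             ((r, r.metabolites[met]) for r in met.reactions)]
    can_produce = any(
        (c > 0 and model.reactions.get_by_id(rid).upper_bound > 0)
        or (c < 0 and model.reactions.get_by_id(rid).lower_bound < 0)
        for rid, c in terms
    )
    if not can_produce:
        warnings.warn(f"metabolite {metabolite!r} has no producing terms; flux-sum 0")

    if isinstance(fluxes, FluxState):
        fluxes = fluxes.fluxes
    if isinstance(fluxes, SamplingEnsemble):
        fluxes = fluxes.samples
    if isinstance(fluxes, pd.Series):
        total = 0.0
        for rid, coeff in terms:
            if rid in fluxes.index:
                total += max(coeff * float(fluxes[rid]), 0.0)
        return total
    # DataFrame: one row per sample
    total = np.zeros(len(fluxes))
    for rid, coeff in terms:
        if rid in fluxes.columns:
            total += np.maximum(coeff * fluxes[rid].to_numpy(float), 0.0)
    return total


@dataclass
class ComparisonReport:
    """Bundle of the three comparison products for one model pair."""

    jaccard: pd.DataFrame
    volcano: pd.DataFrame
    flux_sums: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_tsv(self, jaccard_path, volcano_path) -> None:
        self.jaccard.to_csv(jaccard_path, sep="\t", index=False)
        self.volcano.to_csv(volcano_path, sep="\t", index=False)
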