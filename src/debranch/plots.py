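"""Optional plot outputs (SVG/PNG) for the simulation reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_knockdown", "plot_overexpression", "plot_volcano", "plot_jaccard"]


def plot_knockdown(curve, path: str | Path) -> None:
    frame = curve.frame.dropna(subset=["flux_product"])
    fig, ax1 = plt.subplots(figsize=(5, 3.5))
    ax1.semilogx(frame["factor"], frame["flux_product"], "o-", base=2,
                 color="tab:green", label="product secretion")
    ax1.set_xlabel("inhibition factor")
    ax1.set_ylabel("product flux (mmol/gDW/hr)", color="tab:green")
    ax2 = ax1.twinx()
    ax2.semilogx(frame["factor"], frame["flux_biomass"], "s--", base=2,
                 color="tab:blue", label="biomass")
    ax2.set_ylabel("biomass flux", color="tab:blue")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_overexpression(surface, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, frame in (
        (f"{surface.f1} only", surface.f1_only()),
        (f"{surface.f2} only", surface.f2_only()),
        ("joint", surface.joint()),
    ):
        n = frame[["n1", "n2"]].max(axis=1)
        ax.semilogx(n, frame["product_flux"], "o-", base=2, label=label)
    ax.set_xlabel("capacity scaling factor n")
    ax.set_ylabel("product flux (mmol/gDW/hr)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_volcano(volcano: pd.DataFrame, path: str | Path) -> None:
    p_thr = volcano.attrs.get("p_threshold", 1e-8)
    fc_thr = volcano.attrs.get("fc_threshold", 1.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    logp = -np.log10(np.maximum(volcano["p_value"], 1e-300))
    colors = np.where(volcano["significant"], "tab:red", "0.6")
    ax.scatter(volcano["log2fc"], logp, s=8, c=colors)
    ax.axhline(-np.log10(p_thr), ls="--", c="k", lw=0.8)
    ax.axvline(-fc_thr, ls="--", c="tab:green", lw=0.8)
    ax.axvline(fc_thr, ls="--", c="tab:olive", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p-value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_jaccard(jaccard: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(range(len(jaccard)), jaccard["jaccard"], ".-")
    ax.set_xlabel("reactions (sorted, most changed first)")
    ax.set_ylabel("FVA interval Jaccard index")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
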