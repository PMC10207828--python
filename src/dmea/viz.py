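"""Canonical figures: the all-MOA volcano plot, per-MOA mountain plots, and
simulation-grid heatmaps."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .datatypes import EnrichmentResult, RankedDrugList, ValidationError

__all__ = ["PlotSpec", "volcano_plot", "mountain_plot", "grid_heatmap"]


@dataclass(frozen=True)
class PlotSpec:
    """Where and how to render a figure."""

    output_path: Union[str, Path]
    format: str = "png"
    p_threshold: float = 0.05
    fdr_threshold: float = 0.25
    n_labels: int = 3
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.format not in {"png", "svg"}:
            raise ValidationError(f"unsupported figure format {self.format!r}")
        if self.p_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValidationError("significance thresholds must be positive")


def _save(fig, spec: PlotSpec) -> Path:
    path = Path(spec.output_path).with_suffix(f".{spec.format}")
    fig.savefig(path, dpi=spec.dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def volcano_plot(results: Iterable[EnrichmentResult], spec: PlotSpec) -> Path:
    """NES versus -log10(p) for every tested MOA; significant MOAs (p and
    FDR below their thresholds) are highlighted in red with text labels."""
    results = [r for r in results if np.isfinite(r.nes)]
    if not results:
        raise ValidationError("no result has a computable NES")
    nes = np.array([r.nes for r in results])
    logp = -np.log10([r.p_value for r in results])
    sig = np.array(
        [
            np.isfinite(r.q_value)
            and r.p_value < spec.p_threshold
            and r.q_value < spec.fdr_threshold
            for r in results
        ]
    )

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(nes[~sig], logp[~sig], s=18, c="grey", alpha=0.7)
    ax.scatter(nes[sig], logp[sig], s=24, c="red")
    for r, x, y, s in zip(results, nes, logp, sig):
        if s:
            ax.annotate(r.moa, (x, y), fontsize=8, color="red",
                        xytext=(3, 3), textcoords="offset points")
    ax.axhline(-np.log10(spec.p_threshold), ls="--", lw=0.8, c="black")
    ax.set_xlabel("NES")
    ax.set_ylabel("$-\\log_{10}(p)$")
    ax.set_title("MOA enrichment")
    return _save(fig, spec)


def mountain_plot(
    result: EnrichmentResult, rlist: RankedDrugList, spec: PlotSpec
) -> Path:
    """Running enrichment curve with member tick marks.

    The ``n_labels`` most extreme member drugs (top of the list for
    positive ES, bottom for negative) are annotated with their rank
    values.
    """
    n = len(rlist)
    if len(result.running_sum) != n:
        raise ValidationError("running_sum length does not match the ranked list")
    members = set(result.leading_edge) | _member_positions(result, rlist)
    positions = [i for i, d in enumerate(rlist.drugs) if d in members]

    fig, (ax, ticks) = plt.subplots(
        2, 1, figsize=(6, 4.5), sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.05},
    )
    ax.plot(np.arange(1, n + 1), result.running_sum, lw=1.2, color="tab:blue")
    ax.axhline(0.0, lw=0.6, color="grey")
    ax.set_ylabel("running enrichment score")
    ax.set_title(f"{result.moa}  (ES={result.es:.3f}, NES={result.nes:.3f})")

    ticks.vlines(np.array(positions) + 1, 0, 1, lw=0.6, color="black")
    ticks.set_yticks([])
    ticks.set_xlabel("rank in drug list")

    extreme = sorted(positions)[: spec.n_labels] if result.es >= 0 else sorted(positions)[-spec.n_labels:]
    for i in extreme:
        ax.annotate(
            f"{rlist.drugs[i]} ({rlist.ranks[i]:.3g})",
            (i + 1, result.running_sum[i]),
            fontsize=7,
            xytext=(4, 4),
            textcoords="offset points",
        )
    return _save(fig, spec)


def _member_positions(result: EnrichmentResult, rlist: RankedDrugList) -> set[str]:
    # tick marks cover all set members; reconstruct them from the running
    # sum: member positions are exactly the upward jumps
    inc = np.diff(np.concatenate([[0.0], result.running_sum]))
    return {rlist.drugs[i] for i in np.flatnonzero(inc > 0)}


def grid_heatmap(
    grid: pd.DataFrame,
    value: str,
    x: str,
    y: str,
    spec: PlotSpec,
    fmt: str = ".2g",
) -> Path:
    """Heatmap of one simulation-grid summary column (mean NES or percent
    significant) over the grid axes."""
    pivot = grid.pivot(index=y, columns=x, values=value).sort_index(ascending=False)
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2, 0.6 * len(pivot) + 2))
    sns.heatmap(pivot, annot=True, fmt=fmt, cmap="RdBu_r", center=0, ax=ax)
    ax.set_title(value)
    return _save(fig, spec)
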