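"""Synthetic benchmarks for the enrichment method.

Two studies are generated, matching the conditions under which the method
was characterized:

* **Ranked-list study** — 1351 drugs ranked by draws from N(0, 0.5); a
  planted set of X drugs is re-drawn from N(Y, 0.5).  X spans 5..50 and the
  shift Y spans -1..+1; each (X, Y) cell is replicated 50 times and the
  planted set's mean NES and percent of significant replicates are
  recorded.

* **WGV study** — 200 cell lines with AUC drug-sensitivity scores for 1351
  drugs drawn from a two-component normal mixture (mu=0.83 and 1.31, both
  sigma=0.08, 72% mass in the lower, sensitive component) and expression
  for a planted 25-gene set drawn from N(0, 0.5).  A perturbation v imposes
  a linear gradient of shifts across cell lines, from -v on cell line 1
  rising in steps of 2v/n_cells (0.001 at v=0.1), on the planted genes
  (expression) and planted 10-drug set (AUC).  The signature is the
  top-minus-bottom-decile mean expression difference per planted gene; the
  full WGV -> correlation -> enrichment pipeline is then scored on the
  planted drug set.

The background MOA catalog is a synthetic disjoint partition of the drugs
into sets of 6-50 (a real GMT can be supplied instead); the null behavior
under study depends on set sizes, not identities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._rng import stream
from .core import drug_sea
from .datatypes import (
    EnrichmentParams,
    EnrichmentResult,
    GeneSignature,
    MOACatalog,
    RankedDrugList,
    SensitivityDataset,
    ValidationError,
)
from .wgv import dmea_from_signature

__all__ = [
    "RankListSimConfig",
    "WgvSimConfig",
    "PLANTED_SET",
    "synthetic_moa_catalog",
    "simulate_rank_list",
    "simulate_wgv_dataset",
    "rank_list_grid",
    "wgv_grid",
    "sensitivity_grid",
]

#: Name under which the planted drug set is added to the background catalog.
PLANTED_SET = "planted_set"


@dataclass(frozen=True)
class RankListSimConfig:
    """Conditions of the ranked-list study."""

    n_drugs: int = 1351
    set_size: int = 10
    perturbation: float = 0.0
    mu: float = 0.0
    sigma: float = 0.5
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.set_size < self.n_drugs:
            raise ValidationError("set_size must be in (0, n_drugs)")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


@dataclass(frozen=True)
class WgvSimConfig:
    """Conditions of the WGV-pipeline study."""

    n_cells: int = 200
    n_drugs: int = 1351
    gene_set_size: int = 25
    drug_set_size: int = 10
    expr_perturbation: float = 0.0
    auc_perturbation: float = 0.0
    auc_mu_low: float = 0.83
    auc_sigma_low: float = 0.08
    auc_mu_high: float = 1.31
    auc_sigma_high: float = 0.08
    auc_low_mass: float = 0.72
    expr_mu: float = 0.0
    expr_sigma: float = 0.5
    extreme_fraction: float = 0.10
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.auc_low_mass < 1:
            raise ValidationError("auc_low_mass must be in (0, 1)")
        if not 0 < self.drug_set_size < self.n_drugs:
            raise ValidationError("drug_set_size must be in (0, n_drugs)")
        if not 0 < self.extreme_fraction <= 0.5:
            raise ValidationError("extreme_fraction must be in (0, 0.5]")


def _drug_ids(n: int) -> tuple[str, ...]:
    return tuple(f"drug_{i:04d}" for i in range(n))


def synthetic_moa_catalog(
    n_drugs: int,
    set_sizes: Optional[Sequence[int]] = None,
    seed: int = 0,
    min_size: int = 6,
    max_size: int = 50,
    drug_ids: Optional[Sequence[str]] = None,
) -> MOACatalog:
    """Random disjoint partition of the drugs into named background sets.

    With ``set_sizes`` omitted, sizes are drawn uniformly from
    [min_size, max_size] until fewer than ``min_size`` drugs remain
    unassigned (the remainder stays unannotated background).  Explicit sizes
    below ``min_size`` or exceeding the available drugs are an error.
    """
    ids = list(drug_ids) if drug_ids is not None else list(_drug_ids(n_drugs))
    if len(ids) != n_drugs:
        raise ValidationError("drug_ids length must equal n_drugs")
    rng = stream(seed, "catalog", n_drugs)
    order = list(rng.permutation(ids))

    if set_sizes is not None:
        sizes = list(set_sizes)
        if any(s < min_size for s in sizes):
            raise ValidationError(f"every set size must be >= {min_size}")
        if sum(sizes) > n_drugs:
            raise ValidationError("set sizes exceed the number of drugs")
    else:
        sizes = []
        remaining = n_drugs
        while remaining >= min_size:
            size = int(rng.integers(min_size, min(max_size, remaining) + 1))
            sizes.append(size)
            remaining -= size

    sets: dict[str, frozenset[str]] = {}
    start = 0
    for i, size in enumerate(sizes):
        sets[f"moa_{i:03d}"] = frozenset(order[start : start + size])
        start += size
    return MOACatalog(sets)


def _redraw_zeros(values: np.ndarray, mu: float, sigma: float, rng: np.random.Generator) -> None:
    while True:
        zero = values == 0
        if not zero.any():
            return
        values[zero] = rng.normal(mu, sigma, int(zero.sum()))


def simulate_rank_list(
    cfg: RankListSimConfig, replicate_index: int = 0
) -> tuple[RankedDrugList, frozenset[str]]:
    """One replicate of the ranked-list study: background ranks from
    N(mu, sigma), a random planted set re-drawn from N(mu + Y, sigma).
    Zero draws are re-drawn so every rank is nonzero."""
    rng = stream(cfg.seed, "rank_list", cfg.set_size, cfg.perturbation, replicate_index)
    ids = _drug_ids(cfg.n_drugs)
    values = rng.normal(cfg.mu, cfg.sigma, cfg.n_drugs)
    _redraw_zeros(values, cfg.mu, cfg.sigma, rng)
    planted_idx = rng.choice(cfg.n_drugs, cfg.set_size, replace=False)
    shifted = rng.normal(cfg.mu + cfg.perturbation, cfg.sigma, cfg.set_size)
    _redraw_zeros(shifted, cfg.mu + cfg.perturbation, cfg.sigma, rng)
    values[planted_idx] = shifted
    planted = frozenset(ids[i] for i in planted_idx)
    return RankedDrugList(drugs=ids, ranks=values), planted


def _gradient(v: float, n_cells: int) -> np.ndarray:
    """Shift for cell i (0-based): -v + i * 2v/n_cells; vanishes at v=0."""
    return -v + np.arange(n_cells) * (2.0 * v / n_cells)


def simulate_wgv_dataset(
    cfg: WgvSimConfig, replicate_index: int = 0
) -> tuple[SensitivityDataset, tuple[str, ...], tuple[str, ...], GeneSignature]:
    """One replicate of the WGV study.

    Only the planted genes are materialized in the expression matrix: the
    signature and WGV scores involve no other gene, so unplanted genes are
    inert everywhere downstream.  The signature weight of each planted gene
    is its mean expression in the top decile of cell lines (by planted-gene
    mean) minus the bottom decile.
    """
    rng = stream(
        cfg.seed, "wgv_sim", cfg.expr_perturbation, cfg.auc_perturbation, replicate_index
    )
    cells = [f"cell_{i:03d}" for i in range(cfg.n_cells)]
    drugs = list(_drug_ids(cfg.n_drugs))
    genes = [f"gene_{i:03d}" for i in range(cfg.gene_set_size)]

    low = rng.random((cfg.n_cells, cfg.n_drugs)) < cfg.auc_low_mass
    auc = np.where(
        low,
        rng.normal(cfg.auc_mu_low, cfg.auc_sigma_low, (cfg.n_cells, cfg.n_drugs)),
        rng.normal(cfg.auc_mu_high, cfg.auc_sigma_high, (cfg.n_cells, cfg.n_drugs)),
    )
    expr = rng.normal(cfg.expr_mu, cfg.expr_sigma, (cfg.n_cells, cfg.gene_set_size))

    planted_drug_idx = rng.choice(cfg.n_drugs, cfg.drug_set_size, replace=False)
    expr += _gradient(cfg.expr_perturbation, cfg.n_cells)[:, None]
    auc[:, planted_drug_idx] += _gradient(cfg.auc_perturbation, cfg.n_cells)[:, None]

    n_extreme = max(1, int(round(cfg.extreme_fraction * cfg.n_cells)))
    order = np.argsort(expr.mean(axis=1), kind="stable")
    bottom, top = order[:n_extreme], order[-n_extreme:]
    weights = expr[top].mean(axis=0) - expr[bottom].mean(axis=0)
    signature = GeneSignature(dict(zip(genes, weights.astype(float))))

    dataset = SensitivityDataset(
        expression=pd.DataFrame(expr, index=cells, columns=genes),
        auc=pd.DataFrame(auc, index=cells, columns=drugs),
    )
    planted_drugs = tuple(drugs[i] for i in planted_drug_idx)
    return dataset, tuple(genes), planted_drugs, signature


def _with_planted(catalog: MOACatalog, planted: frozenset[str]) -> MOACatalog:
    return MOACatalog({**catalog.sets, PLANTED_SET: planted})


def _planted_result(
    results: Sequence[EnrichmentResult],
) -> EnrichmentResult:
    for r in results:
        if r.moa == PLANTED_SET:
            return r
    raise ValidationError("planted set missing from enrichment results")


def _summarize(records: pd.DataFrame, axes: list[str]) -> pd.DataFrame:
    grouped = records.groupby(axes, sort=False)
    out = grouped.agg(
        mean_nes=("nes", "mean"),
        pct_significant=("significant", lambda s: 100.0 * s.mean()),
        n_replicates=("significant", "size"),
    ).reset_index()
    return out


def rank_list_grid(
    cfg: RankListSimConfig,
    set_sizes: Sequence[int],
    perturbations: Sequence[float],
    params: EnrichmentParams = EnrichmentParams(),
    catalog: Optional[MOACatalog] = None,
    return_detail: bool = False,
) -> Union[pd.DataFrame, tuple[pd.DataFrame, pd.DataFrame]]:
    """Replicate grid of the ranked-list study.

    For each (set size X, shift Y) cell, runs ``cfg.n_replicates``
    end-to-end analyses of the planted set against the background catalog
    and records its mean NES and the percentage of replicates meeting both
    significance thresholds.  ``min_per_set`` is lowered per cell when X is
    below it, so small planted sets are still evaluated.
    """
    if catalog is None:
        catalog = synthetic_moa_catalog(cfg.n_drugs, seed=cfg.seed)
    rows = []
    for x in set_sizes:
        for y in perturbations:
            cell_cfg = RankListSimConfig(
                n_drugs=cfg.n_drugs,
                set_size=int(x),
                perturbation=float(y),
                mu=cfg.mu,
                sigma=cfg.sigma,
                n_replicates=cfg.n_replicates,
                seed=cfg.seed,
            )
            cell_params = params.with_(min_per_set=min(params.min_per_set, int(x)))
            for rep in range(cfg.n_replicates):
                rlist, planted = simulate_rank_list(cell_cfg, rep)
                outcome = drug_sea(rlist, _with_planted(catalog, planted), cell_params)
                res = _planted_result(outcome.results)
                rows.append(
                    {
                        "set_size": int(x),
                        "perturbation": float(y),
                        "replicate": rep,
                        "es": res.es,
                        "nes": res.nes,
                        "p_value": res.p_value,
                        "q_value": res.q_value,
                        "significant": res.significant,
                    }
                )
    detail = pd.DataFrame(rows)
    grid = _summarize(detail, ["set_size", "perturbation"])
    return (grid, detail) if return_detail else grid


def wgv_grid(
    cfg: WgvSimConfig,
    expr_perturbations: Sequence[float],
    auc_perturbations: Sequence[float],
    params: EnrichmentParams = EnrichmentParams(),
    catalog: Optional[MOACatalog] = None,
    return_detail: bool = False,
) -> Union[pd.DataFrame, tuple[pd.DataFrame, pd.DataFrame]]:
    """Replicate grid of the WGV study over perturbation pairs."""
    if catalog is None:
        catalog = synthetic_moa_catalog(cfg.n_drugs, seed=cfg.seed)
    cell_params = params.with_(min_per_set=min(params.min_per_set, cfg.drug_set_size))
    rows = []
    for ev in expr_perturbations:
        for av in auc_perturbations:
            cell_cfg = WgvSimConfig(
                **{
                    **cfg.__dict__,
                    "expr_perturbation": float(ev),
                    "auc_perturbation": float(av),
                }
            )
            for rep in range(cfg.n_replicates):
                dataset, _, planted_drugs, signature = simulate_wgv_dataset(cell_cfg, rep)
                bundle = dmea_from_signature(
                    signature,
                    dataset,
                    _with_planted(catalog, frozenset(planted_drugs)),
                    cell_params,
                )
                res = _planted_result(bundle.enrichment.results)
                rows.append(
                    {
                        "expr_perturbation": float(ev),
                        "auc_perturbation": float(av),
                        "replicate": rep,
                        "es": res.es,
                        "nes": res.nes,
                        "p_value": res.p_value,
                        "q_value": res.q_value,
                        "significant": res.significant,
                    }
                )
    detail = pd.DataFrame(rows)
    grid = _summarize(detail, ["expr_perturbation", "auc_perturbation"])
    return (grid, detail) if return_detail else grid


def sensitivity_grid(
    cfg: Union[RankListSimConfig, WgvSimConfig],
    grid_axes: dict[str, Sequence],
    params: EnrichmentParams = EnrichmentParams(),
    catalog: Optional[MOACatalog] = None,
) -> pd.DataFrame:
    """Dispatch to the study matching ``cfg``.

    ``grid_axes`` maps axis names to value lists: ``set_size`` and
    ``perturbation`` for the ranked-list study, ``expr_perturbation`` and
    ``auc_perturbation`` for the WGV study.
    """
    if isinstance(cfg, RankListSimConfig):
        return rank_list_grid(
            cfg, grid_axes["set_size"], grid_axes["perturbation"], params, catalog
        )
    if isinstance(cfg, WgvSimConfig):
        return wgv_grid(
            cfg,
            grid_axes["expr_perturbation"],
            grid_axes["auc_perturbation"],
            params,
            catalog,
        )
    raise ValidationError(f"unknown simulation config type {type(cfg).__name__}")
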