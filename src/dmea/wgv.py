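"""Signature -> drug-sensitivity pipeline via weighted gene voting (WGV).

A WGV score classifies each sample by the dot product between a signed gene
signature and the sample's expression over the genes shared by both.  WGV
scores are then Pearson-correlated against each drug's sensitivity profile
(AUC; lower = more sensitive), and the drugs, ranked by correlation
coefficient, feed the MOA enrichment analysis.  Negative enrichment of a
MOA therefore points at candidate selective toxicity toward the signature's
positive phenotype, because samples scoring high on the signature have low
AUC for the drugs at the bottom of the list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import DmeaOutcome, drug_sea
from .datatypes import (
    EnrichmentParams,
    GeneSignature,
    MOACatalog,
    RankedDrugList,
    SensitivityDataset,
    ValidationError,
)

__all__ = ["wgv_scores", "correlate_drug_sensitivity", "dmea_from_signature", "SignatureOutcome"]


def wgv_scores(
    signature: GeneSignature,
    expression: pd.DataFrame,
    alias_table: Optional[dict[str, str]] = None,
) -> tuple[pd.Series, tuple[str, ...]]:
    """Per-sample WGV scores and the signature genes that found no match.

    score(sample) = sum over shared genes of weight_g * expression[sample, g].
    Gene matching is exact and case-sensitive; ``alias_table`` (from -> to)
    is applied to signature symbols first.  Zero overlap is an error listing
    the unmatched symbols.
    """
    weights = signature.weights
    if alias_table:
        weights = {alias_table.get(g, g): w for g, w in weights.items()}
    shared = [g for g in weights if g in expression.columns]
    unmatched = tuple(g for g in weights if g not in expression.columns)
    if not shared:
        raise ValidationError(
            f"no signature gene matches the expression matrix; unmatched: {list(unmatched)}"
        )
    w = np.array([weights[g] for g in shared])
    scores = expression.loc[:, shared].to_numpy() @ w
    return pd.Series(scores, index=expression.index, name="wgv_score"), unmatched


def correlate_drug_sensitivity(
    scores: pd.Series, auc: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Pearson correlation of WGV scores against each drug's AUC profile.

    Missing AUC entries are skipped pairwise.  Drugs with fewer than
    ``min_pairs`` complete pairs or zero variance (in either variable over
    the complete pairs) are excluded and returned separately.  The
    two-sided ``p_corr`` comes from the usual t transform of r; it is
    reported for transparency but never used for ranking.
    """
    shared = auc.index.intersection(scores.index)
    if shared.empty:
        raise ValidationError("no shared samples between WGV scores and AUC matrix")
    s = scores.loc[shared].to_numpy(dtype=float)
    a = auc.loc[shared].to_numpy(dtype=float)

    mask = np.isfinite(a)
    n = mask.sum(axis=0)
    s_col = s[:, None]
    s_sum = (s_col * mask).sum(axis=0)
    s_sq = (s_col**2 * mask).sum(axis=0)
    a0 = np.where(mask, a, 0.0)
    a_sum = a0.sum(axis=0)
    a_sq = (a0**2).sum(axis=0)
    sa = (a0 * s_col).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sa - s_sum * a_sum / n
        var_s = s_sq - s_sum**2 / n
        var_a = a_sq - a_sum**2 / n
        r = cov / np.sqrt(var_s * var_a)

    tiny = 1e-12
    ok = (n >= min_pairs) & (var_s > tiny) & (var_a > tiny)
    r = np.where(ok, np.clip(r, -1.0, 1.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, tiny))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))

    table = pd.DataFrame(
        {"r": r, "n_pairs": n, "p_corr": p}, index=auc.columns
    ).loc[ok]
    excluded = tuple(auc.columns[~ok])
    if table.empty:
        raise ValidationError("no drug has a defined correlation")
    return table, excluded


def ranked_list_from_correlations(table: pd.DataFrame) -> RankedDrugList:
    """Rank drugs by correlation coefficient (zero r drops the drug: ranks
    must be nonzero and a zero correlation carries no direction)."""
    nonzero = table.loc[table["r"] != 0]
    return RankedDrugList(
        drugs=tuple(nonzero.index), ranks=nonzero["r"].to_numpy(dtype=float)
    )


@dataclass(frozen=True)
class SignatureOutcome:
    """Full output bundle of the signature -> enrichment pipeline."""

    wgv: pd.Series
    unmatched_genes: tuple[str, ...]
    correlations: pd.DataFrame
    excluded_drugs: tuple[str, ...]
    ranked_list: RankedDrugList
    enrichment: DmeaOutcome

    def scatter_data(self, drug: str, dataset: SensitivityDataset) -> pd.DataFrame:
        """Per-sample (WGV score, AUC) pairs behind one drug's correlation."""
        df = pd.DataFrame({"wgv_score": self.wgv, "auc": dataset.auc[drug]})
        return df.dropna()


def dmea_from_signature(
    signature: GeneSignature,
    dataset: SensitivityDataset,
    catalog: MOACatalog,
    params: EnrichmentParams = EnrichmentParams(),
    exclude_samples: Optional[set[str]] = None,
    alias_table: Optional[dict[str, str]] = None,
    min_pairs: int = 3,
) -> SignatureOutcome:
    """Signature to MOA enrichment, end to end.

    ``exclude_samples`` removes samples used to derive the signature, so
    the classification is not evaluated on its own training data.
    """
    if exclude_samples:
        dataset = dataset.drop_samples(set(exclude_samples))
    scores, unmatched = wgv_scores(signature, dataset.expression, alias_table)
    table, excluded = correlate_drug_sensitivity(scores, dataset.auc, min_pairs)
    rlist = ranked_list_from_correlations(table)
    outcome = drug_sea(rlist, catalog, params)
    return SignatureOutcome(
        wgv=scores,
        unmatched_genes=unmatched,
        correlations=table,
        excluded_drugs=excluded,
        ranked_list=rlist,
        enrichment=outcome,
    )
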