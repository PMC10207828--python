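"""Weighted Kolmogorov-Smirnov enrichment of drug MOA sets in a ranked list.

Given a drug list sorted descending by a signed rank value, each
mechanism-of-action (MOA) set is scored by a GSEA-style running sum: walking
down the list, member drugs ("hits") push the sum up in proportion to
|rank|^alpha, non-members ("misses") push it down by a constant 1/(N - Nh).
The enrichment score (ES) is the signed maximum deviation from zero.  A
permutation null (random sets of the same size) yields an empirical p-value,
a normalized score (NES = ES over the mean magnitude of same-signed null
scores), and a tail-ratio FDR q-value computed across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .datatypes import (
    EnrichmentParams,
    EnrichmentResult,
    MOACatalog,
    NullDistribution,
    PrepareReport,
    RankedDrugList,
    ValidationError,
)

__all__ = [
    "prepare",
    "catalog_from_annotations",
    "enrichment_score",
    "null_distribution",
    "significance",
    "fdr_adjust",
    "drug_sea",
    "DmeaOutcome",
]


def catalog_from_annotations(rlist: RankedDrugList) -> MOACatalog:
    """Build a MOA catalog from the per-drug annotations of a rank list."""
    if rlist.annotations is None:
        raise ValidationError("rank list carries no MOA annotations")
    sets: dict[str, set[str]] = {}
    for drug, moas in zip(rlist.drugs, rlist.annotations):
        for moa in moas:
            sets.setdefault(moa, set()).add(drug)
    if not sets:
        raise ValidationError("no MOA annotations found in rank list")
    return MOACatalog({name: frozenset(m) for name, m in sets.items()})


def prepare(
    rlist: RankedDrugList, catalog: MOACatalog, params: EnrichmentParams
) -> tuple[RankedDrugList, MOACatalog, PrepareReport]:
    """Sort the list, filter the catalog, and report what was dropped.

    The list is sorted descending by rank value (ties broken by drug id so
    results are reproducible).  Every catalog set is intersected with the
    ranked drugs; sets left with fewer than ``params.min_per_set`` members
    are removed and reported.  Drugs belonging to no catalog set stay in the
    list as background and are reported as unannotated.

    Raises
    ------
    ValidationError
        On duplicate drugs, any zero rank value, or fewer than two
        surviving MOA sets.
    """
    seen: set[str] = set()
    for drug in rlist.drugs:
        if drug in seen:
            raise ValidationError(f"duplicate drug in rank list: {drug!r}")
        seen.add(drug)
    zero = np.flatnonzero(rlist.ranks == 0)
    if zero.size:
        raise ValidationError(
            f"drug {rlist.drugs[zero[0]]!r} has a zero rank value; "
            "every drug must be ranked by a nonzero numeric value"
        )

    prepared = rlist.sort_descending()
    present = set(prepared.drugs)

    kept: dict[str, frozenset[str]] = {}
    removed: dict[str, int] = {}
    for name, members in catalog.sets.items():
        inter = members & present
        if len(inter) >= params.min_per_set:
            kept[name] = frozenset(inter)
        else:
            removed[name] = len(inter)
    if len(kept) < 2:
        raise ValidationError(
            "the ranked list must carry annotations for at least two MOAs "
            f"with >= {params.min_per_set} ranked drugs each ({len(kept)} survived)"
        )

    annotated = set().union(*catalog.sets.values())
    unannotated = tuple(d for d in prepared.drugs if d not in annotated)
    report = PrepareReport(removed_sets=removed, unannotated_drugs=unannotated)
    return prepared, MOACatalog(kept), report


def enrichment_score(
    rlist: RankedDrugList, member_ids: set[str], alpha: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Running-sum enrichment score of one drug set in a prepared list.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum[i]`` is
    the sum after list position ``i`` and the leading edge contains the
    member drugs at or before the extremum (at or after it, for negative
    ES), ordered by list position.
    """
    n = len(rlist)
    is_member = np.fromiter((d in member_ids for d in rlist.drugs), bool, count=n)
    n_hit = int(is_member.sum())
    if n_hit == 0:
        raise ValidationError("member set shares no drugs with the ranked list")
    if n_hit != len(member_ids):
        raise ValidationError("member_ids must be a subset of the ranked drugs")
    if n_hit == n:
        raise ValidationError("member set equals the whole list; no misses to weigh")

    weights = np.abs(rlist.ranks) ** alpha
    hit_total = weights[is_member].sum()
    increments = np.where(is_member, weights / hit_total, -1.0 / (n - n_hit))
    # sequential accumulation (not np.cumsum, whose pairwise summation can
    # differ in the last ulp): the reported ES must equal a plain
    # prefix-sum walk bit for bit
    running = np.empty(n)
    acc = 0.0
    for i, inc in enumerate(increments.tolist()):
        acc += inc
        running[i] = acc

    peak = int(np.argmax(np.abs(running)))  # earliest position on ties
    es = float(running[peak])
    if es > 0:
        edge_mask = is_member & (np.arange(n) <= peak)
    elif es < 0:
        edge_mask = is_member & (np.arange(n) >= peak)
    else:
        edge_mask = np.zeros(n, bool)
    leading_edge = tuple(rlist.drugs[i] for i in np.flatnonzero(edge_mask))
    return es, running, leading_edge


def _null_es(
    weights: np.ndarray, set_size: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Enrichment scores of random same-size sets, vectorized.

    The running sum only attains its extrema at hit positions (local maxima)
    or immediately before them (local minima), so each permutation is scored
    from its sorted member positions alone.
    """
    n = len(weights)
    miss = 1.0 / (n - set_size)
    draws = rng.random((n_permutations, n))
    pos = np.argpartition(draws, set_size - 1, axis=1)[:, :set_size]
    pos.sort(axis=1)

    w = weights[pos]
    hit_cum = np.cumsum(w, axis=1)
    hit_cum /= hit_cum[:, -1:]
    k = np.arange(1, set_size + 1)
    at_hit = hit_cum - (pos + 1 - k) * miss
    before_hit = np.concatenate(
        [np.zeros((n_permutations, 1)), hit_cum[:, :-1]], axis=1
    ) - (pos - k + 1) * miss

    values = np.concatenate([at_hit, before_hit], axis=1)
    positions = np.concatenate([pos, pos - 1], axis=1)
    absv = np.abs(values)
    is_max = absv == absv.max(axis=1, keepdims=True)
    tie_pos = np.where(is_max, positions, n + 1)  # earliest position on ties
    pick = np.argmin(tie_pos, axis=1)
    return values[np.arange(n_permutations), pick]


def _normalize_null(es_null: np.ndarray) -> np.ndarray:
    """Divide each null score by the mean magnitude of its signed portion."""
    nes = np.zeros_like(es_null)
    pos = es_null > 0
    neg = es_null < 0
    if pos.any():
        nes[pos] = es_null[pos] / np.abs(es_null[pos].mean())
    if neg.any():
        nes[neg] = es_null[neg] / np.abs(es_null[neg].mean())
    return nes


def null_distribution(
    rlist: RankedDrugList,
    set_size: int,
    params: EnrichmentParams,
    stream_key: str,
) -> NullDistribution:
    """Permutation null for one set size on a prepared list.

    Each permutation scores a uniformly random subset of ``set_size`` drugs;
    the random stream is derived from ``(params.seed, stream_key)`` so the
    null is reproducible and independent of catalog iteration order.
    """
    n = len(rlist)
    if not 0 < set_size < n:
        raise ValidationError(f"set_size must be in (0, {n}); got {set_size}")
    weights = np.abs(rlist.ranks) ** params.weight_exponent
    rng = stream(params.seed, stream_key)
    es_null = _null_es(weights, set_size, params.n_permutations, rng)
    return NullDistribution(es_null=es_null, nes_null=_normalize_null(es_null))


def significance(es: float, null: NullDistribution) -> tuple[float, float]:
    """Empirical p-value and normalized enrichment score.

    With S the same-signed portion of the null, p is the fraction of S at
    least as extreme as |es| (clamped at the permutation floor), and
    NES = es / |mean(S)|.  When S is empty, p sits at the floor and NES is
    not computable (NaN).  A degenerate es of exactly 0 gives p=1, NES=0.
    """
    n_perm = len(null.es_null)
    if n_perm == 0:
        raise ValidationError("null distribution is empty")
    if es == 0:
        return 1.0, 0.0
    same = null.es_null[null.es_null * np.sign(es) > 0]
    floor = 1.0 / n_perm
    if same.size == 0:
        return floor, float("nan")
    p = max(float(np.mean(np.abs(same) >= abs(es))), floor)
    nes = es / abs(same.mean())
    return p, float(nes)


def fdr_adjust(
    observed_nes: dict[str, float], nes_null_pool: np.ndarray
) -> dict[str, float]:
    """Tail-ratio FDR q-values across all tested MOA sets.

    For each observed NES n*, q is the fraction of same-signed null NES at
    least as extreme as |n*| divided by the fraction of same-signed observed
    NES at least as extreme, clamped to [0, 1].  NaN observations (NES not
    computable) receive NaN.
    """
    pool = np.asarray(nes_null_pool, dtype=float)
    if pool.size == 0:
        raise ValidationError("empty null NES pool")
    obs = np.array([v for v in observed_nes.values() if np.isfinite(v) and v != 0])
    q: dict[str, float] = {}
    for moa, n_star in observed_nes.items():
        if not np.isfinite(n_star) or n_star == 0:
            q[moa] = float("nan")
            continue
        s = np.sign(n_star)
        null_same = pool[pool * s > 0]
        obs_same = obs[obs * s > 0]
        if null_same.size == 0:
            q[moa] = 0.0
            continue
        num = np.mean(np.abs(null_same) >= abs(n_star))
        den = np.mean(np.abs(obs_same) >= abs(n_star))  # includes n* itself
        q[moa] = float(np.clip(num / den, 0.0, 1.0))
    return q


@dataclass(frozen=True)
class DmeaOutcome:
    """Everything one enrichment run produces."""

    results: tuple[EnrichmentResult, ...]
    prepared_list: RankedDrugList
    catalog: MOACatalog
    report: PrepareReport

    def to_frame(self) -> pd.DataFrame:
        from .io import results_to_frame

        return results_to_frame(self.results)

    def __getitem__(self, moa: str) -> EnrichmentResult:
        for r in self.results:
            if r.moa == moa:
                return r
        raise KeyError(moa)


def drug_sea(
    rlist: RankedDrugList,
    catalog: MOACatalog,
    params: EnrichmentParams = EnrichmentParams(),
) -> DmeaOutcome:
    """Run the full enrichment analysis: one result per surviving MOA set.

    Results are sorted by NES descending (not-computable NES last) and
    flagged significant where ``p < p_threshold`` and ``q < fdr_threshold``.
    All randomness derives from ``params.seed`` with one stream per MOA.
    """
    prepared, kept, report = prepare(rlist, catalog, params)

    es_by_moa: dict[str, float] = {}
    nes_by_moa: dict[str, float] = {}
    p_by_moa: dict[str, float] = {}
    extras: dict[str, tuple[np.ndarray, tuple[str, ...]]] = {}
    null_pool: list[np.ndarray] = []
    for moa, members in kept.sets.items():
        es, running, edge = enrichment_score(prepared, set(members), params.weight_exponent)
        null = null_distribution(prepared, len(members), params, stream_key=moa)
        p, nes = significance(es, null)
        es_by_moa[moa] = es
        nes_by_moa[moa] = nes
        p_by_moa[moa] = p
        extras[moa] = (running, edge)
        null_pool.append(null.nes_null)

    q_by_moa = fdr_adjust(nes_by_moa, np.concatenate(null_pool))

    results = []
    for moa, members in kept.sets.items():
        running, edge = extras[moa]
        nes, p, q = nes_by_moa[moa], p_by_moa[moa], q_by_moa[moa]
        significant = bool(
            np.isfinite(q) and p < params.p_threshold and q < params.fdr_threshold
        )
        results.append(
            EnrichmentResult(
                moa=moa,
                n_drugs=len(members),
                es=es_by_moa[moa],
                nes=nes,
                p_value=p,
                q_value=q,
                leading_edge=edge,
                running_sum=running,
                significant=significant,
            )
        )
    results.sort(key=lambda r: (not np.isfinite(r.nes), -r.nes if np.isfinite(r.nes) else 0.0, r.moa))
    return DmeaOutcome(
        results=tuple(results), prepared_list=prepared, catalog=kept, report=report
    )
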