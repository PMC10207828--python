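"""Domain types shared across the package.

The central objects are a rank-ordered drug list (the enrichment substrate),
a catalog of drug sets grouped by mechanism of action (MOA), a signed gene
signature, and a paired expression / drug-sensitivity dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class DmeaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DmeaError):
    """Malformed input file (bad header, non-numeric field, short line...)."""


class ValidationError(DmeaError):
    """Structurally valid input that violates a method precondition."""


@dataclass(frozen=True)
class RankedDrugList:
    """Drugs with signed, nonzero rank values and optional MOA annotations.

    Parameters
    ----------
    drugs
        Drug identifiers, unique after preparation.
    ranks
        Signed rank value per drug; the weight of the KS statistic.
    annotations
        Optional per-drug MOA annotation lists (parallel to ``drugs``);
        ``None`` when the input carried no annotation column.
    """

    drugs: tuple[str, ...]
    ranks: np.ndarray
    annotations: Optional[tuple[tuple[str, ...], ...]] = None

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=float)
        object.__setattr__(self, "ranks", ranks)
        if len(self.drugs) != len(ranks):
            raise ValidationError("drugs and ranks must have equal length")
        if self.annotations is not None and len(self.annotations) != len(self.drugs):
            raise ValidationError("annotations must be parallel to drugs")
        if not np.all(np.isfinite(ranks)):
            raise ValidationError("all rank values must be finite")

    def __len__(self) -> int:
        return len(self.drugs)

    def sort_descending(self) -> "RankedDrugList":
        """Return a copy sorted by rank descending, ties broken by drug id."""
        order = sorted(range(len(self)), key=lambda i: (-self.ranks[i], self.drugs[i]))
        ann = None
        if self.annotations is not None:
            ann = tuple(self.annotations[i] for i in order)
        return RankedDrugList(
            drugs=tuple(self.drugs[i] for i in order),
            ranks=self.ranks[order],
            annotations=ann,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"drug": self.drugs, "rank": self.ranks})
        if self.annotations is not None:
            df["moa"] = ["|".join(a) for a in self.annotations]
        return df


@dataclass(frozen=True)
class MOACatalog:
    """Named drug sets: mechanism-of-action name -> member drug ids."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"MOA set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict_to(self, drugs: Sequence[str]) -> "MOACatalog":
        """Intersect every set with ``drugs``, dropping sets that empty out."""
        present = set(drugs)
        kept = {}
        for name, members in self.sets.items():
            inter = members & present
            if inter:
                kept[name] = frozenset(inter)
        return MOACatalog(kept)


@dataclass(frozen=True)
class GeneSignature:
    """Gene symbol -> signed weight (e.g. log2 fold-change)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for gene, w in self.weights.items():
            if not np.isfinite(w):
                raise ValidationError(f"non-finite weight for gene {gene!r}")

    def __len__(self) -> int:
        return len(self.weights)

    def scaled(self, factor: float) -> "GeneSignature":
        return GeneSignature({g: w * factor for g, w in self.weights.items()})


@dataclass(frozen=True)
class SensitivityDataset:
    """Paired sample x gene expression and sample x drug sensitivity matrices.

    ``expression`` must be complete; ``auc`` may contain missing values
    (NaN).  Both are indexed by the same samples in the same order.
    """

    expression: pd.DataFrame
    auc: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expression.index) != list(self.auc.index):
            raise ValidationError(
                "expression and auc matrices must share identical, co-ordered sample ids"
            )
        if self.expression.isna().any().any():
            raise ValidationError("expression matrix must not contain missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.index)

    def drop_samples(self, exclude: set[str]) -> "SensitivityDataset":
        keep = [s for s in self.sample_ids if s not in exclude]
        if not keep:
            raise ValidationError("excluding these samples leaves an empty dataset")
        return SensitivityDataset(self.expression.loc[keep], self.auc.loc[keep])


@dataclass(frozen=True)
class EnrichmentParams:
    """Tunable parameters of the enrichment analysis.

    ``weight_exponent`` is the alpha of the weighted KS statistic (0 gives
    the classic unweighted KS); ``min_per_set`` is the minimum number of
    ranked drugs a MOA set must retain to be evaluated; significance is
    declared at ``p < p_threshold`` and ``q < fdr_threshold``.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_per_set: int = 6
    p_threshold: float = 0.05
    fdr_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.min_per_set < 2:
            raise ValidationError("min_per_set must be >= 2")
        if self.weight_exponent < 0:
            raise ValidationError("weight_exponent must be nonnegative")

    def with_(self, **kwargs) -> "EnrichmentParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null: raw enrichment scores and their normalized form."""

    es_null: np.ndarray
    nes_null: np.ndarray

    def __post_init__(self) -> None:
        if len(self.es_null) != len(self.nes_null):
            raise ValidationError("es_null and nes_null lengths differ")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-MOA enrichment outcome.

    ``nes`` and ``q_value`` are NaN when not computable (no same-signed null
    scores).  ``running_sum`` holds the KS running-sum value after each list
    position and supports the mountain plot.
    """

    moa: str
    n_drugs: int
    es: float
    nes: float
    p_value: float
    q_value: float
    leading_edge: tuple[str, ...]
    running_sum: np.ndarray
    significant: bool = False


@dataclass(frozen=True)
class PrepareReport:
    """What preparation removed or could not annotate."""

    removed_sets: dict[str, int] = field(default_factory=dict)
    unannotated_drugs: tuple[str, ...] = ()
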