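"""Readers and writers for every external format the tool touches.

Dialects, fixed deliberately so outputs are reproducible byte for byte:

* CSV: comma-separated, UTF-8, header row required; ``|`` is the only
  separator inside annotation fields; missing values are written ``NA``.
* GMT: one named set per line, tab-separated ``name<TAB>description<TAB>
  member...``.
* GCT v1.3: ``#1.3`` version line, four-integer dimension line, a header
  row naming row-metadata columns then score columns, optional
  column-metadata rows, then one data row per score entry.
* Result tables: full double precision (shortest round-tripping repr).
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .datatypes import (
    EnrichmentResult,
    FormatError,
    GeneSignature,
    MOACatalog,
    RankedDrugList,
)

Source = Union[str, Path, TextIO]

#: GCT quality-flag values (case-insensitive) treated as "low quality".
LOW_QUALITY_VALUES = frozenset({"0", "false", "low", "fail", "-666"})


def _open(source: Source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _read_csv(source: Source) -> pd.DataFrame:
    try:
        return pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty CSV input") from exc


def _parse_numeric(raw: pd.Series, what: str) -> pd.Series:
    # Python's float() is correctly rounded (pandas' fast parser is not),
    # which keeps read(write(x)) bit-exact
    def parse(cell: str) -> float:
        try:
            value = float(cell.strip())
        except ValueError:
            return float("nan")
        return value if np.isfinite(value) else float("nan")

    values = raw.map(parse)
    bad = values.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"non-numeric {what} {raw[bad.idxmax()]!r} at row {row}")
    return values


def _split_annotations(cell: str) -> tuple[str, ...]:
    return tuple(dict.fromkeys(p.strip() for p in cell.split("|") if p.strip()))


def read_drug_rank_csv(
    source: Source, average_duplicates: bool = False
) -> RankedDrugList:
    """Read a rank-list CSV: drug, signed rank, optional ``|``-separated MOAs.

    Duplicate drug rows are averaged only when ``average_duplicates`` is
    set; otherwise they are an error naming the drug.  Zero ranks (before
    or after averaging) are rejected.
    """
    df = _read_csv(source)
    if df.shape[1] < 2:
        raise FormatError("rank-list CSV needs at least two columns (drug, rank)")
    drugs = df.iloc[:, 0].str.strip()
    ranks = _parse_numeric(df.iloc[:, 1], "rank")
    has_moa = df.shape[1] >= 3
    annotations = (
        [_split_annotations(c) for c in df.iloc[:, 2]] if has_moa else None
    )

    if drugs.duplicated().any():
        dup = drugs[drugs.duplicated()].iloc[0]
        if not average_duplicates:
            raise FormatError(
                f"duplicate drug {dup!r}; pass average_duplicates=True to average"
            )
        merged_drugs, merged_ranks, merged_ann = [], [], []
        for drug in dict.fromkeys(drugs):
            mask = drugs == drug
            merged_drugs.append(drug)
            merged_ranks.append(float(ranks[mask].mean()))
            if has_moa:
                seen: dict[str, None] = {}
                for i in np.flatnonzero(mask):
                    seen.update(dict.fromkeys(annotations[i]))
                merged_ann.append(tuple(seen))
        drugs_t = tuple(merged_drugs)
        ranks_a = np.array(merged_ranks)
        ann_t = tuple(merged_ann) if has_moa else None
    else:
        drugs_t = tuple(drugs)
        ranks_a = ranks.to_numpy(dtype=float)
        ann_t = tuple(annotations) if has_moa else None

    zero = np.flatnonzero(ranks_a == 0)
    if zero.size:
        raise FormatError(
            f"drug {drugs_t[zero[0]]!r} has a zero rank value; ranks must be nonzero"
        )
    return RankedDrugList(drugs=drugs_t, ranks=ranks_a, annotations=ann_t)


def write_drug_rank_csv(rlist: RankedDrugList, dest: Source) -> None:
    rlist.to_frame().to_csv(dest, index=False, na_rep="NA", float_format="%.17g")


def read_moa_gmt(source: Source) -> MOACatalog:
    """Read a GMT catalog: ``name<TAB>description<TAB>member...`` per line."""
    handle, close = _open(source)
    sets: dict[str, frozenset[str]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    finally:
        if close:
            handle.close()
    if not sets:
        raise FormatError("GMT input contains no sets")
    return MOACatalog(sets)


def write_moa_gmt(catalog: MOACatalog, dest: Source) -> None:
    handle, close = _open_write(dest)
    try:
        for name in sorted(catalog.sets):
            members = "\t".join(sorted(catalog.sets[name]))
            handle.write(f"{name}\tna\t{members}\n")
    finally:
        if close:
            handle.close()


def _open_write(dest: Source):
    if isinstance(dest, (str, Path)):
        return open(dest, "w", encoding="utf-8"), True
    return dest, False


def parse_connectivity_gct(
    source: Source,
    quality_field: Optional[str] = None,
    score_aggregation: Union[str, Callable[[np.ndarray], float]] = "mean",
    drug_field: Optional[str] = None,
    moa_field: Optional[str] = None,
    score_columns: Optional[Sequence[str]] = None,
    low_quality_values: frozenset[str] = LOW_QUALITY_VALUES,
) -> tuple[RankedDrugList, tuple[str, ...]]:
    """Aggregate a GCT v1.3 connectivity-score file into a rank list.

    Rows are score entries (one drug, or one drug x cell-line pair);
    ``drug_field`` names the row-metadata column holding the drug name
    (default: the id column).  Rows whose ``quality_field`` value falls in
    ``low_quality_values`` (case-insensitive) are excluded, as are missing
    scores (blank, NaN, or -666).  Each drug's surviving scores across rows
    and score columns are reduced by ``score_aggregation`` (default: mean)
    into its single rank value.  MOA annotations, if ``moa_field`` is given,
    are carried over (pipe-separated, unioned across rows).

    Returns the rank list plus the drugs dropped for having no surviving
    scores.
    """
    handle, close = _open(source)
    try:
        lines = [ln.rstrip("\n") for ln in handle]
    finally:
        if close:
            handle.close()
    if not lines or not lines[0].startswith("#1."):
        raise FormatError("missing GCT version line (expected '#1.3')")
    if len(lines) < 3:
        raise FormatError("truncated GCT: missing dimension or header line")
    dims = lines[1].split("\t")
    if len(dims) not in (2, 4):
        raise FormatError("malformed GCT dimension line")
    try:
        n_rows = int(dims[0])
        n_row_meta = int(dims[2]) if len(dims) == 4 else 0
        n_col_meta = int(dims[3]) if len(dims) == 4 else 0
    except ValueError as exc:
        raise FormatError("malformed GCT dimension line") from exc

    header = lines[2].split("\t")
    meta_names = header[1 : 1 + n_row_meta]
    col_ids = header[1 + n_row_meta :]
    data_start = 3 + n_col_meta
    body = [ln.split("\t") for ln in lines[data_start : data_start + n_rows]]
    if len(body) != n_rows:
        raise FormatError(f"GCT declares {n_rows} rows but {len(body)} present")

    if score_columns is not None:
        missing = set(score_columns) - set(col_ids)
        if missing:
            raise FormatError(f"score columns not in GCT header: {sorted(missing)}")
        score_idx = [col_ids.index(c) for c in score_columns]
    else:
        score_idx = list(range(len(col_ids)))

    def meta(fields: list[str], name: str) -> str:
        try:
            return fields[1 + meta_names.index(name)].strip()
        except ValueError as exc:
            raise FormatError(f"row-metadata field {name!r} not in GCT header") from exc

    scores: dict[str, list[float]] = {}
    moas: dict[str, dict[str, None]] = {}
    order: dict[str, None] = {}
    for fields in body:
        drug = meta(fields, drug_field) if drug_field else fields[0].strip()
        order.setdefault(drug, None)
        scores.setdefault(drug, [])
        moas.setdefault(drug, {})
        if quality_field is not None:
            if meta(fields, quality_field).lower() in low_quality_values:
                continue
        if moa_field is not None:
            moas[drug].update(dict.fromkeys(_split_annotations(meta(fields, moa_field))))
        for j in score_idx:
            cell = fields[1 + n_row_meta + j].strip() if 1 + n_row_meta + j < len(fields) else ""
            if not cell or cell == "-666":
                continue
            value = float(cell)
            if np.isfinite(value):
                scores[drug].append(value)

    agg = np.mean if score_aggregation == "mean" else score_aggregation
    if isinstance(agg, str):
        raise FormatError(f"unknown score aggregation {score_aggregation!r}")
    kept, ranks, ann, dropped = [], [], [], []
    for drug in order:
        if scores[drug]:
            kept.append(drug)
            ranks.append(float(agg(np.array(scores[drug]))))
            ann.append(tuple(moas[drug]))
        else:
            dropped.append(drug)
    if not kept:
        raise FormatError("no drug has any surviving score")
    annotations = tuple(ann) if moa_field is not None else None
    return (
        RankedDrugList(drugs=tuple(kept), ranks=np.array(ranks), annotations=annotations),
        tuple(dropped),
    )


def read_gene_signature_csv(
    source: Source, average_duplicates: bool = False
) -> GeneSignature:
    """Read a signature CSV: gene symbol, signed weight (header required)."""
    df = _read_csv(source)
    if df.shape[1] < 2:
        raise FormatError("signature CSV needs two columns (gene, weight)")
    genes = df.iloc[:, 0].str.strip()
    weights = _parse_numeric(df.iloc[:, 1], "weight")
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        if not average_duplicates:
            raise FormatError(
                f"duplicate gene {dup!r}; pass average_duplicates=True to average"
            )
        merged = weights.groupby(genes, sort=False).mean()
        return GeneSignature(dict(zip(merged.index, merged.astype(float))))
    return GeneSignature(dict(zip(genes, weights.astype(float))))


def read_expression_csv(source: Source) -> pd.DataFrame:
    """Sample x gene matrix; first column sample ids; no missing values."""
    df = pd.read_csv(source, index_col=0)
    if df.isna().any().any():
        raise FormatError("expression matrix contains missing values")
    return df


def read_auc_csv(source: Source) -> pd.DataFrame:
    """Sample x drug sensitivity (AUC) matrix; missing values allowed."""
    return pd.read_csv(source, index_col=0)


def read_synonym_table(source: Source) -> dict[str, str]:
    """Two-column mapping (from, to) used to harmonize drug or gene names."""
    df = _read_csv(source)
    if df.shape[1] < 2:
        raise FormatError("synonym table needs two columns (from, to)")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


RESULT_COLUMNS = (
    "moa",
    "n_drugs",
    "es",
    "nes",
    "p_value",
    "q_value",
    "significant",
    "leading_edge",
)


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "moa": r.moa,
            "n_drugs": r.n_drugs,
            "es": r.es,
            "nes": r.nes,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": r.significant,
            "leading_edge": "|".join(r.leading_edge),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Iterable[EnrichmentResult], dest: Source) -> None:
    """One row per MOA; stable column order; NaN written as ``NA``."""
    results_to_frame(results).to_csv(
        dest, index=False, na_rep="NA", float_format="%.17g"
    )


def read_results(source: Source) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(source, na_values=["NA"], keep_default_na=False)
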