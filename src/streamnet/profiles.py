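"""Count-table container, I/O, table-level filters and alpha-diversity.

The count table is the pipeline's universal input: a samples x taxa matrix of
non-negative integer read counts (OTU abundances), with unique sample and
taxon identifiers. Filters implemented here are the dataset-wide singleton
filter (taxa seen in at most one read in total) and the abundance filter
(taxa whose share of total reads strictly exceeds a fraction, default 1%).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "read_count_table",
    "write_count_table",
    "filter_singletons",
    "relative_abundance",
    "filter_abundant",
    "richness",
    "shannon",
    "aggregate_by_annotation",
    "read_annotation_map",
    "diversity_summary",
    "group_diversity_stats",
]


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa. Validated on construction:
        identifiers must be unique and every entry a non-negative integer.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dupes}")
        values = df.to_numpy()
        if values.size:
            bad = ~np.isfinite(values.astype(float))
            bad |= values.astype(float) < 0
            bad |= values.astype(float) != np.floor(values.astype(float))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "count table entries must be non-negative integers; "
                    f"offending cell: sample {df.index[i]!r}, taxon "
                    f"{df.columns[j]!r} = {values[i, j]!r}"
                )
        df = df.astype(np.int64)
        df.index = df.index.rename(None)
        df.columns = df.columns.rename(None)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample identifiers: {missing}")
        return CountTable(self.data.loc[ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


def _table_from_frame(df: pd.DataFrame, orientation: str) -> CountTable:
    if orientation == "taxa_rows":
        df = df.T
    elif orientation == "auto":
        name = (df.index.name or "").strip().lower().lstrip("#")
        if name in {"otu id", "otu_id", "taxon", "taxon_id", "feature id", "feature_id"}:
            log.info("orientation auto-detected as taxa-as-rows; transposing")
            df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountTable(df)


def read_count_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "auto",
) -> CountTable:
    """Read a count table from TSV or BIOM 1.0 (JSON).

    TSV orientation is auto-detected from the index-column header (an
    ``#OTU ID``-style header means taxa-as-rows) or forced with
    ``orientation`` in {'samples_rows', 'taxa_rows'}. BIOM files follow the
    format's own convention (observations = taxa as rows).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return _table_from_frame(df, orientation)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type") == "dense":
            mat[:] = np.asarray(doc["data"])
        else:  # sparse [row, col, value] triples
            for r, c, v in doc["data"]:
                mat[r, c] = v
        df = pd.DataFrame(mat.T, index=samples, columns=taxa)
        return CountTable(df)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")


def write_count_table(
    table: CountTable, path: str | Path, format: str = "tsv"
) -> None:
    """Write a count table as TSV (samples as rows) or BIOM 1.0 JSON."""
    path = Path(path)
    if format == "tsv":
        df = table.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
        return
    if format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "streamnet",
            "date": "1970-01-01T00:00:00",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [len(table.taxon_ids), len(table.sample_ids)],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.data.to_numpy().T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")


def filter_singletons(table: CountTable) -> CountTable:
    """Drop taxa observed in at most one read across the whole dataset.

    Removes every taxon whose total count over all samples is <= 1 (this
    includes all-zero taxa). Samples are left untouched.
    """
    totals = table.data.sum(axis=0)
    kept = totals.index[totals > 1]
    dropped = table.shape[1] - len(kept)
    if dropped:
        log.info("filter_singletons dropped %d of %d taxa", dropped, table.shape[1])
    return CountTable(table.data[kept])


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances; each retained row sums to 1.

    All-zero samples cannot be normalised; they are excluded with a warning.
    """
    totals = table.data.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(
            f"excluding {len(zero)} all-zero sample(s) from relative "
            f"abundances: {zero}",
            stacklevel=2,
        )
    df = table.data.loc[totals > 0]
    return df.div(df.sum(axis=1), axis=0)


def filter_abundant(
    table: CountTable,
    threshold: float = 0.01,
    scope: str = "dataset",
    groups: Mapping[str, str] | pd.Series | None = None,
) -> CountTable:
    """Keep taxa whose share of total reads strictly exceeds ``threshold``.

    With ``scope='dataset'`` shares are computed over the whole table. With
    ``scope='group'`` a per-sample group label mapping is required and a
    taxon is kept if it exceeds the threshold within at least one group.
    The inequality is strict: a taxon at exactly 1% of the reads is dropped
    at the default threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if scope == "dataset":
        totals = table.data.sum(axis=0)
        grand = totals.sum()
        kept = totals.index if grand == 0 else totals.index[totals / grand > threshold]
    elif scope == "group":
        if groups is None:
            raise ValueError("scope='group' requires per-sample group labels")
        labels = pd.Series(groups).reindex(table.sample_ids)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing}")
        keep = pd.Series(False, index=table.data.columns)
        for _, idx in labels.groupby(labels).groups.items():
            totals = table.data.loc[idx].sum(axis=0)
            grand = totals.sum()
            if grand > 0:
                keep |= totals / grand > threshold
        kept = keep.index[keep]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return CountTable(table.data[kept])


def richness(counts: np.ndarray | pd.Series | Iterable[int]) -> int:
    """Taxon richness of one sample: the number of taxa with count > 0."""
    arr = np.asarray(list(counts) if not hasattr(counts, "__array__") else counts)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return int((arr > 0).sum())


def shannon(
    counts: np.ndarray | pd.Series | Iterable[float], log_base: str = "e"
) -> float:
    """Shannon–Wiener index H = -sum p_i log(p_i) of one sample.

    ``log_base`` is 'e' (natural log, default) or '2'. Scale-invariant in the
    counts; raises on an all-zero vector (no distribution to summarise).
    """
    arr = np.asarray(
        list(counts) if not hasattr(counts, "__array__") else counts, dtype=float
    )
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if log_base == "2":
        h /= np.log(2.0)
    elif log_base != "e":
        raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")
    return h


def read_annotation_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (taxon_id, label) into a dict."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation map needs two columns: taxon_id, label")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def aggregate_by_annotation(
    table: CountTable | pd.DataFrame,
    annotation: Mapping[str, str],
    unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Sum columns sharing an annotation label (taxonomy or function).

    Taxa absent from the map are pooled under ``unassigned_label``. Row sums
    are preserved exactly, so the operation commutes with relative-abundance
    normalisation.
    """
    df = table.data if isinstance(table, CountTable) else table
    labels = [annotation.get(t, unassigned_label) for t in df.columns]
    return df.T.groupby(pd.Index(labels, name="label"), sort=True).sum().T


def diversity_summary(
    table: CountTable,
    design: pd.DataFrame | None = None,
    log_base: str = "e",
) -> pd.DataFrame:
    """Tidy per-sample richness and Shannon, joined with design factors.

    ``design`` must carry a ``sample_id`` column covering every sample in the
    table; unmatched samples raise with the offenders listed. All-zero
    samples get NaN Shannon (with a warning) rather than an error, so one bad
    sample does not abort a whole summary.
    """
    rows = []
    for sid in table.sample_ids:
        vec = table.data.loc[sid]
        try:
            h = shannon(vec, log_base=log_base)
        except ValueError:
            warnings.warn(f"sample {sid!r} is all-zero; Shannon set to NaN",
                          stacklevel=2)
            h = np.nan
        rows.append({"sample_id": sid, "richness": richness(vec), "shannon": h})
    out = pd.DataFrame(rows)
    if design is not None:
        if "sample_id" not in design.columns:
            raise ValueError("design table needs a 'sample_id' column")
        missing = sorted(set(out.sample_id) - set(design.sample_id))
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        out = out.merge(design, on="sample_id", how="left")
    return out


def group_diversity_stats(
    summary: pd.DataFrame, by: list[str]
) -> pd.DataFrame:
    """Group means and standard errors of richness/Shannon.

    SE is NaN for singleton groups (undefined with n = 1).
    """
    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    g = summary.groupby(by, observed=True)
    out = g.agg(
        n=("sample_id", "size"),
        richness_mean=("richness", "mean"),
        richness_se=("richness", _se),
        shannon_mean=("shannon", "mean"),
        shannon_se=("shannon", _se),
    ).reset_index()
    return out
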