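"""Expression-matrix I/O, probe-to-gene collapsing and scale management.

Expression matrices are tab-delimited text with one header row of sample ids
and feature (probe or gene) ids in the first column.  Phenotype labels live in
a two-column sidecar file (sample_id, label).  The measurement scale -- log2
(as produced by RMA-style preprocessing) or linear (anti-logged intensities)
-- is an explicit attribute of every dataset, and every transform checks it:
probe collapsing is defined on the log2 scale, phenotype averaging on the
linear scale, and silent double transforms are the classic way this kind of
pipeline gets corrupted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOG2 = "log2"
LINEAR = "linear"
_SCALES = (LOG2, LINEAR)


@dataclass
class ExpressionDataset:
    """A labeled gene x sample expression matrix on a declared scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Feature x sample matrix; index holds unique feature ids, columns hold
        unique sample ids.  All entries must be finite, and non-negative when
        the scale is linear.
    scale : str
        Either ``"log2"`` or ``"linear"``.
    phenotype : pandas.Series
        Per-sample label (e.g. ``"N"`` / ``"C"``) indexed by sample id.  Every
        column of `values` must have a label; extra entries are dropped.
    """

    values: pd.DataFrame
    scale: str
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == LINEAR and (arr < 0).any():
            raise ValueError("negative intensities are invalid on the linear scale")
        missing = self.values.columns.difference(self.phenotype.index)
        if len(missing) > 0:
            raise ValueError(f"samples without a phenotype label: {list(missing[:5])}")
        self.phenotype = self.phenotype.reindex(self.values.columns)
        if self.phenotype.isna().any():
            raise ValueError("phenotype labels contain missing values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        """Restrict to the given samples, preserving their order."""
        return ExpressionDataset(
            self.values.loc[:, list(sample_ids)], self.scale, self.phenotype
        )

    def with_phenotype(self, phenotype: pd.Series) -> "ExpressionDataset":
        return ExpressionDataset(self.values, self.scale, phenotype)


@dataclass
class ProbeGeneMap:
    """A many-to-one probe -> gene mapping (no probe maps to two genes)."""

    mapping: pd.Series  # index: probe_id, values: gene_id

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            grouped = self.mapping.groupby(level=0).nunique()
            bad = grouped[grouped > 1]
            if len(bad) > 0:
                raise ValueError(
                    f"probes mapped to more than one gene: {list(bad.index[:5])}"
                )
            self.mapping = self.mapping[~self.mapping.index.duplicated()]

    def __len__(self) -> int:
        return len(self.mapping)


def _read_header_fields(path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        first_data = fh.readline().rstrip("\n")
    fields = header.split("\t")
    n_data = len(first_data.split("\t")) if first_data else len(fields)
    # header may or may not carry a corner cell above the feature-id column
    return fields[1:] if len(fields) == n_data else fields


def read_matrix(path, scale: str, phenotype_path) -> ExpressionDataset:
    """Read a tab-delimited expression matrix plus its phenotype sidecar.

    Raises on duplicated sample ids, non-numeric cells (naming the offending
    row and column) and samples missing from the phenotype file.  Duplicate
    feature ids in a log2-scale matrix are collapsed by their arithmetic mean
    (the same rule used for multi-probe genes) with a warning; on the linear
    scale they are an error.
    """
    sample_fields = _read_header_fields(path)
    seen: set[str] = set()
    for s in sample_fields:
        if s in seen:
            raise ValueError(f"duplicated sample id in header: {s!r}")
        seen.add(s)

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = sample_fields
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value {df.at[row, col]!r} at feature {row!r}, sample {col!r}"
            )
    df = df.astype(float)

    if df.index.has_duplicates:
        if scale == LOG2:
            n_before = len(df)
            df = df.groupby(level=0, sort=True).mean()
            logger.warning(
                "collapsed %d duplicate feature rows by log2-scale mean",
                n_before - len(df),
            )
        else:
            dups = df.index[df.index.duplicated()].unique()
            raise ValueError(
                f"duplicate feature ids on linear scale: {list(dups[:5])}"
            )

    phen = read_phenotype(phenotype_path)
    missing = df.columns.difference(phen.index)
    if len(missing) > 0:
        raise ValueError(f"no phenotype label for samples: {list(missing[:5])}")
    ds = ExpressionDataset(df, scale, phen)
    logger.info("read %d features x %d samples from %s", ds.n_genes, ds.n_samples, path)
    return ds


def write_matrix(dataset: ExpressionDataset, path, phenotype_path=None) -> None:
    """Write a dataset back to tab-delimited text (and optionally its labels)."""
    dataset.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    if phenotype_path is not None:
        write_phenotype(dataset.phenotype, phenotype_path)


def read_phenotype(path) -> pd.Series:
    """Read a two-column (sample_id, label) tab-delimited file, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicated sample ids in phenotype file: {list(dups[:5])}")
    return pd.Series(df["label"].to_numpy(), index=pd.Index(df["sample_id"], name="sample_id"))


def write_phenotype(phenotype: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": phenotype.index, "label": phenotype.to_numpy()}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_probe_map(path) -> ProbeGeneMap:
    """Read a two-column (probe_id, gene_id) tab-delimited file, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_id"], dtype=str)
    return ProbeGeneMap(pd.Series(df["gene_id"].to_numpy(), index=pd.Index(df["probe_id"])))


def collapse_probes(dataset: ExpressionDataset, probe_map: ProbeGeneMap) -> ExpressionDataset:
    """Collapse probe-level rows to genes by the arithmetic mean of log2 values.

    Multiple probes matched to one gene are averaged per sample on the log2
    scale; probes absent from the map are dropped (counted in the log); map
    entries for probes not present in the matrix are ignored with a warning.
    """
    if dataset.scale != LOG2:
        raise ValueError("probe collapsing is defined on the log2 scale")
    if len(probe_map) == 0:
        raise ValueError("probe map is empty")

    absent = probe_map.mapping.index.difference(dataset.gene_ids)
    if len(absent) > 0:
        logger.warning("%d probe-map entries reference absent probes; ignored", len(absent))
    mapped = dataset.gene_ids.intersection(probe_map.mapping.index)
    n_unmapped = dataset.n_genes - len(mapped)
    if n_unmapped > 0:
        logger.info("dropping %d unmapped probes", n_unmapped)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the map")

    sub = dataset.values.loc[mapped]
    genes = probe_map.mapping.loc[mapped].to_numpy()
    collapsed = sub.groupby(genes, sort=True).mean()
    collapsed.index.name = "gene_id"
    return ExpressionDataset(collapsed, LOG2, dataset.phenotype)


def to_linear(dataset: ExpressionDataset) -> ExpressionDataset:
    """Anti-log a log2-scale dataset (each value v becomes 2**v)."""
    if dataset.scale != LOG2:
        raise ValueError("to_linear expects a log2-scale dataset (no double transform)")
    return ExpressionDataset(np.exp2(dataset.values), LINEAR, dataset.phenotype)


def to_log2(dataset: ExpressionDataset) -> ExpressionDataset:
    """Log2-transform a linear-scale dataset; zero intensities are invalid."""
    if dataset.scale != LINEAR:
        raise ValueError("to_log2 expects a linear-scale dataset (no double transform)")
    if (dataset.values.to_numpy() <= 0).any():
        raise ValueError("non-positive intensities cannot be log2-transformed")
    return ExpressionDataset(np.log2(dataset.values), LOG2, dataset.phenotype)
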