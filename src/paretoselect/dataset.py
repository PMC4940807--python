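"""Expression dataset container and plain-TSV input.

An :class:`ExpressionDataset` is a probes x samples real matrix (NaN marks
missing values) with per-sample annotations such as disease state, smoking
status and gender.  Datasets come either from a GEO SOFT/GDS file
(:mod:`paretoselect.geo`) or from a TSV matrix with an annotation sidecar.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd


def normalize_label(text: str) -> str:
    """Lower-case, trim and unify separators so 'disease.state',
    'Disease State' and 'disease_state' all compare equal."""
    return str(text).strip().lower().replace(".", " ").replace("_", " ")


@dataclasses.dataclass
class ExpressionDataset:
    """Probe-level expression matrix plus sample annotations.

    Parameters
    ----------
    probe_ids : list of str
        Unique row labels.
    gene_symbols : list of str
        Per-row gene symbol, may be blank; carried for reporting only
        (no collapsing of multiple probes per gene).
    sample_ids : list of str
        Unique column labels.
    values : ndarray (n_probes, n_samples)
        Expression values exactly as stored in the source file; NaN = missing.
    sample_annotations : DataFrame indexed by sample id
        One column per annotation key (normalized), string values.
    """

    probe_ids: list
    gene_symbols: list
    sample_ids: list
    values: np.ndarray
    sample_annotations: pd.DataFrame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n, m = self.values.shape
        if len(self.probe_ids) != n:
            raise ValueError(f"{len(self.probe_ids)} probe ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        if len(set(self.probe_ids)) != n:
            raise ValueError("duplicated probe ids")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicated sample ids")
        if not self.gene_symbols:
            self.gene_symbols = [""] * n
        if len(self.gene_symbols) != n:
            raise ValueError("gene_symbols length mismatch")
        missing = set(self.sample_ids) - set(self.sample_annotations.index)
        if self.sample_annotations.shape[1] and missing:
            raise ValueError(f"samples without annotations: {sorted(missing)[:5]}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id: {exc.args[0]}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids,
                            columns=self.sample_ids)


def read_expression_tsv(path, annotations_path: Optional[str] = None) -> ExpressionDataset:
    """Read a genes x samples TSV matrix.

    Layout: first column ``probe_id``; an optional second column
    ``gene_symbol``; remaining columns are samples.  Empty cells or the
    literal ``null`` are missing values.

    ``annotations_path`` points to a sidecar TSV whose header row is
    ``annotation`` followed by the sample ids and whose data rows are one
    annotation key followed by its per-sample values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected probe ids plus sample columns")
    probe_ids = df.iloc[:, 0].tolist()
    rest = df.iloc[:, 1:]
    if rest.columns[0].lower() in ("gene_symbol", "identifier", "symbol"):
        gene_symbols = rest.iloc[:, 0].fillna("").tolist()
        rest = rest.iloc[:, 1:]
    else:
        gene_symbols = [""] * len(probe_ids)
    sample_ids = list(rest.columns)
    values = (rest.replace({"null": np.nan, "": np.nan})
                  .apply(pd.to_numeric, errors="raise").to_numpy(dtype=np.float64))

    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", dtype=str, index_col=0)
        ann = ann.T  # rows become samples, columns annotation keys
        ann.columns = [normalize_label(c) for c in ann.columns]
        ann = ann.reindex(sample_ids)
    else:
        ann = pd.DataFrame(index=pd.Index(sample_ids))
    return ExpressionDataset(probe_ids, gene_symbols, sample_ids, values, ann)


def write_expression_tsv(dataset: ExpressionDataset, path,
                         annotations_path: Optional[str] = None) -> None:
    """Inverse of :func:`read_expression_tsv`."""
    df = dataset.to_frame()
    df.insert(0, "gene_symbol", dataset.gene_symbols)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="null")
    if annotations_path is not None:
        ann = dataset.sample_annotations.reindex(dataset.sample_ids).T
        ann.index.name = "annotation"
        ann.to_csv(annotations_path, sep="\t")
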