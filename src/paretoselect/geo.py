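"""GEO SOFT/GDS file reading, sample-subset selection and report I/O.

A GDS SOFT file is plain text: ``^ENTITY`` lines open entities, ``!key =
value`` lines carry metadata, ``#`` lines declare table columns, and the
expression table sits between ``!dataset_table_begin`` and
``!dataset_table_end`` with an ``ID_REF``/``IDENTIFIER`` header.  Curated
``^SUBSET`` entities assign samples to annotation categories (disease state,
stress/smoking status, gender, ...); these become the dataset's
sample annotations.

No network access: users supply the downloaded SOFT file.
"""

from __future__ import annotations

import io
import warnings
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, normalize_label
from .frontier import CriteriaTable, FrontierResult

#: Sample-group shorthand used for the lung-cancer smoking study (GDS3257):
#: H = healthy control, C = cancer; NS = never smoker, CS = current smoker.
#: "Former smoker" samples exist in that dataset but belong to no shorthand
#: group and are simply never selected by these filters.
GDS3257_GROUPS: Dict[str, Dict[str, str]] = {
    "HNS": {"disease state": "control", "stress": "never smoked"},
    "HCS": {"disease state": "control", "stress": "currently smoking"},
    "CNS": {"disease state": "lung cancer", "stress": "never smoked"},
    "CCS": {"disease state": "lung cancer", "stress": "currently smoking"},
}


def read_gds_soft(path) -> ExpressionDataset:
    """Parse a GDS-dialect SOFT file into an :class:`ExpressionDataset`.

    Subset blocks become sample annotations; ``null`` or empty table cells
    become NaN.  Line endings may be LF or CRLF.
    """
    subsets = []        # (type, description, [sample ids])
    table_lines = []
    in_table = False
    current: Optional[dict] = None

    with open(path, "r", encoding="utf-8", errors="replace", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if in_table:
                if line.startswith("!dataset_table_end"):
                    in_table = False
                    continue
                table_lines.append(line)
                continue
            if line.startswith("^SUBSET"):
                current = {}
                subsets.append(current)
            elif line.startswith("^"):
                current = None
            elif line.startswith("!dataset_table_begin"):
                in_table = True
            elif line.startswith("!") and current is not None and "=" in line:
                key, _, value = line[1:].partition("=")
                current[key.strip().lower()] = value.strip()

    if not table_lines:
        raise ValueError(f"{path}: no !dataset_table_begin/_end data table found")

    try:
        df = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", dtype=str)
    except Exception as exc:
        raise ValueError(f"{path}: unparseable data table: {exc}") from exc
    if df.shape[1] < 3 or df.columns[0].upper() != "ID_REF":
        raise ValueError(f"{path}: data table must start with ID_REF, IDENTIFIER "
                         f"and at least one sample column")
    bad = df.iloc[:, 0].isna()
    if bad.any():
        raise ValueError(f"{path}: unparseable data row "
                         f"{int(np.flatnonzero(bad)[0]) + 2} of the table")

    probe_ids = df.iloc[:, 0].tolist()
    if len(set(probe_ids)) != len(probe_ids):
        dup = pd.Series(probe_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated probe id {dup!r}")
    has_identifier = df.columns[1].upper() == "IDENTIFIER"
    gene_symbols = df.iloc[:, 1].fillna("").tolist() if has_identifier else None
    data = df.iloc[:, 2 if has_identifier else 1:]
    sample_ids = list(data.columns)
    cleaned = data.replace({"null": np.nan, "": np.nan})
    values = cleaned.apply(pd.to_numeric, errors="coerce").to_numpy(np.float64)
    garbled = np.isnan(values) & cleaned.notna().to_numpy()
    if garbled.any():
        i, j = np.argwhere(garbled)[0]
        raise ValueError(
            f"{path}: unparseable value {cleaned.iat[i, j]!r} in data-table row "
            f"{i + 2} (probe {probe_ids[i]!r}, sample {sample_ids[j]!r})")

    ann = pd.DataFrame(index=pd.Index(sample_ids), dtype=object)
    known = set(sample_ids)
    for sub in subsets:
        key = normalize_label(sub.get("subset_type", ""))
        value = sub.get("subset_description", "").strip()
        members = [s.strip() for s in sub.get("subset_sample_id", "").split(",")
                   if s.strip()]
        unknown = set(members) - known
        if unknown:
            raise ValueError(f"{path}: subset {value!r} references unknown "
                             f"sample ids {sorted(unknown)[:5]}")
        if key not in ann.columns:
            ann[key] = ""
        ann.loc[members, key] = value

    return ExpressionDataset(probe_ids, gene_symbols or [""] * len(probe_ids),
                             sample_ids, values, ann)


def select_samples(dataset: ExpressionDataset,
                   filters: Dict[str, str]) -> list:
    """Sample ids matching ALL annotation filters, in dataset column order.

    Keys and values are compared after normalization (lower-case, trimmed,
    separators unified), so ``disease.state=Lung Cancer`` matches a subset
    typed ``disease state`` with description ``lung cancer``.
    """
    ann = dataset.sample_annotations
    norm_cols = {normalize_label(c): c for c in ann.columns}
    keep = pd.Series(True, index=ann.index)
    for key, value in filters.items():
        nkey = normalize_label(key)
        if nkey not in norm_cols:
            raise KeyError(f"unknown annotation key {key!r}; available: "
                           f"{sorted(norm_cols)}")
        col = ann[norm_cols[nkey]].map(normalize_label)
        keep &= col == normalize_label(value)
    selected = [s for s in dataset.sample_ids if keep.get(s, False)]
    if not selected:
        warnings.warn(f"no samples match filters {filters}", stacklevel=2)
    return selected


# ---------------------------------------------------------------------------
# frontier reports


REPORT_COLUMNS = ["id", "beta", "layer", "on_frontier", "duplicate_group"]


def write_frontier_report(results, criteria: CriteriaTable, path,
                          metadata: Optional[dict] = None) -> None:
    """Write a TSV frontier report.

    ``results`` is a single :class:`FrontierResult` or the list produced by
    frontier peeling.  One row per alternative of ``criteria``: its layer-0
    beta, the peel layer at which it reached a frontier (-1 if none within
    the computed layers), an ``on_frontier`` 0/1 flag for the first frontier,
    and its duplicate-group index (empty if its criteria vector is unique).
    Run metadata goes into ``#``-prefixed header lines.
    """
    if isinstance(results, FrontierResult):
        results = [results]
    layer_of = {}
    for res in results:
        for gid in res.frontier_ids:
            layer_of.setdefault(gid, res.layer)
    beta = results[0].beta if results else None
    dup_of = {}
    if results:
        for g, group in enumerate(results[0].duplicate_groups):
            for gid in group:
                dup_of[gid] = g

    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        if not results:
            return
        for gid in criteria.ids:
            b = "" if beta is None else repr(float(beta[gid]))
            layer = layer_of.get(gid, -1)
            dup = dup_of.get(gid, "")
            fh.write(f"{gid}\t{b}\t{layer}\t{int(layer == 0)}\t{dup}\n")


def read_frontier_report(path) -> pd.DataFrame:
    """Read a report written by :func:`write_frontier_report`."""
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"id": str, "duplicate_group": "Int64"})
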