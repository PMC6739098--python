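"""Readers, writers and the shared data model.

The pipeline moves four kinds of objects between stages:

``TaxonTable``
    an integer count matrix (samples x taxa) with optional ranked taxonomy,
    as produced by 16S amplicon pipelines (mothur "shared" files or plain
    wide CSV).
``SampleMetadata``
    per-sample blocking information: lake system and the site-by-year
    ``group_id`` used to build leave-one-group-out folds.
``FcmSample``
    one flow-cytometry replicate: an event table with green (FL1) and red
    (FL3) fluorescence per event on the instrument scale, plus the analysed
    volume in ml.
``TargetVector``
    a sample-aligned response (HNA/LNA cell concentrations in cells/ml,
    or productivity).

All writers emit UTF-8, newline-terminated CSV/TSV with a header row, and a
write followed by a read reproduces integer tables bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "otu")

__all__ = [
    "TaxonTable",
    "SampleMetadata",
    "FcmSample",
    "TargetVector",
    "read_taxon_table",
    "write_taxon_table",
    "read_metadata",
    "read_targets",
    "read_fcm_events",
    "write_fcm_events",
    "align",
]


class FormatError(ValueError):
    """A file does not parse under its declared dialect."""


@dataclass
class TaxonTable:
    """Sample x taxon count matrix with optional ranked taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = sample ids, columns = taxon ids.
    taxonomy : pandas.DataFrame or None
        One row per taxon (index matching ``counts.columns``), columns are
        taxonomic ranks ordered coarse to fine, e.g. phylum ... genus/otu.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)):
                raise FormatError("counts must be finite")
            if np.any(arr != np.floor(arr)):
                raise FormatError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise FormatError("counts must be non-negative")
        if self.taxonomy is not None:
            tax = self.taxonomy.reindex(c.columns)
            if tax.isna().all(axis=1).any():
                missing = tax.index[tax.isna().all(axis=1)].tolist()
                raise FormatError(f"taxonomy missing for taxa: {missing[:5]}")
            self.taxonomy = tax

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SampleMetadata:
    """Per-sample blocking metadata (lake system and site-by-year group)."""

    frame: pd.DataFrame  # index = sample_id; columns include lake_system, group_id

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("lake_system", "group_id"):
            if col not in f.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dups}")

    @property
    def groups(self) -> pd.Series:
        return self.frame["group_id"]


@dataclass
class FcmSample:
    """One flow-cytometry replicate: events on the instrument scale."""

    sample_id: str
    replicate_id: str
    events: pd.DataFrame  # columns FL1, FL3
    volume_ml: float

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in ("FL1", "FL3") if c not in ev.columns]
        if missing:
            raise FormatError(
                f"event table missing channel(s) {missing}; available: {list(ev.columns)}"
            )
        self.events = ev[["FL1", "FL3"]].astype(float)
        if len(self.events) < 1:
            raise FormatError(f"no events in sample {self.sample_id}/{self.replicate_id}")
        if not np.all(np.isfinite(self.events.to_numpy())):
            raise FormatError("non-finite channel values")
        if not (self.volume_ml > 0):
            raise ValueError("volume_ml must be positive")

    @property
    def n_events(self) -> int:
        return len(self.events)


TargetVector = pd.Series  # sample_id-indexed real response


# ---------------------------------------------------------------------------
# taxon tables


def read_taxon_table(
    path: str | Path,
    format: str = "wide_csv",
    taxonomy_path: str | Path | None = None,
) -> TaxonTable:
    """Read a count table.

    ``format="shared_tsv"`` accepts mothur shared-style files whose first
    columns are ``label``/``Group``/``numOtus`` (case-insensitive; the
    ``label``/``numOtus`` columns are optional).  ``format="wide_csv"`` is a
    plain CSV whose first column holds sample ids.  Row and column order are
    preserved.  ``taxonomy_path`` points to an optional two-column CSV/TSV
    (taxon id, semicolon-separated lineage).
    """
    path = Path(path)
    if format == "shared_tsv":
        df = pd.read_csv(path, sep="\t")
        lower = {c.lower(): c for c in df.columns}
        if "group" not in lower:
            raise FormatError(f"{path}: shared file lacks a Group column")
        df = df.set_index(lower["group"])
        drop = [lower[c] for c in ("label", "numotus") if c in lower]
        df = df.drop(columns=drop)
    elif format == "wide_csv":
        df = pd.read_csv(path, index_col=0)
    else:
        raise ValueError(f"unknown format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = _read_taxonomy(taxonomy_path)
    return TaxonTable(df, taxonomy)


def _read_taxonomy(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".taxonomy") else ","
    raw = pd.read_csv(path, sep=sep, index_col=0)
    lineage_col = raw.columns[-1]
    split = raw[lineage_col].astype(str).str.rstrip(";").str.split(";", expand=True)
    split.columns = list(RANKS[: split.shape[1]])
    split.index = raw.index.astype(str)
    return split


def write_taxon_table(table: TaxonTable, path: str | Path) -> None:
    """Write counts as wide CSV (round-trips bit-exactly through read)."""
    table.counts.to_csv(path, index_label="sample_id", lineterminator="\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata needs a sample_id column")
    return SampleMetadata(df.set_index("sample_id"))


def read_targets(path: str | Path, column: str) -> TargetVector:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns or column not in df.columns:
        raise FormatError(f"{path}: needs sample_id and {column!r} columns")
    s = df.set_index("sample_id")[column].astype(float)
    n_missing = int(s.isna().sum())
    if n_missing:
        logger.warning("dropping %d samples with missing %s", n_missing, column)
        s = s.dropna()
    s.name = column
    return s


# ---------------------------------------------------------------------------
# cytometry events


_CHANNEL_ALIASES = {"FL1": ("FL1", "FL1-H", "FL1-A"), "FL3": ("FL3", "FL3-H", "FL3-A")}


def _pick_channels(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for canon, aliases in _CHANNEL_ALIASES.items():
        hit = next((a for a in aliases if a in df.columns), None)
        if hit is None:
            raise FormatError(
                f"missing channel {canon}; available columns: {list(df.columns)}"
            )
        out[canon] = df[hit].astype(float)
    return pd.DataFrame(out)


def read_fcm_events(
    path: str | Path,
    format: str = "csv",
    sample_id: str | None = None,
    replicate_id: str = "r1",
    volume_ml: float | None = None,
) -> FcmSample:
    """Read one replicate's event table (CSV or FCS 3.0/3.1).

    CSV files need FL1/FL3 columns (``-H``/``-A`` suffixes accepted) and may
    carry the analysed volume in a ``volume_ml`` column (constant per file);
    otherwise pass ``volume_ml`` explicitly.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if format == "csv":
        df = pd.read_csv(path)
        if len(df) == 0:
            raise FormatError(f"{path}: no events")
        if volume_ml is None and "volume_ml" in df.columns:
            volume_ml = float(df["volume_ml"].iloc[0])
        events = _pick_channels(df)
    elif format == "fcs":
        events, text = _read_fcs(path)
        if volume_ml is None and "$VOL" in text:
            volume_ml = float(text["$VOL"]) / 1e3  # $VOL is in microliters
    else:
        raise ValueError(f"unknown format {format!r}")
    if volume_ml is None:
        raise ValueError(f"{path}: analysed volume not found; pass volume_ml")
    return FcmSample(sample_id, replicate_id, events, volume_ml)


def write_fcm_events(sample: FcmSample, path: str | Path) -> None:
    df = sample.events.copy()
    df["volume_ml"] = sample.volume_ml
    df.to_csv(path, index=False, lineterminator="\n")


def _read_fcs(path: Path) -> tuple[pd.DataFrame, dict]:
    """Minimal FCS 3.0/3.1 reader: list-mode F/D/I data, both byte orders."""
    blob = path.read_bytes()
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    text_beg, text_end = int(blob[10:18]), int(blob[18:26])
    text = blob[text_beg : text_end + 1].decode("utf-8", "replace")
    delim = text[0]
    parts = text[1:].split(delim)
    kv = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    dtype_code = kv["$DATATYPE"].strip().upper()
    byteord = kv.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")
    data_beg = int(kv.get("$BEGINDATA") or blob[26:34])
    data_end = int(kv.get("$ENDDATA") or blob[34:42])
    raw = blob[data_beg : data_end + 1]
    order = "<" if little else ">"
    if dtype_code == "F":
        np_dtype = np.dtype(order + "f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(order + "f8")
    elif dtype_code == "I":
        bits = {int(kv[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1:
            raise FormatError("mixed-width integer FCS data not supported")
        np_dtype = np.dtype(order + f"u{bits.pop() // 8}")
    else:
        raise FormatError(f"unsupported $DATATYPE {dtype_code!r}")
    arr = np.frombuffer(raw[: n_tot * n_par * np_dtype.itemsize], dtype=np_dtype)
    arr = arr.reshape(n_tot, n_par).astype(float)
    names = [kv.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    df = _pick_channels(pd.DataFrame(arr, columns=names))
    return df, kv


def write_fcs(sample: FcmSample, path: str | Path) -> None:
    """Write a minimal single-dataset FCS 3.0 file (float data, little-endian).

    Used to exercise the FCS reading path without shipping binary fixtures.
    """
    ev = sample.events.to_numpy(dtype=np.float32)
    n_tot, n_par = ev.shape
    names = list(sample.events.columns)
    data = ev.astype("<f4").tobytes()
    # build TEXT with placeholder offsets, then patch
    def text_segment(beg: int, end: int) -> bytes:
        pairs = {
            "$DATATYPE": "F",
            "$MODE": "L",
            "$BYTEORD": "1,2,3,4",
            "$PAR": str(n_par),
            "$TOT": str(n_tot),
            "$NEXTDATA": "0",
            "$BEGINDATA": str(beg),
            "$ENDDATA": str(end),
            "$VOL": str(sample.volume_ml * 1e3),
        }
        for i, name in enumerate(names, start=1):
            pairs[f"$P{i}N"] = name
            pairs[f"$P{i}B"] = "32"
            pairs[f"$P{i}R"] = "262144"
            pairs[f"$P{i}E"] = "0,0"
        body = "/" + "/".join(f"{k}/{v}" for k, v in pairs.items()) + "/"
        return body.encode("ascii")

    header_len = 58
    text = text_segment(0, 0)
    # iterate once: text length changes as offsets gain digits
    for _ in range(3):
        text_beg = header_len
        text_end = text_beg + len(text) - 1
        data_beg = text_end + 1
        data_end = data_beg + len(data) - 1
        new_text = text_segment(data_beg, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    header = (
        b"FCS3.0    "
        + f"{text_beg:8d}{text_end:8d}{data_beg:8d}{data_end:8d}{0:8d}{0:8d}".encode()
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + data)


# ---------------------------------------------------------------------------
# alignment


def align(
    table: TaxonTable,
    meta: SampleMetadata,
    targets: TargetVector,
) -> tuple[TaxonTable, SampleMetadata, TargetVector, list[str]]:
    """Restrict all three inputs to their shared samples, in canonical order.

    Canonical order is lexicographic by sample id, so the result is invariant
    to input row permutations.  Returns the aligned triple plus the sorted
    list of dropped sample ids (logged as a warning when non-empty).
    """
    ids = (
        set(table.counts.index) & set(meta.frame.index) & set(targets.index)
    )
    if not ids:
        raise ValueError("no shared sample ids between counts, metadata and targets")
    order = sorted(ids)
    dropped = sorted(
        (set(table.counts.index) | set(meta.frame.index) | set(targets.index)) - ids
    )
    if dropped:
        logger.warning("align: dropping %d unmatched samples: %s", len(dropped), dropped)
    aligned_table = TaxonTable(table.counts.loc[order], table.taxonomy)
    aligned_meta = SampleMetadata(meta.frame.loc[order])
    aligned_targets = targets.loc[order]
    return aligned_table, aligned_meta, aligned_targets, dropped
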