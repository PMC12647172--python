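"""Genomic interval, coverage-track, and tabular I/O.

All coordinates are 0-based half-open (BED convention).  Coverage and score
tracks are held as fixed-width bin arrays per contig and serialized as
fixed-step bedGraph text.  Tabular inputs (intron-retention tables, splicing
event tables, clinical survival tables, proteomics tables, feature matrices)
are pandas DataFrames validated against a named schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "read_intervals",
    "write_intervals",
    "read_table",
    "write_table",
    "extract_counts",
    "average_speckle_score",
    "BedParseError",
    "SchemaError",
]

_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised on a malformed BED line; message names the offending line."""


class SchemaError(ValueError):
    """Raised when a table does not conform to its declared schema."""


@dataclass(frozen=True)
class GenomicInterval:
    """Strand-aware 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.id is None:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_intervals(path) -> list[GenomicInterval]:
    """Parse a BED file (>=3 columns) into a list of intervals.

    Coordinates are kept verbatim (0-based half-open).  A missing strand
    column yields strand ".", a missing name column yields the auto id
    ``chrom:start-end``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from None
            name = f[3] if len(f) > 3 and f[3] not in ("", ".") else None
            strand = f[5] if len(f) > 5 else "."
            try:
                out.append(GenomicInterval(f[0], start, end, strand, name))
            except ValueError as e:
                raise BedParseError(f"line {lineno}: {e}") from None
    ids = [iv.id for iv in out]
    if len(set(ids)) != len(ids):
        raise BedParseError("duplicate interval ids in annotation set")
    return out


def write_intervals(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t.\t{iv.strand}\n")


@dataclass
class CoverageTrack:
    """Fixed-bin-width coverage (or score) arrays keyed by contig.

    ``data`` maps contig name to a 1-D array; bin i covers
    ``[i*bin_width, (i+1)*bin_width)``.  For read-count tracks
    ``total_reads`` equals the grand sum of all bins; score tracks may hold
    floats and NaN for no-data bins.
    """

    bin_width: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.data = {c: np.asarray(a) for c, a in self.data.items()}

    @property
    def total_reads(self) -> float:
        return float(sum(np.nansum(a) for a in self.data.values()))

    @property
    def genome_length(self) -> int:
        return sum(a.size * self.bin_width for a in self.data.values())

    def contig_length(self, chrom: str) -> int:
        return self.data[chrom].size * self.bin_width

    def weighted_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of bin values over [start, end), partial bins weighted by
        overlap fraction.  NaN bins contribute nothing."""
        if chrom not in self.data:
            raise KeyError(f"contig {chrom!r} not in track")
        arr = self.data[chrom]
        bw = self.bin_width
        start = max(start, 0)
        end = min(end, arr.size * bw)
        if start >= end:
            return 0.0
        b0, b1 = start // bw, (end - 1) // bw
        if b0 == b1:
            v = arr[b0]
            return 0.0 if np.isnan(v) else float(v) * (end - start) / bw
        total = 0.0
        v0 = arr[b0]
        if not np.isnan(v0):
            total += float(v0) * ((b0 + 1) * bw - start) / bw
        mid = arr[b0 + 1 : b1]
        total += float(np.nansum(mid))
        v1 = arr[b1]
        if not np.isnan(v1):
            total += float(v1) * (end - b1 * bw) / bw
        return total

    def mean_score(self, chrom: str, start: int, end: int) -> float:
        """Mean bin value over the interval, NaN bins excluded; NaN if the
        interval has no data at all."""
        if chrom not in self.data:
            raise KeyError(f"contig {chrom!r} not in track")
        arr = self.data[chrom]
        bw = self.bin_width
        b0 = max(start // bw, 0)
        b1 = min((end - 1) // bw + 1, arr.size)
        if b0 >= b1:
            return float("nan")
        window = arr[b0:b1]
        if np.isnan(window).all():
            return float("nan")
        return float(np.nanmean(window))

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                arr = self.data[chrom]
                bw = self.bin_width
                for i, v in enumerate(arr):
                    if np.isnan(v):
                        continue
                    val = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{i * bw}\t{(i + 1) * bw}\t{val}\n")

    @classmethod
    def from_bedgraph(cls, path, bin_width: int, dtype=float) -> "CoverageTrack":
        """Read a fixed-step bedGraph whose lines align to ``bin_width``."""
        ends: dict[str, int] = {}
        rows: dict[str, list[tuple[int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split("\t")
                s, e = int(s), int(e)
                if s % bin_width or (e - s) != bin_width:
                    raise ValueError(f"bedGraph line not aligned to {bin_width} bp bins: {line!r}")
                rows.setdefault(chrom, []).append((s // bin_width, float(v)))
                ends[chrom] = max(ends.get(chrom, 0), e)
        data = {}
        for chrom, entries in rows.items():
            arr = np.full(ends[chrom] // bin_width, np.nan if dtype is float else 0, dtype=dtype)
            if dtype is float:
                arr[:] = 0.0
            for i, v in entries:
                arr[i] = v
            data[chrom] = arr
        return cls(bin_width=bin_width, data=data)


def extract_counts(track: CoverageTrack, intervals) -> np.ndarray:
    """Per-interval read counts: bin sums with partial-bin overlap weighting,
    rounded half-up to integers."""
    out = np.empty(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        if iv.chrom not in track.data:
            raise KeyError(f"interval {iv.id} on unknown contig {iv.chrom!r}")
        out[i] = int(np.floor(track.weighted_sum(iv.chrom, iv.start, iv.end) + 0.5))
    return out


def average_speckle_score(tracks, intervals) -> np.ndarray:
    """Per-interval mean of per-track within-interval mean scores.

    Mirrors the compilation of many normalized speckle-proximity (SON
    TSA-seq) score tracks into one average score per gene.  A track with no
    data over an interval is excluded from that interval's mean; an interval
    with no data in any track yields NaN.
    """
    if not tracks:
        raise ValueError("at least one score track required")
    mat = np.full((len(intervals), len(tracks)), np.nan)
    for j, tr in enumerate(tracks):
        for i, iv in enumerate(intervals):
            if iv.chrom in tr.data:
                mat[i, j] = tr.mean_score(iv.chrom, iv.start, iv.end)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mat, axis=1)


# --- typed tables -----------------------------------------------------------

_EVENT_TYPES = {"RI", "SE", "A5SS", "A3SS", "MXE"}


def _check_unit(df, cols, schema):
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise SchemaError(f"{schema}: column {c!r} outside [0, 1]")


def _validate_ir(df):
    _check_unit(df, [c for c in df.columns if c.startswith("ir_")], "ir")
    for c in df.columns:
        if c.startswith(("flank5_", "flank3_")) and (df[c].to_numpy(dtype=float) < 0).any():
            raise SchemaError("ir: negative flanking read support")


def _validate_events(df):
    bad = set(df["event_type"]) - _EVENT_TYPES
    if bad:
        raise SchemaError(f"events: unknown event type(s) {sorted(bad)}")
    if (df["delta_psi"].abs() > 1).any():
        raise SchemaError("events: |delta_psi| > 1")
    _check_unit(df, ["fdr"] + [c for c in df.columns if c.startswith("psi_")], "events")


def _validate_survival(df):
    if (df["time"].to_numpy(dtype=float) < 0).any():
        raise SchemaError("survival: negative time")
    if not set(df["event"].astype(int)) <= {0, 1}:
        raise SchemaError("survival: event flag must be 0/1")


def _validate_proteomics(df):
    for c in df.columns:
        if c.startswith(("intensity_", "peptides_")) and (df[c].to_numpy(dtype=float) < 0).any():
            raise SchemaError(f"proteomics: negative values in {c!r}")


SCHEMAS: dict[str, tuple[tuple[str, ...], object]] = {
    "ir": (("transcript_id", "chrom", "start", "end", "ir_control"), _validate_ir),
    "events": (("event_id", "event_type", "delta_psi", "fdr"), _validate_events),
    "survival": (("sample_id", "time", "event", "subtype"), _validate_survival),
    "proteomics": (("protein_id",), _validate_proteomics),
    "features": (("row_id",), None),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV into a validated DataFrame for one of the named schemas
    (``ir``, ``events``, ``survival``, ``proteomics``, ``features``).
    Extra columns are passed through untouched."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    required, validator = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{schema}: file has no header row") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing required column(s) {missing}")
    if len(df) and validator is not None:
        try:
            validator(df)
        except (TypeError, ValueError) as e:
            if isinstance(e, SchemaError):
                raise
            raise SchemaError(f"{schema}: unparseable value ({e})") from None
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
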