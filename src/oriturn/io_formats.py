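"""Readers, writers and domain containers for every external format.

All coordinates in this package are 0-based, half-open (BED convention).
Records coming from 1-based inclusive sources must be shifted at the parser
boundary, exactly once; nothing downstream ever converts coordinates again.

Formats handled here:

* BED3/BED5 for generic intervals and mappability masks;
* FASTA for genome sequences (via Biopython);
* a TSV dialect for polarized variant tables
  (``chrom  pos  ancestral  derived  [daf]``);
* a TSV dialect for pairwise homology maps of co-linear conserved genomic
  segments (``chromA startA endA chromB startB endB orientation``);
* bedGraph for per-base score tracks and binned read counts;
* BED-like TSV for origin sets (BED5 plus a peak column).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRef",
    "ReadTrack",
    "Interval",
    "OriginSet",
    "HomologyMap",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_variant_table",
    "write_variant_table",
    "read_homology_map",
    "write_homology_map",
    "read_bedgraph",
    "write_bedgraph",
    "read_read_track",
    "write_read_track",
    "read_origins",
    "write_origins",
    "merge_interval_array",
    "interval_array",
]

_IUPAC = set("ACGTNRYSWKMBDHV")
_TO_ACGTN = str.maketrans({c: "N" for c in "RYSWKMBDHV"})


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# interval array helpers (numpy (n, 2) arrays of half-open intervals)
# ---------------------------------------------------------------------------

def from_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive coordinate pair to 0-based half-open.

    The single sanctioned conversion point: parsers for 1-based dialects
    call this exactly once, and nothing downstream converts again.
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based inclusive record {start}..{end}")
    return start - 1, end


def interval_array(pairs: Iterable[tuple[int, int]]) -> np.ndarray:
    """Build a sorted, validated (n, 2) int64 array of half-open intervals."""
    arr = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
    if arr.size:
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        if np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError("interval with start >= end")
    return arr


def merge_interval_array(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping or touching intervals in a sorted (n, 2) array."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_interval_length(arr: np.ndarray) -> int:
    return int((arr[:, 1] - arr[:, 0]).sum()) if len(arr) else 0


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeRef:
    """A reference genome: sequences, lengths and mappability mask.

    ``mappable`` maps chromosome name to a sorted, non-overlapping (n, 2)
    array of half-open intervals; every analysis that samples or normalizes
    by genomic space restricts itself to these intervals.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str]
    mappable: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            L = self.chrom_lengths[name]
            if len(self.sequence[name]) != L:
                raise ValueError(
                    f"{name}: sequence length {len(self.sequence[name])} "
                    f"!= declared length {L}"
                )
            arr = np.asarray(
                self.mappable.get(name, np.empty((0, 2), dtype=np.int64)),
                dtype=np.int64,
            ).reshape(-1, 2)
            if len(arr):
                if arr[:, 0].min() < 0 or arr[:, 1].max() > L:
                    raise ValueError(f"{name}: mappable interval outside [0, {L})")
                if np.any(arr[:, 0] >= arr[:, 1]):
                    raise ValueError(f"{name}: empty mappable interval")
                if np.any(np.diff(arr[:, 0]) < 0) or np.any(arr[1:, 0] < arr[:-1, 1]):
                    raise ValueError(f"{name}: mappable intervals unsorted/overlapping")
            self.mappable[name] = arr

    # -- convenience -------------------------------------------------------
    def mappable_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return total_interval_length(self.mappable[chrom])
        return sum(total_interval_length(self.mappable[c]) for c in self.chrom_names)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), clipped to the chromosome."""
        L = self.chrom_lengths[chrom]
        return self.sequence[chrom][max(0, start):min(L, end)]

    def mappable_mask(self, chrom: str) -> np.ndarray:
        """Boolean per-bp mappability vector for one chromosome."""
        mask = np.zeros(self.chrom_lengths[chrom], dtype=bool)
        for s, e in self.mappable[chrom]:
            mask[s:e] = True
        return mask


@dataclass
class ReadTrack:
    """Per-chromosome sorted arrays of 0-based read 5' positions."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) < 0):
                pos = np.sort(pos)
            if len(pos) and pos[0] < 0:
                raise ValueError(f"{chrom}: negative read position")
            self.positions[chrom] = pos

    @property
    def total_reads(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def depth_per_kb(self, genome: GenomeRef) -> float:
        """Sequencing depth in reads per mappable kb."""
        mlen = genome.mappable_length()
        if mlen == 0:
            raise ValueError("genome has no mappable space")
        return self.total_reads / (mlen / 1000.0)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        lo, hi = np.searchsorted(pos, [start, end])
        return int(hi - lo)


@dataclass
class Interval:
    """A scored genomic interval; ``peak`` is the SNS peak when known."""

    chrom: str
    start: int
    end: int
    peak: int | None = None
    intensity_rpkm: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.peak is not None and not (self.start <= self.peak < self.end):
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: peak {self.peak} "
                "outside interval"
            )
        if self.intensity_rpkm < 0:
            raise ValueError("intensity_rpkm must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


_ORIGIN_COLS = ["chrom", "start", "end", "peak", "intensity_rpkm", "label"]


class OriginSet:
    """An ordered collection of scored origin intervals.

    Thin wrapper over a pandas DataFrame with columns
    ``chrom, start, end, peak, intensity_rpkm, label`` (``peak`` is a
    nullable integer; absent peaks are ``pd.NA``).
    """

    def __init__(self, intervals: Iterable[Interval] | pd.DataFrame = ()):
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
            for col in _ORIGIN_COLS:
                if col not in df.columns:
                    df[col] = pd.NA if col in ("peak", "label") else 0
            df = df[_ORIGIN_COLS]
        else:
            rows = [
                (iv.chrom, iv.start, iv.end, iv.peak, iv.intensity_rpkm, iv.label)
                for iv in intervals
            ]
            df = pd.DataFrame(rows, columns=_ORIGIN_COLS)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["peak"] = df["peak"].astype("Int64")
        df["intensity_rpkm"] = df["intensity_rpkm"].astype(float)
        if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
            raise ValueError("origin with start >= end")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Interval(
                row.chrom, int(row.start), int(row.end),
                None if pd.isna(row.peak) else int(row.peak),
                float(row.intensity_rpkm),
                None if pd.isna(row.label) else row.label,
            )

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def sorted_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) sorted by start for one chromosome."""
        sub = self.by_chrom(chrom).sort_values("start")
        return sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)

    def peaks(self) -> pd.DataFrame:
        """(chrom, peak) for origins with a located peak."""
        sub = self.df.dropna(subset=["peak"])
        return pd.DataFrame(
            {"chrom": sub["chrom"].to_numpy(), "peak": sub["peak"].astype(np.int64)}
        )

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy(np.int64)


class HomologyMap:
    """Pairwise map of co-linear, ungapped conserved genomic segments (CGS).

    Each row pairs an interval on genome A with an equal-length interval on
    genome B; orientation ``-`` means B runs on the reverse strand, so offsets
    mirror within the segment. Segments must not overlap on the A side.
    """

    COLS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "orientation"]

    def __init__(self, df: pd.DataFrame):
        df = df[self.COLS].copy().reset_index(drop=True)
        for col in ("start_a", "end_a", "start_b", "end_b"):
            df[col] = df[col].astype(np.int64)
        len_a = df["end_a"] - df["start_a"]
        len_b = df["end_b"] - df["start_b"]
        bad = np.flatnonzero((len_a != len_b) | (len_a <= 0))
        if len(bad):
            raise ValueError(
                f"segment pair {bad[0]}: A and B lengths differ or are empty"
            )
        if not set(df["orientation"]) <= {"+", "-"}:
            raise ValueError("orientation must be '+' or '-'")
        for chrom, sub in df.groupby("chrom_a"):
            sub = sub.sort_values("start_a")
            if np.any(sub["start_a"].to_numpy()[1:] < sub["end_a"].to_numpy()[:-1]):
                raise ValueError(f"overlapping A-side segments on {chrom}")
        self.df = df
        self._by_chrom: dict[str, pd.DataFrame] = {
            c: sub.sort_values("start_a").reset_index(drop=True)
            for c, sub in df.groupby("chrom_a")
        }
        self._arrays: dict[str, tuple] = {}

    def __len__(self) -> int:
        return len(self.df)

    def segments_on(self, chrom: str) -> pd.DataFrame:
        return self._by_chrom.get(chrom, self.df.iloc[0:0])

    def arrays_on(self, chrom: str):
        """(start_a, end_a, chrom_b, start_b, orientation) numpy views, cached."""
        if chrom not in self._arrays:
            sub = self.segments_on(chrom)
            self._arrays[chrom] = (
                sub["start_a"].to_numpy(np.int64),
                sub["end_a"].to_numpy(np.int64),
                sub["chrom_b"].to_numpy(object),
                sub["start_b"].to_numpy(np.int64),
                sub["orientation"].to_numpy(object),
            )
        return self._arrays[chrom]

    def reversed(self) -> "HomologyMap":
        """The same map with A and B sides swapped (B-side overlaps allowed)."""
        df = self.df.rename(
            columns={
                "chrom_a": "chrom_b", "start_a": "start_b", "end_a": "end_b",
                "chrom_b": "chrom_a", "start_b": "start_a", "end_b": "end_a",
            }
        )
        return HomologyMap(df[self.COLS])


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read BED3/BED5 into 0-based half-open :class:`Interval` records."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            intervals.append(Interval(fields[0], start, end,
                                      intensity_rpkm=score, label=label))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None and iv.intensity_rpkm == 0.0:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.label if iv.label is not None else '.'}\t"
                    f"{iv.intensity_rpkm:g}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike,
               mask_path: str | os.PathLike | None = None) -> GenomeRef:
    """Read a genome FASTA, optionally with a mappability mask BED.

    Without a mask file, soft-masked (lower-case) stretches are kept in the
    sequence but excluded from the mappable intervals; with a mask file the
    mask defines mappability and case is ignored. IUPAC ambiguity codes other
    than ACGT are stored as N.
    """
    names: list[str] = []
    lengths: dict[str, int] = {}
    seqs: dict[str, str] = {}
    mappable: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        raw = str(rec.seq)
        upper = raw.upper()
        bad = set(upper) - _IUPAC
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        names.append(rec.id)
        seqs[rec.id] = upper.translate(_TO_ACGTN)
        lengths[rec.id] = len(upper)
        if mask_path is None:
            is_up = np.frombuffer(raw.encode(), dtype=np.uint8) < ord("a")
            mappable[rec.id] = _runs_of_true(is_up)
    if mask_path is not None:
        mappable = {name: np.empty((0, 2), dtype=np.int64) for name in names}
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in read_bed(mask_path):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in per_chrom.items():
            if chrom in mappable:
                mappable[chrom] = merge_interval_array(interval_array(pairs))
    return GenomeRef(names, lengths, seqs, mappable)


def _runs_of_true(mask: np.ndarray) -> np.ndarray:
    """Half-open intervals of consecutive True values."""
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    padded = np.diff(np.concatenate(([0], mask.view(np.uint8), [0])).astype(np.int8))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return np.column_stack([starts, ends]).astype(np.int64)


def write_fasta(genome: GenomeRef, path: str | os.PathLike,
                line_width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequence[name]), id=name, description="")
        for name in genome.chrom_names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


def write_mask_bed(genome: GenomeRef, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            for s, e in genome.mappable[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_VARIANT_COLS = ["chrom", "pos", "ancestral", "derived", "daf", "kind"]


def read_variant_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a polarized variant TSV into a validated DataFrame.

    Expected columns (with or without a header line): chrom, pos, ancestral,
    derived and optionally daf. Missing ``daf`` (the mouse/chicken case, where
    rare and common variants cannot be distinguished) is stored as NaN.
    ``kind`` is derived: single-base alleles are SNPs, everything else indels.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 1] is not None and not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)  # header line present
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected >=4 columns (chrom pos ancestral derived)")
    out = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0],
            "pos": df.iloc[:, 1].astype(np.int64),
            "ancestral": df.iloc[:, 2].str.upper(),
            "derived": df.iloc[:, 3].str.upper(),
            "daf": (
                pd.to_numeric(df.iloc[:, 4].replace({".": None, "": None, "-": None}),
                              errors="coerce")
                if df.shape[1] > 4 else np.nan
            ),
        }
    )
    return validate_variant_table(out, origin=str(path))


def validate_variant_table(df: pd.DataFrame, origin: str = "<frame>") -> pd.DataFrame:
    df = df.copy()
    if "daf" not in df.columns:
        df["daf"] = np.nan
    same = df["ancestral"] == df["derived"]
    if same.any():
        row = int(np.flatnonzero(same.to_numpy())[0])
        raise ValueError(f"{origin}: row {row}: ancestral == derived allele")
    daf = df["daf"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((daf < 0) | (daf > 1)):
            raise ValueError(f"{origin}: daf outside [0, 1]")
    df["kind"] = np.where(
        (df["ancestral"].str.len() == 1) & (df["derived"].str.len() == 1),
        "snp", "indel",
    )
    return df[_VARIANT_COLS].reset_index(drop=True)


def write_variant_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df[["chrom", "pos", "ancestral", "derived", "daf"]].copy()
    out["daf"] = out["daf"].map(lambda v: "." if pd.isna(v) else f"{v:g}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# homology maps
# ---------------------------------------------------------------------------

def read_homology_map(path: str | os.PathLike) -> HomologyMap:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=HomologyMap.COLS,
        dtype={"chrom_a": str, "chrom_b": str, "orientation": str},
    )
    return HomologyMap(df)


def write_homology_map(hmap: HomologyMap, path: str | os.PathLike) -> None:
    hmap.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph score tracks and read tracks
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
        raise ParseError(f"{path}: bedGraph interval with start >= end")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_read_track(path: str | os.PathLike) -> ReadTrack:
    """Read 5' positions stored as 1-bp BED intervals."""
    positions: dict[str, list[int]] = {}
    for iv in read_bed(path):
        positions.setdefault(iv.chrom, []).append(iv.start)
    return ReadTrack({c: np.sort(np.asarray(p, dtype=np.int64))
                      for c, p in positions.items()})


def write_read_track(track: ReadTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for p in track.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


# ---------------------------------------------------------------------------
# origin sets (BED5 + peak column)
# ---------------------------------------------------------------------------

def read_origins(path: str | os.PathLike) -> OriginSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=_ORIGIN_COLS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "label": str},
    )
    df["peak"] = pd.to_numeric(df["peak"].replace({".": None}), errors="coerce")
    return OriginSet(df)


def write_origins(origins: OriginSet, path: str | os.PathLike) -> None:
    out = origins.df.copy()
    out["peak"] = out["peak"].map(lambda v: "." if pd.isna(v) else str(int(v)))
    out["label"] = out["label"].map(lambda v: "." if pd.isna(v) else str(v))
    out["intensity_rpkm"] = out["intensity_rpkm"].map(lambda v: f"{v:.6g}")
    out[_ORIGIN_COLS].to_csv(path, sep="\t", header=False, index=False)
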