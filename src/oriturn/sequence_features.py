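"""Sequence signatures anchored on SNS peaks.

Replication initiation leaves compositional footprints: base-content
asymmetries, GC/AT skews (S_GC = (G-C)/(G+C), S_AT = (A-T)/(A+T)) that
invert at the initiation site, and flanking G-quadruplex motifs
(G3 N1-7 G3 N1-7 G3 N1-7 G3, scanned on both strands). This module computes
those statistics as profiles of offset vs value around a set of anchor
positions (SNS peaks), and locates skew inversion points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeRef, OriginSet

__all__ = [
    "AnchoredProfile",
    "G4Hit",
    "SkewInversion",
    "nucleotide_profile",
    "skew_profile",
    "find_skew_inversion",
    "scan_g4",
    "g4_density_profile",
    "G4_PATTERN",
]

G4_PATTERN = re.compile(r"G{3}[ACGT]{1,7}G{3}[ACGT]{1,7}G{3}[ACGT]{1,7}G{3}")
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class AnchoredProfile:
    """A statistic as a function of offset from a set of anchors.

    ``offsets`` are the left edges (bp) of each bin relative to the anchor
    (negative = upstream of the anchor in reference orientation); strictly
    increasing. ``values`` holds the per-bin statistic (NaN = undefined).
    """

    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int
    bin_size: int = 1

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets and values must have equal length")
        if len(self.offsets) > 1 and np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.n_anchors < 1:
            raise ValueError("profile needs at least one anchor")

    @property
    def centers(self) -> np.ndarray:
        """Continuous bin midpoints (a bin spans [offset, offset + bin))."""
        return self.offsets + self.bin_size / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "n": self.n_anchors}
        )


@dataclass(frozen=True)
class G4Hit:
    """One G-quadruplex motif match (genomic, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.length // 2


def _anchor_positions(peaks) -> pd.DataFrame:
    """Normalize peaks input to a (chrom, peak) frame."""
    if isinstance(peaks, OriginSet):
        df = peaks.peaks()
    else:
        df = pd.DataFrame(peaks)
        if "peak" not in df.columns and "pos" in df.columns:
            df = df.rename(columns={"pos": "peak"})
        df = df[["chrom", "peak"]]
    if not len(df):
        raise ValueError("no anchors with a defined peak position")
    return df


# ---------------------------------------------------------------------------
# nucleotide content
# ---------------------------------------------------------------------------

def nucleotide_profile(peaks, genome: GenomeRef,
                       halfwidth: int = 250) -> dict[str, AnchoredProfile]:
    """Per-offset base frequencies in the window centred on each anchor.

    Offsets run -halfwidth..halfwidth at 1 bp; N bases are excluded from the
    per-offset denominator, so the four profiles sum to 1 at every offset.
    Anchors closer than ``halfwidth`` to a chromosome end are dropped; if all
    are dropped an error is raised.
    """
    df = _anchor_positions(peaks)
    width = 2 * halfwidth + 1
    rows = []
    for row in df.itertuples(index=False):
        p = int(row.peak)
        L = genome.chrom_lengths[row.chrom]
        if p - halfwidth < 0 or p + halfwidth + 1 > L:
            continue
        seq = genome.sequence[row.chrom][p - halfwidth:p + halfwidth + 1]
        rows.append(np.frombuffer(seq.encode(), dtype=np.uint8))
    if not rows:
        raise ValueError("all anchors clipped at chromosome ends")
    mat = np.vstack(rows)
    offsets = np.arange(-halfwidth, halfwidth + 1)
    denom = (mat != ord("N")).sum(axis=0).astype(float)
    denom[denom == 0] = np.nan
    out = {}
    for base in "ACGT":
        frac = (mat == ord(base)).sum(axis=0) / denom
        out[base] = AnchoredProfile(offsets, frac, n_anchors=mat.shape[0])
    return out


# ---------------------------------------------------------------------------
# skew
# ---------------------------------------------------------------------------

def skew_profile(peaks, genome: GenomeRef, halfwidth: int = 2500,
                 bin: int = 25) -> tuple[AnchoredProfile, AnchoredProfile]:
    """Pooled GC and AT skew per offset bin around the anchors.

    Counts are pooled over all anchors per bin (robust at low coverage);
    bins where the relevant denominator (G+C, or A+T) is zero come out NaN.
    Anchors are not orientation-flipped: origins are unoriented, so the sign
    convention is purely "upstream = negative offsets on the reference".
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    df = _anchor_positions(peaks)
    n_bins = (2 * halfwidth) // bin
    half_span = n_bins // 2 * bin
    offsets = np.arange(-half_span, half_span, bin)
    counts = np.zeros((4, len(offsets)), dtype=np.int64)   # A C G T per bin
    n_used = 0
    for row in df.itertuples(index=False):
        p = int(row.peak)
        L = genome.chrom_lengths[row.chrom]
        lo, hi = p - half_span, p + half_span
        if lo < 0 or hi > L:
            continue
        n_used += 1
        seq = np.frombuffer(genome.sequence[row.chrom][lo:hi].encode(),
                            dtype=np.uint8)
        bins = np.arange(len(seq)) // bin
        for i, b in enumerate(b"ACGT"):
            counts[i] += np.bincount(bins, weights=(seq == b), minlength=len(offsets)
                                     ).astype(np.int64)
    if n_used == 0:
        raise ValueError("all anchors clipped at chromosome ends")
    A, C, G, T = counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sgc = np.where(G + C > 0, (G - C) / (G + C), np.nan)
        sat = np.where(A + T > 0, (A - T) / (A + T), np.nan)
    return (
        AnchoredProfile(offsets, sgc, n_anchors=n_used, bin_size=bin),
        AnchoredProfile(offsets, sat, n_anchors=n_used, bin_size=bin),
    )


@dataclass
class SkewInversion:
    """Location of the skew sign change and of the flanking extrema (bp)."""

    offset: float            # interpolated zero crossing nearest the anchor
    positive_extremum: float  # bin center of the maximum
    negative_extremum: float  # bin center of the minimum


def find_skew_inversion(profile: AnchoredProfile) -> SkewInversion:
    """Zero crossing of the skew profile nearest offset 0.

    The crossing is linearly interpolated between the centers of the two
    flanking bins of opposite sign (NaN bins are skipped). A profile with no
    sign change raises, signalling a monotone profile.
    """
    centers = profile.centers
    v = profile.values
    ok = ~np.isnan(v)
    centers, v = centers[ok], v[ok]
    if (v > 0).sum() < 2 or (v < 0).sum() < 2:
        raise ValueError("profile needs at least two bins of each sign")
    crossings = []
    for i in range(len(v) - 1):
        if v[i] == 0.0:
            crossings.append(float(centers[i]))
        elif v[i] * v[i + 1] < 0:
            x0 = centers[i] + (0.0 - v[i]) * (centers[i + 1] - centers[i]) / (
                v[i + 1] - v[i])
            crossings.append(float(x0))
    if not crossings:
        raise ValueError("no sign change: monotone skew profile")
    nearest = min(crossings, key=abs)
    return SkewInversion(
        offset=nearest,
        positive_extremum=float(centers[int(np.nanargmax(v))]),
        negative_extremum=float(centers[int(np.nanargmin(v))]),
    )


# ---------------------------------------------------------------------------
# G-quadruplex motifs
# ---------------------------------------------------------------------------

def _scan_plus(seq: str, chrom: str, strand: str, L: int | None = None,
               overlapping: bool = False) -> list[G4Hit]:
    hits = []
    if overlapping:
        it = re.finditer(r"(?=(" + G4_PATTERN.pattern + "))", seq)
        spans = [(m.start(1), m.end(1)) for m in it]
    else:
        spans = [(m.start(), m.end()) for m in G4_PATTERN.finditer(seq)]
    for s, e in spans:
        if strand == "+":
            hits.append(G4Hit(chrom, s, e, "+"))
        else:
            hits.append(G4Hit(chrom, L - e, L - s, "-"))
    return hits


def scan_g4(genome: GenomeRef, chroms: list[str] | None = None,
            overlapping: bool = False) -> list[G4Hit]:
    """Scan both strands for the G4 motif G3 N1-7 G3 N1-7 G3 N1-7 G3.

    Each strand is scanned independently with leftmost non-overlapping
    (regex) semantics; minus-strand hits are matches on the reverse
    complement with coordinates mapped back to the reference. N never
    matches. With ``overlapping=True`` a (greedy) match is reported at every
    start position instead.
    """
    hits: list[G4Hit] = []
    for chrom in chroms or genome.chrom_names:
        seq = genome.sequence[chrom]
        L = len(seq)
        hits.extend(_scan_plus(seq, chrom, "+", overlapping=overlapping))
        rc = seq.translate(_COMP)[::-1]
        hits.extend(_scan_plus(rc, chrom, "-", L=L, overlapping=overlapping))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def g4_density_profile(peaks, hits: list[G4Hit], halfwidth: int = 250,
                       bin: int = 5) -> AnchoredProfile:
    """Total count of G4 midpoints per offset bin, summed over anchors.

    Matches the "total number of motifs" convention (no per-anchor
    averaging); each motif contributes at the position of its middle
    nucleotide.
    """
    df = _anchor_positions(peaks)
    mids: dict[str, np.ndarray] = {}
    for h in hits:
        mids.setdefault(h.chrom, [])
    for h in hits:
        mids[h.chrom].append(h.midpoint)
    mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}
    n_bins = (2 * halfwidth) // bin
    half_span = n_bins // 2 * bin
    offsets = np.arange(-half_span, half_span, bin)
    values = np.zeros(len(offsets), dtype=np.int64)
    for row in df.itertuples(index=False):
        p = int(row.peak)
        m = mids.get(row.chrom)
        if m is None or not len(m):
            continue
        lo, hi = np.searchsorted(m, [p - half_span, p + half_span])
        rel = m[lo:hi] - (p - half_span)
        values += np.bincount(rel // bin, minlength=len(offsets))
    return AnchoredProfile(offsets, values.astype(float),
                           n_anchors=len(df), bin_size=bin)
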