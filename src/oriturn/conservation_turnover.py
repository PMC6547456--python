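"""Cross-species conservation and turnover of replication origins.

Covers the landscape-level and element-level comparisons: concentration of
initiation activity in 100-kb windows (Lorenz-style curves), overlap of
origins with conserved genomic segments (CGS), functional conservation of
the top-quartile origins through pairwise homology maps, randomization
baselines that preserve per-chromosome counts and size distributions,
TSS-based controls, homologous SNS read profiles, per-base conservation
score profiles, and CGI/TSS categorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeRef,
    HomologyMap,
    Interval,
    OriginSet,
    ReadTrack,
)
from .sequence_features import AnchoredProfile

__all__ = [
    "ConcentrationCurve",
    "ConservationReport",
    "RandomizedBaseline",
    "concentration_curve",
    "select_top_quartile",
    "overlaps_cgs",
    "map_interval",
    "functional_conservation",
    "randomized_baseline",
    "tss_activity_conservation",
    "homologous_profile",
    "score_profile",
    "categorize_origins",
]


# ---------------------------------------------------------------------------
# read concentration (Lorenz-style)
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationCurve:
    """Cumulative read share of the x richest fixed-size windows."""

    window_size: int
    window_fraction: np.ndarray     # k/n for k = 1..n
    cum_read_fraction: np.ndarray   # share of reads in the k richest windows

    def share(self, genome_fraction: float) -> float:
        """Read share of the top ``genome_fraction`` of windows."""
        n = len(self.window_fraction)
        k = int(round(genome_fraction * n))
        if k <= 0:
            return 0.0
        return float(self.cum_read_fraction[min(k, n) - 1])


def concentration_curve(track: ReadTrack, genome: GenomeRef,
                        window: int = 100_000) -> ConcentrationCurve:
    """Sorted cumulative read fractions over fixed windows.

    Windows tile each chromosome from its start; the last partial window is
    dropped. Reads in dropped windows do not contribute.
    """
    counts = []
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        n_win = L // window
        if n_win == 0:
            continue
        pos = track.positions.get(chrom, np.empty(0, dtype=np.int64))
        pos = pos[pos < n_win * window]
        counts.append(np.bincount(pos // window, minlength=n_win))
    if not counts:
        raise ValueError("no full windows: genome shorter than window size")
    c = np.concatenate(counts)
    if len(c) < 10:
        raise ValueError("need at least 10 windows for a concentration curve")
    c = np.sort(c)[::-1]
    total = c.sum()
    cum = np.cumsum(c) / total if total else np.zeros(len(c))
    frac = np.arange(1, len(c) + 1) / len(c)
    return ConcentrationCurve(window, frac, cum)


# ---------------------------------------------------------------------------
# top quartile and CGS overlap
# ---------------------------------------------------------------------------

def select_top_quartile(origins: OriginSet) -> OriginSet:
    """Origins with RPKM >= the 75th percentile (ties included)."""
    if len(origins) < 4:
        raise ValueError("need at least 4 origins to take a quartile")
    rpkm = origins.df["intensity_rpkm"].to_numpy()
    thr = np.percentile(rpkm, 75)
    return OriginSet(origins.df[rpkm >= thr].reset_index(drop=True))


def overlaps_cgs(origins: OriginSet, hmap: HomologyMap) -> np.ndarray:
    """Boolean per origin: >=1 bp intersection with any A-side CGS."""
    out = np.zeros(len(origins), dtype=bool)
    for chrom in origins.chroms():
        seg = hmap.segments_on(chrom)
        mask = (origins.df["chrom"] == chrom).to_numpy()
        if not len(seg):
            continue  # chromosome absent from the map counts as no overlap
        starts = seg["start_a"].to_numpy()
        ends = seg["end_a"].to_numpy()
        s = origins.df.loc[mask, "start"].to_numpy()
        e = origins.df.loc[mask, "end"].to_numpy()
        idx = np.searchsorted(starts, e, side="left") - 1
        hit = (idx >= 0) & (ends[np.clip(idx, 0, None)] > s)
        out[np.flatnonzero(mask)] = hit
    return out


def map_interval(hmap: HomologyMap, interval: Interval) -> Interval | None:
    """Map an A-side interval into genome B through its containing CGS.

    The interval is clipped to the CGS with the largest overlap; offsets are
    preserved for '+' pairs and mirrored within the segment for '-' pairs.
    Returns None when the interval overlaps no CGS.
    """
    starts, ends, chroms_b, starts_b, orient = hmap.arrays_on(interval.chrom)
    if not len(starts):
        return None
    # A-side segments are sorted and non-overlapping: only the segments
    # bracketing the interval can overlap it
    lo = int(np.searchsorted(ends, interval.start, side="right"))
    hi = int(np.searchsorted(starts, interval.end, side="left"))
    if hi <= lo:
        return None
    ov = (np.minimum(ends[lo:hi], interval.end)
          - np.maximum(starts[lo:hi], interval.start))
    best = lo + int(np.argmax(ov))
    if ov[best - lo] <= 0:
        return None
    sa, ea = int(starts[best]), int(ends[best])
    s = max(interval.start, sa)
    e = min(interval.end, ea)
    sb = int(starts_b[best])
    if orient[best] == "+":
        bs, be = sb + (s - sa), sb + (e - sa)
    else:
        bs, be = sb + (ea - e), sb + (ea - s)
    return Interval(str(chroms_b[best]), bs, be, label=str(orient[best]))


# ---------------------------------------------------------------------------
# functional conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationReport:
    """Conservation summary for a set of (top-quartile) origins."""

    n_origins_considered: int
    pct_overlapping_cgs: float
    pct_functionally_conserved: float
    per_origin: pd.DataFrame = field(repr=False, default=None)
    fold_enrichment: float | None = None
    random_mean_pct: float | None = None


def _overlap_any(s: int, e: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    """>=1 bp overlap with intervals sorted by start (may overlap)."""
    i = int(np.searchsorted(starts, e, side="left")) - 1
    while i >= 0:
        if ends[i] > s:
            return True
        i -= 1
        # keep scanning left: an earlier long interval may still reach past s
        if i >= 0 and ends[: i + 1].max(initial=0) <= s:
            return False
    return False


def functional_conservation(origins_a: OriginSet, origins_b: OriginSet,
                            hmap: HomologyMap) -> ConservationReport:
    """Which A origins are functionally conserved in B.

    An origin is functionally conserved when it overlaps a CGS *and* its
    mapped (clipped) interval overlaps >=1 bp of any B origin; the conserved
    set is therefore always a subset of the CGS-overlapping set. Percentages
    are relative to all origins considered.
    """
    if len(origins_a) == 0:
        raise ValueError("empty origin set")
    cache = {c: origins_b.sorted_arrays(c) for c in origins_b.chroms()}
    in_cgs = overlaps_cgs(origins_a, hmap)
    conserved = np.zeros(len(origins_a), dtype=bool)
    for i, row in enumerate(origins_a.df.itertuples(index=False)):
        if not in_cgs[i]:
            continue
        mapped = map_interval(hmap, Interval(row.chrom, int(row.start),
                                             int(row.end)))
        if mapped is None:
            continue
        starts, ends = cache.get(mapped.chrom, (np.empty(0), np.empty(0)))
        if len(starts) and _overlap_any(mapped.start, mapped.end, starts, ends):
            conserved[i] = True
    per_origin = origins_a.df.copy()
    per_origin["overlaps_cgs"] = in_cgs
    per_origin["functionally_conserved"] = conserved
    n = len(origins_a)
    return ConservationReport(
        n_origins_considered=n,
        pct_overlapping_cgs=100.0 * in_cgs.mean(),
        pct_functionally_conserved=100.0 * conserved.mean(),
        per_origin=per_origin,
    )


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------

@dataclass
class RandomizedBaseline:
    """Null conservation level from randomly placed origin-like segments."""

    random_pcts: np.ndarray          # per random set, % functionally conserved
    random_cgs_pcts: np.ndarray      # per random set, % overlapping CGS
    observed_pct: float
    fold_enrichment: float
    fold_ci: tuple[float, float]


def _random_origin_set(origins: OriginSet, genome: GenomeRef,
                       rng: np.random.Generator) -> OriginSet:
    """One random set preserving per-chromosome counts and size spectra."""
    intervals: list[Interval] = []
    for chrom in origins.chroms():
        sub = origins.by_chrom(chrom)
        n_i = len(sub)
        lengths = (sub["end"] - sub["start"]).to_numpy()
        ivs = genome.mappable[chrom]
        space = int((ivs[:, 1] - ivs[:, 0]).sum()) if len(ivs) else 0
        if space == 0:
            raise ValueError(f"{chrom} has origins but no mappable space")
        sizes = ivs[:, 1] - ivs[:, 0]
        cum = np.concatenate(([0], np.cumsum(sizes)))
        u = rng.integers(0, space, size=n_i)
        idx = np.searchsorted(cum, u, side="right") - 1
        starts = ivs[idx, 0] + (u - cum[idx])
        drawn = rng.choice(lengths, size=n_i, replace=True)
        L = genome.chrom_lengths[chrom]
        for s, ln in zip(starts, drawn):
            s = int(min(s, max(0, L - ln)))
            mid = s + int(ln) // 2
            intervals.append(Interval(chrom, s, min(int(s + ln), L), peak=mid))
    return OriginSet(intervals)


def randomized_baseline(origins: OriginSet, genome: GenomeRef,
                        hmap: HomologyMap, origins_b: OriginSet,
                        n_sets: int = 10, seed: int = 0) -> RandomizedBaseline:
    """Fold enrichment of observed conservation over random placement.

    Each of ``n_sets`` random sets keeps, per chromosome, the observed
    number of origins and draws each segment length uniformly from the
    observed size distribution of that chromosome. fold = observed
    conserved fraction / mean(random fractions); the CI is a prediction
    interval treating the observed value as one more draw from the null
    spread of the random sets (se = sd * sqrt(1 + 1/n_sets) / mean, with a
    Student-t quantile on n_sets - 1 df since the sd is itself estimated
    from the sets).
    """
    from scipy import stats as _stats

    obs = functional_conservation(origins, origins_b, hmap)
    rng = np.random.default_rng(seed)
    pcts, cgs_pcts = [], []
    for _ in range(n_sets):
        rnd = _random_origin_set(origins, genome, rng)
        rep = functional_conservation(rnd, origins_b, hmap)
        pcts.append(rep.pct_functionally_conserved)
        cgs_pcts.append(rep.pct_overlapping_cgs)
    pcts = np.asarray(pcts)
    mean = pcts.mean()
    fold = obs.pct_functionally_conserved / mean if mean > 0 else np.inf
    if mean > 0 and n_sets > 1:
        tq = float(_stats.t.ppf(0.975, df=n_sets - 1))
        se = pcts.std(ddof=1) * np.sqrt(1.0 + 1.0 / n_sets) / mean
        ci = (fold - tq * se, fold + tq * se)
    else:
        ci = (np.nan, np.nan)
    return RandomizedBaseline(pcts, np.asarray(cgs_pcts),
                              obs.pct_functionally_conserved, float(fold),
                              (float(ci[0]), float(ci[1])))


# ---------------------------------------------------------------------------
# TSS controls
# ---------------------------------------------------------------------------

def _extend_tss(tss: pd.DataFrame, lengths: np.ndarray,
                rng: np.random.Generator, genome: GenomeRef) -> OriginSet:
    if "strand" not in tss.columns or tss["strand"].isna().any() \
            or not set(tss["strand"]) <= {"+", "-"}:
        raise ValueError("TSSs must be oriented ('+' or '-')")
    drawn = rng.choice(lengths, size=len(tss), replace=True)
    intervals = []
    for (row, ln) in zip(tss.itertuples(index=False), drawn):
        p = int(row.pos)
        L = genome.chrom_lengths[row.chrom]
        ln = int(ln)
        if row.strand == "+":
            s, e = max(0, p - ln + 1), p + 1      # extend 5'-ward = leftward
        else:
            s, e = p, min(L, p + ln)              # minus strand: rightward
        intervals.append(Interval(row.chrom, s, max(e, s + 1), peak=p))
    return OriginSet(intervals)


def tss_activity_conservation(tss_a: pd.DataFrame, tss_b: pd.DataFrame,
                              origin_lengths: np.ndarray, hmap: HomologyMap,
                              genome_a: GenomeRef, genome_b: GenomeRef,
                              seed: int = 0) -> ConservationReport:
    """Conservation of TSS activity, using origin-sized 5'-extended regions.

    TSSs (frames with chrom, pos, strand) are extended on their 5' side by
    lengths drawn from the origin size distribution, then run through the
    same CGS-overlap / mapped-overlap logic as origins, "active in B"
    meaning the mapped region overlaps a B TSS region.
    """
    rng = np.random.default_rng(seed)
    regions_a = _extend_tss(tss_a, origin_lengths, rng, genome_a)
    regions_b = _extend_tss(tss_b, origin_lengths, rng, genome_b)
    return functional_conservation(regions_a, regions_b, hmap)


# ---------------------------------------------------------------------------
# homologous read profiles and score profiles
# ---------------------------------------------------------------------------

def homologous_profile(peaks_a, hmap: HomologyMap, track_b: ReadTrack,
                       genome_b: GenomeRef | None = None,
                       window: int = 3000, bin: int = 50,
                       ) -> tuple[AnchoredProfile, float, int]:
    """B-genome read accumulation around the homologs of A SNS peaks.

    For every A peak inside a CGS, the peak position is mapped to B and the
    B reads in a ``window`` centred there are binned ('-' segments flip the
    offsets so upstream/downstream are preserved through the map). Values
    are mean reads per bin per anchor. Returns (profile, expectation per bin
    under uniform B coverage, number of peaks skipped for lack of CGS).
    """
    from .sequence_features import _anchor_positions

    anchors = _anchor_positions(peaks_a)
    half = window // 2
    n_bins = window // bin
    offsets = np.arange(-(n_bins // 2) * bin, (n_bins - n_bins // 2) * bin, bin)
    counts = np.zeros(len(offsets), dtype=np.int64)
    n_used = 0
    n_skipped = 0
    for row in anchors.itertuples(index=False):
        p = int(row.peak)
        mapped = map_interval(hmap, Interval(row.chrom, p, p + 1))
        if mapped is None:
            n_skipped += 1
            continue
        bp = mapped.start
        pos = track_b.positions.get(mapped.chrom, np.empty(0, dtype=np.int64))
        lo, hi = np.searchsorted(pos, [bp - half, bp + half])
        rel = pos[lo:hi] - (bp - half)
        binned = np.bincount(rel // bin, minlength=len(offsets))[:len(offsets)]
        if mapped.label == "-":
            binned = binned[::-1]
        counts += binned
        n_used += 1
    if n_used == 0:
        raise ValueError("no A peak could be mapped through the homology map")
    values = counts / n_used
    if genome_b is not None:
        expectation = track_b.total_reads / genome_b.mappable_length() * bin
    else:
        expectation = float("nan")
    return (AnchoredProfile(offsets, values, n_anchors=n_used, bin_size=bin),
            float(expectation), n_skipped)


def score_profile(anchors: pd.DataFrame, score: pd.DataFrame,
                  genome: GenomeRef, halfwidth: int = 700,
                  bin: int = 10) -> AnchoredProfile:
    """Mean per-base score (e.g. PhastCons) by offset bin around anchors.

    ``anchors``: frame with chrom, peak and optional strand; minus-strand
    anchors are flipped before averaging so profiles read 5'->3'.
    ``score``: bedGraph frame (chrom, start, end, value); bases without a
    score are excluded from the means.
    """
    dense: dict[str, np.ndarray] = {}
    for chrom, sub in score.groupby("chrom"):
        if chrom not in genome.chrom_lengths:
            continue
        arr = np.full(genome.chrom_lengths[chrom], np.nan)
        for row in sub.itertuples(index=False):
            arr[row.start:row.end] = row.value
        dense[chrom] = arr
    n_bins = (2 * halfwidth) // bin
    half_span = n_bins // 2 * bin
    offsets = np.arange(-half_span, half_span, bin)
    sums = np.zeros(len(offsets))
    ns = np.zeros(len(offsets))
    n_used = 0
    has_strand = "strand" in anchors.columns
    for row in anchors.itertuples(index=False):
        arr = dense.get(row.chrom)
        if arr is None:
            continue
        p = int(row.peak)
        lo, hi = p - half_span, p + half_span
        if lo < 0 or hi > len(arr):
            continue
        vals = arr[lo:hi]
        if has_strand and row.strand == "-":
            vals = vals[::-1]
        vals = vals.reshape(len(offsets), bin)
        ok = ~np.isnan(vals)
        sums += np.where(ok, vals, 0.0).sum(axis=1)
        ns += ok.sum(axis=1)
        n_used += 1
    if n_used == 0 or ns.sum() == 0:
        raise ValueError("no scored positions under any anchor")
    with np.errstate(invalid="ignore"):
        values = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return AnchoredProfile(offsets, values, n_anchors=n_used, bin_size=bin)


# ---------------------------------------------------------------------------
# CGI / TSS categorization
# ---------------------------------------------------------------------------

def categorize_origins(origins: OriginSet, cgi: list[Interval],
                       tss: pd.DataFrame,
                       tss_distance: int = 750) -> pd.Series:
    """Assign each origin to one of CGI[+/-] x TSS[+/-].

    CGI[+] means >=1 bp overlap with a CpG-island interval; TSS[+] means a
    TSS lies within ``tss_distance`` bp of the origin interval (distance 0
    when the TSS falls inside; the boundary distance counts as associated).
    """
    cgi_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in cgi:
        cgi_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    cgi_by_chrom = {
        c: (lambda a: (a[:, 0], a[:, 1]))(
            np.asarray(sorted(v), dtype=np.int64).reshape(-1, 2))
        for c, v in cgi_by_chrom.items()
    }
    tss_by_chrom = {c: np.sort(sub["pos"].to_numpy(np.int64))
                    for c, sub in tss.groupby("chrom")}
    cats = []
    for row in origins.df.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        starts, ends = cgi_by_chrom.get(row.chrom, (np.empty(0), np.empty(0)))
        has_cgi = len(starts) > 0 and _overlap_any(s, e, starts, ends)
        pos = tss_by_chrom.get(row.chrom, np.empty(0, dtype=np.int64))
        lo, hi = np.searchsorted(pos, [s - tss_distance, e + tss_distance])
        has_tss = hi > lo
        cats.append(f"CGI[{'+' if has_cgi else '-'}]"
                    f"TSS[{'+' if has_tss else '-'}]")
    return pd.Series(cats, index=origins.df.index, name="category")
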