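"""Selection signatures at origins from intra-species polymorphism.

Derived-allele-frequency (DAF) stratification separates mutational input
(rare variants, DAF < 1%) from the combined effect of drift, selection and
GC-biased gene conversion (common variants, DAF > 10%). Purifying selection
on the origin core shows up as a deficit of common variants in the ~40 bp
window around the SNS peak, while rare variants stay flat at the genome-wide
mutation rate. Mutation-class splits (GC->AT, AT->GC, GC-conservative)
distinguish selection from gBGC, which is directional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeRef
from .sequence_features import AnchoredProfile, _anchor_positions

__all__ = [
    "VariantClassing",
    "CoreDepletion",
    "classify_variants",
    "snp_density_profile",
    "indel_density_profile",
    "base_specific_density",
    "core_depletion",
]

_GC = frozenset("GC")
_AT = frozenset("AT")


@dataclass
class VariantClassing:
    """Boundaries of the DAF frequency classes (strict inequalities)."""

    daf_rare_max: float = 0.01
    daf_common_min: float = 0.10

    def __post_init__(self) -> None:
        if not self.daf_rare_max < self.daf_common_min:
            raise ValueError("daf_rare_max must be < daf_common_min")


def classify_variants(table: pd.DataFrame,
                      classing: VariantClassing | None = None) -> pd.DataFrame:
    """Attach ``freq_class`` and ``mut_class`` columns to a variant table.

    freq_class: rare (daf < rare_max), common (daf > common_min),
    intermediate otherwise; missing daf -> "unknown-frequency" (the
    small-sample mouse/chicken situation). DAF exactly on a boundary is
    intermediate. mut_class (SNPs only): {G,C}->{A,T} = "GC->AT",
    {A,T}->{G,C} = "AT->GC", everything else "GC-conservative".
    """
    classing = classing or VariantClassing()
    df = table.copy()
    daf = df["daf"].to_numpy(dtype=float)
    freq = np.full(len(df), "intermediate", dtype=object)
    with np.errstate(invalid="ignore"):
        freq[daf < classing.daf_rare_max] = "rare"
        freq[daf > classing.daf_common_min] = "common"
    freq[np.isnan(daf)] = "unknown-frequency"
    df["freq_class"] = freq

    anc = df["ancestral"].to_numpy(dtype=object)
    der = df["derived"].to_numpy(dtype=object)
    snp = (df["kind"] == "snp").to_numpy()
    mut = np.full(len(df), pd.NA, dtype=object)
    anc_gc = np.isin(anc, ("G", "C"))
    der_gc = np.isin(der, ("G", "C"))
    mut[snp & anc_gc & ~der_gc] = "GC->AT"
    mut[snp & ~anc_gc & der_gc] = "AT->GC"
    mut[snp & (anc_gc == der_gc)] = "GC-conservative"
    df["mut_class"] = mut
    return df


def _filter(table: pd.DataFrame, kind: str | None, freq_class: str | None,
            mut_class: str | None) -> pd.DataFrame:
    df = table
    if kind is not None:
        df = df[df["kind"] == kind]
    if freq_class is not None:
        if "freq_class" not in df.columns:
            df = classify_variants(df)
        df = df[df["freq_class"] == freq_class]
    if mut_class is not None:
        df = df[df["mut_class"] == mut_class]
    return df


def _positions_by_chrom(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {c: np.sort(sub["pos"].to_numpy(np.int64))
            for c, sub in df.groupby("chrom")}


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

def snp_density_profile(peaks, table: pd.DataFrame,
                        freq_class: str | None = None,
                        mut_class: str | None = None,
                        halfwidth: int = 500, bin: int = 10,
                        genome: GenomeRef | None = None,
                        kind: str = "snp",
                        ) -> tuple[AnchoredProfile, float]:
    """Variant density (per bp per anchor) by offset bin around anchors.

    Returns the profile and the genome-wide baseline (class count divided by
    mappable genome length; NaN when no genome is supplied).
    """
    anchors = _anchor_positions(peaks)
    df = _filter(table, kind, freq_class, mut_class)
    by_chrom = _positions_by_chrom(df)
    n_bins = (2 * halfwidth) // bin
    half_span = n_bins // 2 * bin
    offsets = np.arange(-half_span, half_span, bin)
    counts = np.zeros(len(offsets), dtype=np.int64)
    for row in anchors.itertuples(index=False):
        p = int(row.peak)
        pos = by_chrom.get(row.chrom)
        if pos is None or not len(pos):
            continue
        lo, hi = np.searchsorted(pos, [p - half_span, p + half_span])
        rel = pos[lo:hi] - (p - half_span)
        counts += np.bincount(rel // bin, minlength=len(offsets))
    values = counts / (len(anchors) * bin)
    baseline = np.nan
    if genome is not None:
        mlen = genome.mappable_length()
        baseline = len(df) / mlen if mlen else np.nan
    return (AnchoredProfile(offsets, values, n_anchors=len(anchors),
                            bin_size=bin), float(baseline))


def indel_density_profile(peaks, table: pd.DataFrame,
                          freq_class: str | None = None,
                          halfwidth: int = 500, bin: int = 10,
                          genome: GenomeRef | None = None,
                          ) -> tuple[AnchoredProfile, float]:
    """As :func:`snp_density_profile`, restricted to indels."""
    return snp_density_profile(peaks, table, freq_class=freq_class,
                               halfwidth=halfwidth, bin=bin, genome=genome,
                               kind="indel")


def base_specific_density(peaks, table: pd.DataFrame, genome: GenomeRef,
                          x: str, y: str, halfwidth: int = 250,
                          freq_class: str | None = None) -> float:
    """Observed x->y variants per ancestral x base around the anchors.

    Density = count of x->y SNPs within +-halfwidth of any anchor, divided
    by the count of x bases in the same windows; NaN when no x bases occur.
    """
    if len(x) != 1 or len(y) != 1 or x == y:
        raise ValueError("x and y must be distinct single bases")
    anchors = _anchor_positions(peaks)
    df = _filter(table, "snp", freq_class, None)
    df = df[(df["ancestral"] == x) & (df["derived"] == y)]
    by_chrom = _positions_by_chrom(df)
    n_var = 0
    n_x = 0
    for row in anchors.itertuples(index=False):
        p = int(row.peak)
        L = genome.chrom_lengths[row.chrom]
        lo, hi = max(0, p - halfwidth), min(L, p + halfwidth + 1)
        seq = genome.sequence[row.chrom][lo:hi]
        n_x += seq.count(x)
        pos = by_chrom.get(row.chrom)
        if pos is not None and len(pos):
            a, b = np.searchsorted(pos, [lo, hi])
            n_var += int(b - a)
    return n_var / n_x if n_x else float("nan")


# ---------------------------------------------------------------------------
# core depletion
# ---------------------------------------------------------------------------

@dataclass
class CoreDepletion:
    """Core vs flank variant density around SNS peaks, with bootstrap CI."""

    core_halfwidth: int
    flank: tuple[int, int]
    core_density: float
    flank_density: float
    ratio: float
    ci_low: float
    ci_high: float
    n_anchors: int
    n_core: int
    n_flank: int


def core_depletion(peaks, table: pd.DataFrame,
                   freq_class: str | None = "common",
                   mut_class: str | None = None,
                   core_halfwidth: int = 20,
                   flank: tuple[int, int] = (100, 500),
                   n_boot: int = 1000, seed: int = 0,
                   kind: str = "snp") -> CoreDepletion:
    """Ratio of variant density in the ~40 bp core to the flanks.

    Core = [-core_halfwidth, +core_halfwidth) around each anchor; flanks =
    flank[0] <= |offset| < flank[1] on both sides. The 95% CI is a
    percentile bootstrap over anchors (origins are resampled, not variants,
    because variant counts within an origin are dependent).
    """
    anchors = _anchor_positions(peaks)
    df = _filter(table, kind, freq_class, mut_class)
    by_chrom = _positions_by_chrom(df)
    n = len(anchors)
    core_counts = np.zeros(n, dtype=np.int64)
    flank_counts = np.zeros(n, dtype=np.int64)
    f0, f1 = flank
    for i, row in enumerate(anchors.itertuples(index=False)):
        p = int(row.peak)
        pos = by_chrom.get(row.chrom)
        if pos is None or not len(pos):
            continue
        a, b = np.searchsorted(pos, [p - core_halfwidth, p + core_halfwidth])
        core_counts[i] = b - a
        l0, l1 = np.searchsorted(pos, [p - f1, p - f0])
        r0, r1 = np.searchsorted(pos, [p + f0, p + f1])
        flank_counts[i] = (l1 - l0) + (r1 - r0)
    core_bp = 2 * core_halfwidth
    flank_bp = 2 * (f1 - f0)
    if flank_counts.sum() == 0:
        raise ValueError("no variants of the requested class in the flanks")
    core_density = core_counts.sum() / (n * core_bp)
    flank_density = flank_counts.sum() / (n * flank_bp)
    ratio = core_density / flank_density

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_core = core_counts[idx].sum(axis=1) / core_bp
    boot_flank = flank_counts[idx].sum(axis=1) / flank_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        boot_ratio = boot_core / boot_flank
    boot_ratio = boot_ratio[np.isfinite(boot_ratio)]
    lo, hi = np.percentile(boot_ratio, [2.5, 97.5])
    return CoreDepletion(core_halfwidth, flank, float(core_density),
                         float(flank_density), float(ratio), float(lo),
                         float(hi), n, int(core_counts.sum()),
                         int(flank_counts.sum()))
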