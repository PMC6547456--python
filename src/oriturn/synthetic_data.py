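"""Synthetic genomes, SNS read tracks, variant tables and homology maps.

Every generator here plants a known, recoverable structure that one of the
downstream analysis stages is designed to measure:

* :func:`make_genome` — block-compositional genomes (distinct GC regimes)
  so background k-mer clustering has signal;
* :func:`plant_origins` — a truth set of replication origins with long-tailed
  activities, so "top 25% most active" is well defined;
* :func:`simulate_reads` — Poisson-uniform background reads plus peak-shaped
  pileups (truncated-normal displacement) at planted origins;
* :func:`simulate_skew` — strand-compositional GC/AT skew of amplitude *a*
  inverting exactly at origin centers and extending ~2 kb per side;
* :func:`simulate_variants` — SNPs/indels with a three-component derived
  allele frequency (DAF) mixture and a configurable depletion of common
  variants inside the ~40 bp origin core;
* :func:`simulate_homology` — a sister genome made of block-shuffled
  conserved genomic segments (CGS) with a controlled fraction of
  functionally conserved origins.

All randomness derives from ``SimConfig.seed``; each stage uses an
independent child stream so generators can be re-run in any order.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeRef,
    HomologyMap,
    Interval,
    OriginSet,
    ReadTrack,
    merge_interval_array,
    validate_variant_table,
)

__all__ = [
    "SimConfig",
    "make_genome",
    "plant_origins",
    "simulate_reads",
    "simulate_skew",
    "simulate_variants",
    "simulate_homology",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# child-stream tags so each generator gets an independent stream per seed
_STREAM = {"genome": 1, "origins": 2, "reads": 3, "skew": 4,
           "variants": 5, "homology": 6, "reads_b": 7}


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Defaults mirror the vertebrate SNS-seq setting being emulated:
    ~50 origins/Mb (between the chicken 34/Mb and mouse 84/Mb extremes),
    28 reads/kb sequencing depth (the depth all species were equalized to),
    a ~40 bp constrained core with 25% depletion of common variants, skew
    amplitude 0.2 extending 2 kb per side of the initiation site, and a DAF
    mixture whose rare (<1%) / common (>10%) class weights follow the
    1000-Genomes proportions (76.2% rare, 9.5% common).
    """

    genome_length: int = 10_000_000
    n_chroms: int = 1
    origin_density: float = 50.0          # origins per mappable Mb
    origin_width: int = 1000              # bp, truth interval width
    min_spacing: int = 3000               # bp between origin centers
    background_rate: float = 28.0         # reads per mappable kb
    peak_enrichment: float = 7.0          # origin reads = rate * fold * weight
    peak_sd: float = 100.0                # bp, read displacement sd
    intensity_sigma: float = 1.0          # log-normal sigma of activities
    skew_amplitude: float = 0.2           # plateau |S_GC| = |S_AT|
    skew_extent: int = 2000               # bp of full-amplitude plateau
    skew_decay: int = 500                 # bp of linear decay to zero
    core_width: int = 40                  # bp, constrained core around center
    snp_rate: float = 0.01                # SNPs per bp
    indel_rate: float = 0.0               # indels per bp
    common_depletion: float = 0.25        # core thinning of common variants
    daf_weights: tuple[float, float, float] = (0.762, 0.143, 0.095)
    # (rare <1%, intermediate, common >10%) mixture weights
    conserved_fraction: float = 0.3       # of top-25% origins inside CGS
    cgs_fraction: float = 0.5             # of genome A covered by CGS
    cgs_block: int = 10_000               # bp, CGS segment size
    regime_gc: tuple[float, ...] = (0.35, 0.55)
    block_length: int = 100_000           # bp, compositional block size
    mask_fraction: float = 0.0            # fraction of genome made unmappable
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("origin_density", "background_rate", "peak_enrichment",
                     "peak_sd", "snp_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("skew_amplitude", "common_depletion", "conserved_fraction",
                     "cgs_fraction", "mask_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.daf_weights) - 1.0) > 1e-9:
            raise ValueError("daf_weights must sum to 1")
        if not self.regime_gc:
            raise ValueError("at least one compositional regime required")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stage]])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(cfg: SimConfig) -> GenomeRef:
    """Generate a block-compositional genome.

    Chromosomes are tiled with ``block_length`` blocks whose GC content
    cycles through ``regime_gc``, giving >=2 distinct k-mer usage regimes
    when more than one GC value is configured. The genome is fully mappable
    unless ``mask_fraction`` > 0, in which case that fraction is removed in
    ``block_length``-sized chunks.
    """
    rng = cfg.rng("genome")
    chrom_len = cfg.genome_length // cfg.n_chroms
    names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs: dict[str, str] = {}
    mappable: dict[str, np.ndarray] = {}
    for name in names:
        n_blocks = int(np.ceil(chrom_len / cfg.block_length))
        parts = []
        for b in range(n_blocks):
            gc = cfg.regime_gc[b % len(cfg.regime_gc)]
            size = min(cfg.block_length, chrom_len - b * cfg.block_length)
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            parts.append(_BASES[rng.choice(4, size=size, p=p)])
        seq = np.concatenate(parts)
        seqs[name] = seq.tobytes().decode()
        if cfg.mask_fraction > 0:
            n_masked = int(round(cfg.mask_fraction * n_blocks))
            masked = set(rng.choice(n_blocks, size=n_masked, replace=False))
            keep = [
                (b * cfg.block_length, min(chrom_len, (b + 1) * cfg.block_length))
                for b in range(n_blocks) if b not in masked
            ]
            mappable[name] = merge_interval_array(
                np.asarray(keep, dtype=np.int64).reshape(-1, 2)
            )
        else:
            mappable[name] = np.array([[0, chrom_len]], dtype=np.int64)
    return GenomeRef(names, {n: chrom_len for n in names}, seqs, mappable)


# ---------------------------------------------------------------------------
# origins
# ---------------------------------------------------------------------------

def _mappable_sampler(genome: GenomeRef, chrom: str):
    """Uniform sampler over mappable bp of one chromosome."""
    ivs = genome.mappable[chrom]
    lens = ivs[:, 1] - ivs[:, 0]
    cum = np.concatenate(([0], np.cumsum(lens)))

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.integers(0, cum[-1], size=n)
        idx = np.searchsorted(cum, u, side="right") - 1
        return ivs[idx, 0] + (u - cum[idx])

    return sample, int(cum[-1])


def plant_origins(genome: GenomeRef, cfg: SimConfig) -> OriginSet:
    """Plant a truth set of origins uniformly on mappable space.

    Centers keep a minimum pairwise spacing of ``cfg.min_spacing`` and stay
    clear of chromosome ends; per-origin activity weights are log-normal
    (mean 1), long-tailed so the top quartile is well separated.
    """
    rng = cfg.rng("origins")
    half = cfg.origin_width // 2
    margin = max(cfg.min_spacing, half + 1, cfg.skew_extent + cfg.skew_decay)
    intervals: list[Interval] = []
    for chrom in genome.chrom_names:
        sample, mlen = _mappable_sampler(genome, chrom)
        n = rng.poisson(cfg.origin_density * mlen / 1e6)
        if n == 0:
            continue
        if n * cfg.min_spacing > 0.5 * mlen:
            raise ValueError(
                f"{chrom}: requested density infeasible given "
                f"{cfg.min_spacing} bp minimum spacing"
            )
        accepted: list[int] = []
        L = genome.chrom_lengths[chrom]
        attempts = 0
        while len(accepted) < n and attempts < 200:
            attempts += 1
            for c in sample(rng, 4 * n):
                if len(accepted) == n:
                    break
                c = int(c)
                if c < margin or c > L - margin:
                    continue
                i = bisect.bisect_left(accepted, c)
                if i > 0 and c - accepted[i - 1] < cfg.min_spacing:
                    continue
                if i < len(accepted) and accepted[i] - c < cfg.min_spacing:
                    continue
                accepted.insert(i, c)
        if len(accepted) < n:
            raise ValueError(f"{chrom}: could not place {n} origins with spacing")
        weights = rng.lognormal(
            mean=-0.5 * cfg.intensity_sigma ** 2, sigma=cfg.intensity_sigma,
            size=n,
        )
        for c, w in zip(accepted, weights):
            intervals.append(
                Interval(chrom, c - half, c + (cfg.origin_width - half),
                         peak=c, intensity_rpkm=float(w))
            )
    return OriginSet(intervals)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(genome: GenomeRef, origins: OriginSet, cfg: SimConfig,
                   stream: str = "reads") -> ReadTrack:
    """Background Poisson reads plus origin-centered pileups.

    Expected reads per origin = ``background_rate * peak_enrichment * weight``
    where the weight is the origin's planted activity (mean 1); displacements
    from the true center are normal with sd ``peak_sd``, truncated at four
    standard deviations.
    """
    rng = cfg.rng(stream)
    positions: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        sample, mlen = _mappable_sampler(genome, chrom)
        n_bg = rng.poisson(cfg.background_rate * mlen / 1000.0)
        reads = [sample(rng, n_bg)] if n_bg else []
        sub = origins.by_chrom(chrom)
        if len(sub) and cfg.peak_enrichment > 0:
            centers = sub["peak"].astype(np.int64).to_numpy()
            weights = sub["intensity_rpkm"].to_numpy()
            counts = rng.poisson(cfg.background_rate * cfg.peak_enrichment * weights)
            total = int(counts.sum())
            if total:
                disp = rng.normal(0.0, cfg.peak_sd, size=total)
                lim = 4.0 * cfg.peak_sd
                while True:
                    bad = np.abs(disp) > lim
                    if not bad.any():
                        break
                    disp[bad] = rng.normal(0.0, cfg.peak_sd, size=int(bad.sum()))
                pos = np.repeat(centers, counts) + np.rint(disp).astype(np.int64)
                L = genome.chrom_lengths[chrom]
                reads.append(np.clip(pos, 0, L - 1))
        allpos = (np.sort(np.concatenate(reads)) if reads
                  else np.empty(0, dtype=np.int64))
        positions[chrom] = allpos.astype(np.int64)
    return ReadTrack(positions)


# ---------------------------------------------------------------------------
# skew
# ---------------------------------------------------------------------------

def simulate_skew(genome: GenomeRef, origins: OriginSet, cfg: SimConfig) -> GenomeRef:
    """Rewrite sequence around each origin with an inverting GC/AT skew.

    Upstream of the center (offset < 0) bases are drawn with
    S_GC = S_AT = +a; downstream with -a; the amplitude holds over
    ``skew_extent`` bp and decays linearly to zero over ``skew_decay`` bp.
    Positions claimed by two origins go to the nearer center.
    """
    a = cfg.skew_amplitude
    reach = cfg.skew_extent + cfg.skew_decay
    rng = cfg.rng("skew")
    new_seqs = dict(genome.sequence)
    for chrom in genome.chrom_names:
        sub = origins.by_chrom(chrom)
        if not len(sub) or a == 0:
            continue
        centers = np.sort(sub["peak"].astype(np.int64).to_numpy())
        seq = np.frombuffer(genome.sequence[chrom].encode(), dtype=np.uint8).copy()
        L = len(seq)
        mids = (centers[:-1] + centers[1:]) // 2
        los = np.concatenate(([0], mids))
        his = np.concatenate((mids, [L]))
        for c, lo, hi in zip(centers, los, his):
            lo = max(lo, c - reach, 0)
            hi = min(hi, c + reach + 1, L)
            off = np.arange(lo, hi) - c
            taper = np.clip((reach - np.abs(off)) / cfg.skew_decay, 0.0, 1.0)
            s = -np.sign(off) * a * taper      # +a upstream, -a downstream
            # base probabilities per position: GC and AT split by skew
            p = np.empty((len(off), 4))
            p[:, 0] = 0.25 * (1 + s)           # A
            p[:, 1] = 0.25 * (1 - s)           # C
            p[:, 2] = 0.25 * (1 + s)           # G
            p[:, 3] = 0.25 * (1 - s)           # T
            u = rng.random(len(off))
            cdf = np.cumsum(p, axis=1)
            idx = (u[:, None] > cdf[:, :3]).sum(axis=1)
            seq[lo:hi] = _BASES[idx]
        new_seqs[chrom] = seq.tobytes().decode()
    return GenomeRef(list(genome.chrom_names), dict(genome.chrom_lengths),
                     new_seqs, {c: v.copy() for c, v in genome.mappable.items()})


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _draw_daf(rng: np.random.Generator, comp: np.ndarray) -> np.ndarray:
    """DAF given mixture component (0=rare <1%, 1=intermediate, 2=common >10%)."""
    n = len(comp)
    daf = np.empty(n)
    r = comp == 0
    daf[r] = 0.01 * rng.beta(1.0, 3.0, size=int(r.sum()))
    m = comp == 1
    daf[m] = 0.01 + 0.09 * rng.random(int(m.sum()))
    c = comp == 2
    daf[c] = 0.10 + 0.90 * rng.beta(1.0, 5.0, size=int(c.sum()))
    return daf


def _in_core(pos: np.ndarray, centers: np.ndarray, half: int) -> np.ndarray:
    """Boolean: is each position inside [c - half, c + half) of a center."""
    if len(centers) == 0:
        return np.zeros(len(pos), dtype=bool)
    if len(centers) > 1:
        idx = np.clip(np.searchsorted(centers, pos), 1, len(centers) - 1)
        left = centers[idx - 1]
        right = centers[idx]
        nearest = np.where(pos - left <= right - pos, left, right)
    else:
        nearest = np.full(len(pos), centers[0])
    off = pos - nearest
    return (off >= -half) & (off < half)


def simulate_variants(genome: GenomeRef, origins: OriginSet,
                      cfg: SimConfig) -> pd.DataFrame:
    """Polarized SNPs (and optionally indels) with core depletion.

    SNPs arise as a homogeneous Poisson process at ``snp_rate`` per bp; each
    gets a DAF from the three-component mixture. Inside the ``core_width``
    window around true origin centers, common-component variants are thinned
    by ``common_depletion``; rare and intermediate variants are untouched, so
    the rare-variant profile stays flat (a mutation-rate control).
    """
    rng = cfg.rng("variants")
    half = cfg.core_width // 2
    frames = []
    for chrom in genome.chrom_names:
        seq = np.frombuffer(genome.sequence[chrom].encode(), dtype=np.uint8)
        L = genome.chrom_lengths[chrom]
        sub = origins.by_chrom(chrom)
        centers = np.sort(sub["peak"].astype(np.int64).to_numpy()) if len(sub) \
            else np.empty(0, dtype=np.int64)
        for kind, rate in (("snp", cfg.snp_rate), ("indel", cfg.indel_rate)):
            if rate <= 0:
                continue
            n = rng.poisson(rate * L)
            pos = rng.integers(0, L - 1, size=n)
            comp = rng.choice(3, size=n, p=np.asarray(cfg.daf_weights))
            core = _in_core(pos, centers, half)
            drop = core & (comp == 2) & (rng.random(n) < cfg.common_depletion)
            pos, comp = pos[~drop], comp[~drop]
            anc_b = seq[pos]
            ok = anc_b != ord("N")
            pos, comp, anc_b = pos[ok], comp[ok], anc_b[ok]
            daf = _draw_daf(rng, comp)
            anc = np.char.mod("%c", anc_b)
            anc_idx = np.searchsorted(_BASES, anc_b)
            der_idx = (anc_idx + rng.integers(1, 4, size=len(pos))) % 4
            der = np.char.mod("%c", _BASES[der_idx])
            if kind == "indel":
                ins = rng.random(len(pos)) < 0.5
                anc = np.where(ins, anc, np.char.add(anc, der))
                der = np.where(ins, np.char.add(anc, der), anc.astype("U1"))
                # ancestral/derived now differ in length: insertion or deletion
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos.astype(np.int64),
                "ancestral": anc, "derived": der, "daf": daf,
            }))
    if not frames:
        return validate_variant_table(pd.DataFrame(
            columns=["chrom", "pos", "ancestral", "derived", "daf"]))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return validate_variant_table(df)


# ---------------------------------------------------------------------------
# homology
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def simulate_homology(genome_a: GenomeRef, truth_a: OriginSet, cfg: SimConfig,
                      shuffle: bool = True,
                      ) -> tuple[HomologyMap, GenomeRef, OriginSet, ReadTrack]:
    """Build a sister genome B by block-shuffling CGS out of genome A.

    A fraction ``cgs_fraction`` of A (in ``cgs_block`` chunks) becomes
    conserved genomic segments placed at shuffled positions (random
    orientation) in a same-sized genome B; the rest of B is random sequence.
    Among the top-25% most active truth origins whose center lies inside a
    CGS, an exact rounded fraction ``conserved_fraction`` gets a B origin
    planted at the homologous position. B is topped up (best effort) with
    random extra origins placed *outside* the CGS images — species-B-specific
    origins arise in non-homologous sequence — so the planted conserved
    fraction is exactly what interval mapping can recover; B reads are then
    simulated.

    With ``shuffle=False`` the map is the identity layout (same coordinates,
    all '+'), which is convenient for exact-recovery tests.
    """
    if cfg.conserved_fraction > 0 and cfg.cgs_fraction == 0:
        raise ValueError("conserved_fraction > 0 requires cgs_fraction > 0")
    rng = cfg.rng("homology")
    block = cfg.cgs_block
    half = cfg.origin_width // 2

    # --- choose CGS blocks on A and their destinations on B ---------------
    pairs = []
    b_name = "chrB1"
    a_blocks: list[tuple[str, int]] = []
    for chrom in genome_a.chrom_names:
        L = genome_a.chrom_lengths[chrom]
        for s in range(0, L - block + 1, block):
            a_blocks.append((chrom, s))
    n_sel = int(round(cfg.cgs_fraction * len(a_blocks)))
    sel_idx = np.sort(rng.choice(len(a_blocks), size=n_sel, replace=False))
    selected = [a_blocks[i] for i in sel_idx]

    b_len = genome_a.total_length
    n_b_blocks = b_len // block
    if shuffle:
        dest = rng.choice(n_b_blocks, size=n_sel, replace=False)
        orient = rng.choice(["+", "-"], size=n_sel)
    else:
        if cfg.n_chroms != 1:
            raise ValueError("identity layout requires a single chromosome")
        dest = np.array([s // block for _, s in selected])
        orient = np.array(["+"] * n_sel)

    # --- genome B sequence -------------------------------------------------
    seq_b = _BASES[rng.integers(0, 4, size=b_len)].tobytes().decode()
    seq_b = np.frombuffer(seq_b.encode(), dtype=np.uint8).copy()
    for (chrom, s), d, o in zip(selected, dest, orient):
        frag = genome_a.sequence[chrom][s:s + block]
        if o == "-":
            frag = frag.translate(_COMP)[::-1]
        seq_b[d * block:(d + 1) * block] = np.frombuffer(frag.encode(), np.uint8)
        pairs.append((chrom, s, s + block, b_name, d * block, (d + 1) * block, o))
    hmap = HomologyMap(pd.DataFrame(pairs, columns=HomologyMap.COLS))
    genome_b = GenomeRef([b_name], {b_name: b_len},
                         {b_name: seq_b.tobytes().decode()},
                         {b_name: np.array([[0, b_len]], dtype=np.int64)})

    # --- conserved origins on B -------------------------------------------
    from .conservation_turnover import map_interval, select_top_quartile

    top = select_top_quartile(truth_a)
    eligible = []
    for row in top.df.itertuples(index=False):
        c = int(row.peak)
        seg = hmap.segments_on(row.chrom)
        hit = seg[(seg["start_a"] <= c) & (seg["end_a"] > c)]
        if len(hit):
            eligible.append((row.chrom, c, float(row.intensity_rpkm)))
    n_cons = int(round(cfg.conserved_fraction * len(eligible)))
    order = rng.permutation(len(eligible))
    centers_b: list[tuple[int, float]] = []
    for i in order[:n_cons]:
        chrom, c, w = eligible[i]
        mapped = map_interval(hmap, Interval(chrom, c, c + 1))
        if mapped is None:
            continue
        centers_b.append((mapped.start, w))

    # top up with random extra origins outside CGS images, respecting spacing
    images = np.sort(np.asarray(dest, dtype=np.int64)) * block
    margin = max(cfg.min_spacing, half + 1)
    taken = sorted(c for c, _ in centers_b)
    n_extra = max(0, len(truth_a) - len(centers_b))
    tries = 0
    while n_extra > 0 and tries < 200 * max(1, len(truth_a)):
        tries += 1
        c = int(rng.integers(margin, b_len - margin))
        if len(images):
            j = np.searchsorted(images, c, side="right") - 1
            if j >= 0 and c < images[j] + block + cfg.origin_width:
                continue
            if j + 1 < len(images) and c + cfg.origin_width > images[j + 1]:
                continue
        i = bisect.bisect_left(taken, c)
        if i > 0 and c - taken[i - 1] < cfg.min_spacing:
            continue
        if i < len(taken) and taken[i] - c < cfg.min_spacing:
            continue
        taken.insert(i, c)
        w = float(rng.lognormal(-0.5 * cfg.intensity_sigma ** 2,
                                cfg.intensity_sigma))
        centers_b.append((c, w))
        n_extra -= 1

    intervals_b = [
        Interval(b_name, c - half, c + (cfg.origin_width - half),
                 peak=c, intensity_rpkm=w)
        for c, w in sorted(centers_b)
        if half <= c <= b_len - (cfg.origin_width - half)
    ]
    origins_b = OriginSet(intervals_b)
    reads_b = simulate_reads(genome_b, origins_b, cfg, stream="reads_b")
    return hmap, genome_b, origins_b, reads_b
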