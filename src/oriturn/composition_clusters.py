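"""Background compositional clustering of short genomic segments.

Genomes are compositionally heterogeneous (isochores, CpG islands), which
confounds naive motif-enrichment tests. The remedy used here: sample random
40-bp segments, reduce their 5-mer count matrix with non-negative matrix
factorization (6 axes), k-means the loadings into 6 background clusters,
assign origin cores to those clusters by a maximum-a-posteriori rule, and
test motif enrichment cluster-wise so each comparison happens inside a
compositionally homogeneous stratum.

:class:`CompositionClusterer` is the scikit-learn style estimator; the
module functions wrap it and the surrounding plumbing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

from .io_formats import GenomeRef, Interval

__all__ = [
    "KmerMatrix",
    "CompositionClusterer",
    "sample_random_segments",
    "kmer_counts",
    "fit_background_clusters",
    "assign_map",
    "motif_fold_enrichment",
    "DEFAULT_MOTIFS",
]

# the short motifs reported as enriched in origin cores (reverse complements
# are counted by scanning both strands)
DEFAULT_MOTIFS = ("CG", "CCC", "GAG", "AC")

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class KmerMatrix:
    """Segments x k-mers count matrix (overlapping windows, given strand)."""

    counts: np.ndarray          # (n_segments, 4**k) int
    k: int
    segments: list[Interval] | None = None

    @property
    def kmers(self) -> list[str]:
        return ["".join(p) for p in product("ACGT", repeat=self.k)]


# ---------------------------------------------------------------------------
# sampling and counting
# ---------------------------------------------------------------------------

def sample_random_segments(genome: GenomeRef, n: int, length: int = 40,
                           seed: int = 0) -> list[Interval]:
    """n segments uniform over mappable starts, never crossing a gap or end."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    choices = []   # (chrom, iv_start, n_starts)
    for chrom in genome.chrom_names:
        for s, e in genome.mappable[chrom]:
            if e - s >= length:
                choices.append((chrom, int(s), int(e - s - length + 1)))
    if not choices:
        raise ValueError(f"no mappable stretch can hold a {length} bp segment")
    sizes = np.array([c[2] for c in choices], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(sizes)))
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    out = []
    for j, ui in zip(idx, u):
        chrom, base, _ = choices[j]
        start = base + int(ui - cum[j])
        out.append(Interval(chrom, start, start + length))
    return out


def kmer_counts(segments: list[Interval], genome: GenomeRef,
                k: int = 5) -> KmerMatrix:
    """Overlapping k-mer counts per segment on the given strand.

    Windows containing N are skipped, so a clean segment of length L
    contributes L - k + 1 counts.
    """
    n_kmers = 4 ** k
    mat = np.zeros((len(segments), n_kmers), dtype=np.int64)
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    mult = 4 ** np.arange(k - 1, -1, -1)
    for i, seg in enumerate(segments):
        if seg.length < k:
            raise ValueError(f"segment {i} shorter than k={k}")
        seq = np.frombuffer(
            genome.fetch(seg.chrom, seg.start, seg.end).encode(), dtype=np.uint8
        )
        c = code[seq]
        win = np.lib.stride_tricks.sliding_window_view(c, k)
        valid = (win >= 0).all(axis=1)
        if valid.any():
            codes = (win[valid] * mult).sum(axis=1)
            mat[i] = np.bincount(codes, minlength=n_kmers)
    return KmerMatrix(mat, k, list(segments))


# ---------------------------------------------------------------------------
# the clusterer
# ---------------------------------------------------------------------------

class CompositionClusterer(ClusterMixin, BaseEstimator):
    """NMF dimension reduction + k-means background clustering.

    ``fit(X)`` factorizes the (segments x k-mers) count matrix into
    ``n_axes`` non-negative components and k-means the loadings into
    ``n_clusters`` groups (``n_init`` restarts, best inertia kept).
    ``predict(X)`` projects new segments into the component space and
    assigns each to a cluster by the maximum-a-posteriori rule under a
    spherical Gaussian per cluster with empirical priors; ties break to the
    larger prior, then the lower cluster index.
    """

    def __init__(self, n_axes: int = 6, n_clusters: int = 6,
                 n_init: int = 10, max_iter: int = 500,
                 random_state: int = 0):
        self.n_axes = n_axes
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    @staticmethod
    def _matrix(X) -> np.ndarray:
        arr = X.counts if isinstance(X, KmerMatrix) else np.asarray(X)
        zero = np.flatnonzero(arr.sum(axis=1) == 0)
        if len(zero):
            raise ValueError(f"all-zero k-mer rows: {zero.tolist()[:20]}")
        return arr.astype(float)

    def fit(self, X, y=None) -> "CompositionClusterer":
        arr = self._matrix(X)
        if arr.shape[0] < self.n_clusters * 10:
            raise ValueError(
                f"need >= {self.n_clusters * 10} segments to fit "
                f"{self.n_clusters} clusters"
            )
        self.nmf_ = NMF(n_components=self.n_axes, init="nndsvda",
                        max_iter=self.max_iter, random_state=self.random_state)
        W = self.nmf_.fit_transform(arr)
        self.kmeans_ = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                              random_state=self.random_state)
        self.labels_ = self.kmeans_.fit_predict(W)
        self.embedding_ = W
        k = self.n_clusters
        counts = np.bincount(self.labels_, minlength=k)
        self.priors_ = counts / counts.sum()
        d = W.shape[1]
        self.sigma2_ = np.empty(k)
        for c in range(k):
            pts = W[self.labels_ == c]
            if len(pts):
                self.sigma2_[c] = max(
                    ((pts - self.kmeans_.cluster_centers_[c]) ** 2).sum()
                    / (len(pts) * d), 1e-12,
                )
            else:
                self.sigma2_[c] = 1e-12
        self.cluster_sizes_ = counts
        return self

    def transform(self, X) -> np.ndarray:
        return self.nmf_.transform(self._matrix(X))

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "kmeans_"):
            raise ValueError("CompositionClusterer is not fitted")
        W = self.transform(X)
        d = W.shape[1]
        centers = self.kmeans_.cluster_centers_
        dist2 = ((W[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        with np.errstate(divide="ignore"):
            log_post = (
                np.log(np.maximum(self.priors_, 1e-300))[None, :]
                - 0.5 * d * np.log(self.sigma2_)[None, :]
                - dist2 / (2.0 * self.sigma2_[None, :])
            )
        # ties: larger prior wins, then lower index
        order = np.lexsort((np.arange(self.n_clusters), -self.priors_))
        reordered = log_post[:, order]
        best = np.argmax(reordered, axis=1)
        return order[best]

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def fit_background_clusters(matrix: KmerMatrix, n_axes: int = 6,
                            n_clusters: int = 6,
                            seed: int = 0) -> CompositionClusterer:
    """Fit the background cluster model on random-segment k-mer counts."""
    return CompositionClusterer(
        n_axes=n_axes, n_clusters=n_clusters, random_state=seed
    ).fit(matrix)


def assign_map(model: CompositionClusterer, matrix: KmerMatrix) -> np.ndarray:
    """MAP cluster labels for origin-core segments."""
    return model.predict(matrix)


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

def _count_motif(seqs: list[str], motif: str) -> tuple[int, int]:
    """(occurrences on both strands incl. overlaps, total scanned bp)."""
    pat = re.compile("(?=" + re.escape(motif) + ")")
    rc = motif.translate(_COMP)[::-1]
    pat_rc = re.compile("(?=" + re.escape(rc) + ")")
    occ = 0
    bp = 0
    for s in seqs:
        occ += sum(1 for _ in pat.finditer(s))
        occ += sum(1 for _ in pat_rc.finditer(s))
        bp += len(s)
    return occ, bp


def motif_fold_enrichment(core_seqs: list[str], core_labels: np.ndarray,
                          rand_seqs: list[str], rand_labels: np.ndarray,
                          motifs: tuple[str, ...] = DEFAULT_MOTIFS,
                          min_segments: int = 20) -> pd.DataFrame:
    """Cluster-wise motif fold-enrichment of origin cores vs random segments.

    fold = (occurrences per bp in cores of cluster c) / (per bp in random
    segments of cluster c), motifs counted on both strands with overlaps.
    Columns: cluster, motif, fold, p_value (Fisher exact on occurrence vs bp
    counts), n_core, n_random, flag ("ok", "unstable" for clusters with
    fewer than ``min_segments`` random segments, "degenerate" when the
    random rate is zero; degenerate folds are reported as inf).
    """
    core_labels = np.asarray(core_labels)
    rand_labels = np.asarray(rand_labels)
    seg_len = min((len(s) for s in core_seqs + rand_seqs), default=0)
    for m in motifs:
        if len(m) > seg_len:
            raise ValueError(f"motif {m!r} longer than the shortest segment")
    rows = []
    clusters = sorted(set(core_labels.tolist()) | set(rand_labels.tolist()))
    for c in clusters:
        cs = [core_seqs[i] for i in np.flatnonzero(core_labels == c)]
        rs = [rand_seqs[i] for i in np.flatnonzero(rand_labels == c)]
        for m in motifs:
            occ_c, bp_c = _count_motif(cs, m)
            occ_r, bp_r = _count_motif(rs, m)
            flag = "ok" if len(rs) >= min_segments else "unstable"
            if bp_c == 0 or bp_r == 0 or occ_r == 0:
                fold = np.inf if occ_c > 0 else np.nan
                flag = "degenerate"
                p = np.nan
            else:
                fold = (occ_c / bp_c) / (occ_r / bp_r)
                table = [[occ_c, max(bp_c - occ_c, 0)],
                         [occ_r, max(bp_r - occ_r, 0)]]
                p = float(stats.fisher_exact(table)[1])
            rows.append((c, m, float(fold), p, len(cs), len(rs), flag))
    return pd.DataFrame(
        rows, columns=["cluster", "motif", "fold", "p_value",
                       "n_core", "n_random", "flag"]
    )
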