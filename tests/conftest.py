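import numpy as np
import pytest

from oriturn.io_formats import GenomeRef, Interval, OriginSet, ReadTrack
from oriturn.synthetic_data import SimConfig, make_genome, plant_origins


def make_flat_genome(length: int, base: str = "A", name: str = "chr1",
                     gc: float | None = None, seed: int = 0) -> GenomeRef:
    """A single-chromosome genome, constant or iid-random sequence."""
    if gc is None:
        seq = base * length
    else:
        rng = np.random.default_rng(seed)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return GenomeRef([name], {name: length}, {name: seq},
                     {name: np.array([[0, length]], dtype=np.int64)})


@pytest.fixture(scope="session")
def small_system():
    """A 2-Mb genome with planted origins shared across read-only tests."""
    cfg = SimConfig(genome_length=2_000_000, seed=101)
    genome = make_genome(cfg)
    truth = plant_origins(genome, cfg)
    return cfg, genome, truth


@pytest.fixture
def toy_track():
    return ReadTrack({"chr1": np.array([10, 499, 500, 1500, 1501, 1502])})


@pytest.fixture
def toy_origin():
    return Interval("chr1", 1000, 2000, peak=1500, intensity_rpkm=3.0)


# ---------------------------------------------------------------------------
# motif-planting helpers shared by the composition and acceptance suites
# ---------------------------------------------------------------------------

def both_strand_count(seq: str, motif: str) -> int:
    """Overlapping occurrences of a motif on both strands of one sequence."""
    import re
    comp = str.maketrans("ACGT", "TGCA")
    rc = motif.translate(comp)[::-1]
    n = sum(1 for _ in re.finditer("(?=" + motif + ")", seq))
    n += sum(1 for _ in re.finditer("(?=" + rc + ")", seq))
    return n


def plant_doubling(seqs: list[str], motif: str,
                   rng: np.random.Generator) -> list[str]:
    """Insert motif copies until each segment doubles its own both-strand
    occurrence count. Each accepted insertion adds exactly one occurrence;
    insertions that would create or destroy extra occurrences are retried,
    so the planted rate is 2x by construction."""
    out = []
    for s in seqs:
        target = 2 * both_strand_count(s, motif)
        cur = s
        tries = 0
        while both_strand_count(cur, motif) < target and tries < 100:
            tries += 1
            p = int(rng.integers(0, len(cur) - len(motif) + 1))
            cand = cur[:p] + motif + cur[p + len(motif):]
            if both_strand_count(cand, motif) == both_strand_count(cur, motif) + 1:
                cur = cand
        out.append(cur)
    return out
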