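import numpy as np
import pytest

from creatlas.tracks import ElementSet, GenomicInterval, SignalTrack


@pytest.fixture
def tiny_elements() -> ElementSet:
    return ElementSet(
        [
            GenomicInterval("chr1", 10, 20, "E1"),
            GenomicInterval("chr1", 40, 60, "E2"),
            GenomicInterval("chr2", 5, 25, "E3"),
        ]
    )


@pytest.fixture
def constant_track() -> SignalTrack:
    return SignalTrack.constant({"chr1": 1000, "chr2": 1000}, 3.0)


def random_track(rng: np.random.Generator, chrom_len: int = 200) -> SignalTrack:
    """Random sparse run-length track on one chromosome."""
    edges = np.sort(rng.choice(chrom_len, size=rng.integers(4, 12), replace=False))
    runs = []
    for s, e in zip(edges[:-1], edges[1:]):
        if rng.random() < 0.6:
            runs.append((int(s), int(e), float(rng.uniform(0, 5))))
    if not runs:
        runs = [(0, chrom_len, 1.0)]
    return SignalTrack.from_runs({"chr1": runs})


def dense_oracle(track: SignalTrack, chrom: str, length: int) -> np.ndarray:
    """Brute-force dense expansion of a run-length track."""
    out = np.zeros(length)
    if chrom not in track.data:
        return out
    starts, ends, values = track.data[chrom]
    for s, e, v in zip(starts, ends, values):
        out[s:e] = v
    return out
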