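"""Genomic intervals and per-base signal tracks.

Coordinates are 0-based half-open (BED convention) everywhere.  Signal
tracks are run-length encoded per chromosome; positions not covered by a
run have value 0, matching bedGraph sparsity semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "ElementSet",
    "SignalTrack",
    "read_element_bed",
    "read_labeled_bed",
    "mean_signal_over_elements",
    "sum_tracks",
    "overlap_fractions",
    "count_overlapping",
]


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an identifier."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for {self.id}: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.id} has start >= end ({self.start} >= {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ElementSet:
    """An ordered collection of genomic intervals with optional class labels.

    Elements are kept sorted by (chrom, start, end) and ids must be unique.
    """

    def __init__(
        self,
        elements: Iterable[GenomicInterval],
        labels: Mapping[str, str] | None = None,
    ) -> None:
        elems = sorted(elements, key=lambda e: (e.chrom, e.start, e.end))
        ids = [e.id for e in elems]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate element id: {dup!r}")
        self.elements: list[GenomicInterval] = elems
        self.labels: dict[str, str] | None = dict(labels) if labels is not None else None
        if self.labels is not None:
            unknown = set(self.labels) - set(ids)
            if unknown:
                raise ValueError(f"labels reference unknown ids: {sorted(unknown)[:5]}")
        self._by_id = {e.id: e for e in elems}

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.elements)

    def __getitem__(self, element_id: str) -> GenomicInterval:
        return self._by_id[element_id]

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.elements]

    def label_of(self, element_id: str, default: str | None = None) -> str | None:
        if self.labels is None:
            return default
        return self.labels.get(element_id, default)

    def subset(self, ids: Iterable[str]) -> "ElementSet":
        keep = set(ids)
        elems = [e for e in self.elements if e.id in keep]
        labels = None
        if self.labels is not None:
            labels = {i: l for i, l in self.labels.items() if i in keep}
        return ElementSet(elems, labels)

    def with_labels(self, labels: Mapping[str, str]) -> "ElementSet":
        return ElementSet(self.elements, labels)

    def chroms(self) -> list[str]:
        return sorted({e.chrom for e in self.elements})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
        """Per-chrom (starts, ends, ids), sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        cur: str | None = None
        starts: list[int] = []
        ends: list[int] = []
        ids: list[str] = []
        for e in self.elements:
            if e.chrom != cur:
                if cur is not None:
                    out[cur] = (np.asarray(starts), np.asarray(ends), ids)
                cur, starts, ends, ids = e.chrom, [], [], []
            starts.append(e.start)
            ends.append(e.end)
            ids.append(e.id)
        if cur is not None:
            out[cur] = (np.asarray(starts), np.asarray(ends), ids)
        return out

    def merged(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chrom merged, non-overlapping (starts, ends)."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, _) in self.by_chrom().items():
            ms: list[int] = []
            me: list[int] = []
            for s, e in zip(starts, ends):
                if ms and s <= me[-1]:
                    me[-1] = max(me[-1], int(e))
                else:
                    ms.append(int(s))
                    me.append(int(e))
            out[chrom] = (np.asarray(ms), np.asarray(me))
        return out

    def to_bed(self, path, name: str = "id") -> None:
        """Write BED4; ``name`` selects column 4 ("id" or "label")."""
        with open(path, "w") as fh:
            for e in self.elements:
                if name == "label":
                    col4 = self.label_of(e.id, ".")
                else:
                    col4 = e.id
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{col4}\n")


def read_element_bed(path) -> ElementSet:
    """Read a BED3+ file into an :class:`ElementSet`.

    A 4th column, when present, is used as the element id; otherwise ids
    are auto-generated as ``chrom:start-end``.
    """
    elems: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            eid = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            try:
                elems.append(GenomicInterval(chrom, start, end, eid))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return ElementSet(elems)


def read_labeled_bed(path) -> ElementSet:
    """Read BED4 where column 4 is a (non-unique) class label.

    Ids are auto-generated as ``chrom:start-end``; labels go into
    ``ElementSet.labels``.
    """
    elems: list[GenomicInterval] = []
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: expected >=4 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            eid = f"{chrom}:{start}-{end}"
            elems.append(GenomicInterval(chrom, start, end, eid))
            labels[eid] = fields[3]
    return ElementSet(elems, labels)


class SignalTrack:
    """Run-length-encoded nonnegative per-base signal over a genome.

    ``data`` maps chrom -> (starts, ends, values) with runs sorted and
    non-overlapping.  Gaps have implicit value 0.
    """

    def __init__(
        self,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        allow_negative: bool = False,
    ) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged run arrays")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted run")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping runs")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite values")
            if not allow_negative and np.any(values < 0):
                raise ValueError(f"{chrom}: negative values in track")
            clean[chrom] = (starts, ends, values)
        self.data = clean
        self.allow_negative = allow_negative

    @classmethod
    def from_runs(
        cls,
        runs: Mapping[str, Iterable[tuple[int, int, float]]],
        allow_negative: bool = False,
    ) -> "SignalTrack":
        data = {}
        for chrom, rs in runs.items():
            rs = list(rs)
            data[chrom] = (
                np.array([r[0] for r in rs], dtype=np.int64),
                np.array([r[1] for r in rs], dtype=np.int64),
                np.array([r[2] for r in rs], dtype=np.float64),
            )
        return cls(data, allow_negative=allow_negative)

    @classmethod
    def constant(cls, chrom_sizes: Mapping[str, int], value: float) -> "SignalTrack":
        return cls(
            {
                c: (np.array([0]), np.array([n]), np.array([float(value)]))
                for c, n in chrom_sizes.items()
            },
            allow_negative=value < 0,
        )

    @classmethod
    def read_bedgraph(cls, path, allow_negative: bool = False) -> "SignalTrack":
        runs: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise BedParseError(f"{path}: line {lineno}: expected 4 columns")
                try:
                    runs.setdefault(fields[0], []).append(
                        (int(fields[1]), int(fields[2]), float(fields[3]))
                    )
                except ValueError as exc:
                    raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
        return cls.from_runs(runs, allow_negative=allow_negative)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                starts, ends, values = self.data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); gaps and missing chroms are 0."""
        if end <= start:
            raise ValueError("dense(): empty interval")
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.data:
            return out
        starts, ends, values = self.data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                out[s - start : e - start] = values[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Base-weighted mean of the track over [start, end)."""
        if end <= start:
            raise ValueError("mean(): empty interval")
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        w = np.maximum(e - s, 0)
        return float(np.dot(w, values[lo:hi]) / (end - start))

    def total_mass(self) -> float:
        """Sum of value x run length over all runs (signal conservation checks)."""
        return float(
            sum(np.dot(ends - starts, values) for starts, ends, values in self.data.values())
        )


def mean_signal_over_elements(track: SignalTrack, elements: ElementSet) -> np.ndarray:
    """Base-weighted mean of ``track`` over each element, in element order.

    Elements on chroms absent from the track get 0 with a warning.
    """
    missing = sorted({e.chrom for e in elements} - set(track.data))
    if missing:
        warnings.warn(
            f"elements on chroms absent from track get signal 0: {missing}",
            stacklevel=2,
        )
    return np.array([track.mean(e.chrom, e.start, e.end) for e in elements])


def sum_tracks(tracks: list[SignalTrack]) -> SignalTrack:
    """Pointwise sum of signal tracks, re-normalized to sorted runs."""
    if not tracks:
        raise ValueError("sum_tracks() requires at least one track")
    if len(tracks) == 1:
        return tracks[0]
    allow_negative = any(t.allow_negative for t in tracks)
    chroms = sorted(set().union(*(t.data.keys() for t in tracks)))
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        bounds: set[int] = set()
        for t in tracks:
            if chrom in t.data:
                starts, ends, _ = t.data[chrom]
                bounds.update(starts.tolist())
                bounds.update(ends.tolist())
        edges = np.array(sorted(bounds), dtype=np.int64)
        seg_s, seg_e = edges[:-1], edges[1:]
        total = np.zeros(len(seg_s), dtype=np.float64)
        for t in tracks:
            if chrom not in t.data:
                continue
            starts, ends, values = t.data[chrom]
            # run covering each segment start, if any
            idx = np.searchsorted(starts, seg_s, side="right") - 1
            valid = (idx >= 0) & (seg_s < ends[np.clip(idx, 0, None)])
            total[valid] += values[idx[valid]]
        keep = total != 0.0
        # merge adjacent equal-value segments
        ks, ke, kv = seg_s[keep], seg_e[keep], total[keep]
        ms: list[int] = []
        me: list[int] = []
        mv: list[float] = []
        for s, e, v in zip(ks, ke, kv):
            if ms and s == me[-1] and v == mv[-1]:
                me[-1] = int(e)
            else:
                ms.append(int(s))
                me.append(int(e))
                mv.append(float(v))
        out[chrom] = (np.asarray(ms), np.asarray(me), np.asarray(mv))
    return SignalTrack(out, allow_negative=allow_negative)


def overlap_fractions(
    query: ElementSet, targets: ElementSet
) -> dict[str, list[tuple[str, float]]]:
    """Per query element, overlapping targets and overlap bp / target length.

    Only overlapping pairs are reported; fractions are in (0, 1].
    """
    tgt = targets.by_chrom()
    out: dict[str, list[tuple[str, float]]] = {}
    for q in query:
        hits: list[tuple[str, float]] = []
        if q.chrom in tgt:
            starts, ends, ids = tgt[q.chrom]
            hi = int(np.searchsorted(starts, q.end, side="left"))
            for i in range(hi):
                ov = min(q.end, int(ends[i])) - max(q.start, int(starts[i]))
                if ov > 0:
                    hits.append((ids[i], ov / (int(ends[i]) - int(starts[i]))))
        if hits:
            out[q.id] = hits
    return out


def count_overlapping(
    intervals: Iterable[tuple[str, int, int]],
    merged_targets: Mapping[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """Number of intervals overlapping >=1 bp of the merged target intervals."""
    n = 0
    for chrom, start, end in intervals:
        if chrom not in merged_targets:
            continue
        ms, me = merged_targets[chrom]
        # last merged target starting before `end`; earlier ones end sooner
        i = int(np.searchsorted(ms, end, side="left")) - 1
        if i >= 0 and me[i] > start:
            n += 1
    return n
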