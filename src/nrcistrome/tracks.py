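"""Mappability and sequencing-tag tracks.

A :class:`MappabilityTrack` stores, per chromosome, the sorted disjoint
intervals of uniquely mappable base pairs; the peak caller's window
probability is a ratio of mappable-bp counts, so fast interval-coverage
queries are the core operation here.

A :class:`TagTrack` stores aligned tag 5' positions as a sparse
position -> count map per chromosome.  Tags are reduced to their single 5'
base; no fragment extension is applied.  A multiplicative ``scale`` supports
depth normalization of input libraries without rewriting counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .intervals import GenomicInterval


@dataclass
class MappabilityTrack:
    """Per-chromosome sorted disjoint intervals of uniquely mappable bp."""

    #: chrom -> (starts, ends) as sorted int arrays, plus cumulative lengths
    _data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "MappabilityTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        track = cls()
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            # merge touching/overlapping blocks so disjointness holds
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            track._data[chrom] = (starts, ends, cum)
        return track

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._data):
            starts, ends, _ = self._data[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield GenomicInterval(chrom, s, e)

    def chrom_extent(self, chrom: str) -> int:
        """Rightmost mappable coordinate (used as a chromosome-length fallback)."""
        starts, ends, _ = self._require(chrom)
        return int(ends[-1]) if len(ends) else 0

    def _require(self, chrom: str):
        if chrom not in self._data:
            raise KeyError(f"unknown chromosome {chrom!r} in mappability track")
        return self._data[chrom]

    def coverage_to(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vector of mappable bp in ``[0, pos)`` for each position."""
        starts, ends, cum = self._require(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(ends, positions, side="right")
        full = cum[idx]
        # partial block: position falls inside block idx
        inside = (idx < len(starts)) & (positions > starts[np.minimum(idx, len(starts) - 1)])
        partial = np.where(
            inside, positions - starts[np.minimum(idx, len(starts) - 1)], 0
        )
        return full + partial

    def mappable_bp_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        return self.coverage_to(chrom, ends) - self.coverage_to(chrom, starts)


def mappable_bp(interval: GenomicInterval, track: MappabilityTrack) -> int:
    """Uniquely mappable base pairs inside ``interval``.

    Raises ``KeyError`` for a chromosome the track does not know.  An empty
    track (no chromosomes) yields 0 for any chromosome, matching the
    degenerate "nothing is mappable" reading.
    """
    if not track.chroms:
        return 0
    out = track.mappable_bp_many(
        interval.chrom,
        np.array([interval.start], dtype=np.int64),
        np.array([interval.end], dtype=np.int64),
    )
    return int(out[0])


@dataclass
class TagTrack:
    """Sparse per-chromosome tag 5'-position counts for one sample.

    ``scale`` is a multiplicative factor applied to every count when querying
    through :meth:`count_in`; it is how input libraries are normalized to the
    matched ChIP depth without mutating stored integers.
    """

    #: chrom -> (sorted unique positions int64, counts int64, cumulative counts)
    _data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    total_tags: int = 0
    scale: float = 1.0

    @classmethod
    def from_positions(
        cls, positions_by_chrom: Mapping[str, np.ndarray], scale: float = 1.0
    ) -> "TagTrack":
        """Build from raw (possibly duplicated, unsorted) tag positions."""
        track = cls(scale=scale)
        total = 0
        for chrom, raw in positions_by_chrom.items():
            raw = np.asarray(raw, dtype=np.int64)
            pos, counts = np.unique(raw, return_counts=True)
            track._data[chrom] = (pos, counts, np.concatenate([[0], np.cumsum(counts)]))
            total += int(counts.sum())
        track.total_tags = total
        return track

    @classmethod
    def from_counts(
        cls, counts_by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]], scale: float = 1.0
    ) -> "TagTrack":
        track = cls(scale=scale)
        total = 0
        for chrom, (pos, counts) in counts_by_chrom.items():
            pos = np.asarray(pos, dtype=np.int64)
            counts = np.asarray(counts, dtype=np.int64)
            if np.any(counts < 0):
                raise ValueError("tag counts must be non-negative")
            order = np.argsort(pos, kind="stable")
            pos, counts = pos[order], counts[order]
            keep = counts > 0
            pos, counts = pos[keep], counts[keep]
            track._data[chrom] = (pos, counts, np.concatenate([[0], np.cumsum(counts)]))
            total += int(counts.sum())
        track.total_tags = total
        return track

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @property
    def effective_total(self) -> float:
        return self.total_tags * self.scale

    def positions(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, counts) for one chromosome; empty arrays if absent."""
        if chrom not in self._data:
            empty = np.array([], dtype=np.int64)
            return empty, empty
        pos, counts, _ = self._data[chrom]
        return pos, counts

    def counts_in_ranges(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Scaled tag counts in each half-open range ``[start, end)``."""
        if chrom not in self._data:
            return np.zeros(len(np.atleast_1d(starts)), dtype=float)
        pos, _, cum = self._data[chrom]
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        return (cum[hi] - cum[lo]) * self.scale

    def count_in(self, interval: GenomicInterval) -> float:
        return float(
            self.counts_in_ranges(
                interval.chrom,
                np.array([interval.start]),
                np.array([interval.end]),
            )[0]
        )

    def rescaled(self, scale: float) -> "TagTrack":
        out = TagTrack(total_tags=self.total_tags, scale=scale)
        out._data = self._data  # stored counts are immutable by convention
        return out


# ---------------------------------------------------------------------------
# BED I/O


def read_bed3(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3(+) file into intervals; extra columns ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed3(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_mappability(path: str | Path) -> MappabilityTrack:
    return MappabilityTrack.from_intervals(read_bed3(path))


def read_tags_bed(path: str | Path) -> TagTrack:
    """Read tags from BED6 (one record per tag; 5' position = BED start).

    Strand (column 6) is retained in the file format but unused by the
    window statistic, so it is not stored.
    """
    by_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            by_chrom.setdefault(fields[0], []).append(int(fields[1]))
    return TagTrack.from_positions(
        {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}
    )


def write_tags_bed(track: TagTrack, path: str | Path, tag_length: int = 36) -> None:
    """Write one BED6 record per tag (counts expanded), '+' strand."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            pos, counts = track.positions(chrom)
            for p, c in zip(pos.tolist(), counts.tolist()):
                for _ in range(c):
                    fh.write(f"{chrom}\t{p}\t{p + tag_length}\ttag\t0\t+\n")
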