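"""Hotspot-style windowed binomial z-score peak calling.

Local tag enrichment is scored in a small target window (default 150 bp)
against a large local background window (default 200 kb) under a binomial
model.  A window with ``n`` input-subtracted tags, ``N`` background tags and
mappability probability ``p`` (mappable bp in the target window over
mappable bp in the background window) is scored

    z = (n - N*p) / sqrt(N*p*(1-p))

and windows with ``z`` above the threshold (default 60) are retained and
merged into peaks.  Peaks overlapping a knockout-null peak by more than
1 bp are treated as non-specific and excluded.

Candidate windows are anchored at tag-bearing positions (the window
``[pos, pos + window_bp)`` for every distinct ChIP tag 5' position) rather
than tiled at every bp; an exhaustive every-window scoring of small
chromosomes is used as a test oracle for this choice.  The background
window is centered on the target window and clipped at chromosome ends,
with ``p`` recomputed from the clipped extent.  ``N`` is counted from the
ChIP track alone; input subtraction applies only to the target window and
is floored at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, interval_overlap
from .tracks import MappabilityTrack, TagTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakCallerParams:
    window_bp: int = 150
    background_bp: int = 200_000
    z_threshold: float = 60.0
    min_window_tags: int = 1
    merge_adjacent: bool = True

    def __post_init__(self) -> None:
        if not self.window_bp < self.background_bp:
            raise ValueError("window_bp must be smaller than background_bp")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass(frozen=True)
class PeakCall:
    """A called enrichment region.

    ``n``, ``N``, ``p`` and ``z`` are the statistics of the maximum-z window
    contributing to the (possibly merged) region ``interval``.
    """

    interval: GenomicInterval
    n: float
    N: int
    p: float
    z: float
    sample: str = ""


def normalize_input(input_track: TagTrack, chip_total: int) -> TagTrack:
    """Scale an input library to match the ChIP library size.

    Returns a view of the same counts with ``scale = chip_total /
    input_total`` so that the effective total equals ``chip_total`` exactly
    as a real number.
    """
    if input_track.total_tags <= 0:
        raise ValueError("input track has zero tags; cannot normalize")
    return input_track.rescaled(chip_total / input_track.total_tags)


def window_zscore(n: float, N: int, p: float) -> float:
    """Binomial z-score of ``n`` observed tags given ``N`` background tags.

    ``z = (n - mu) / sigma`` with ``mu = N*p`` and
    ``sigma = sqrt(N*p*(1-p))``; returns 0 when ``N`` is 0.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if n < 0:
        raise ValueError("n must be non-negative")
    if N == 0:
        return 0.0
    mu = N * p
    sigma = math.sqrt(N * p * (1.0 - p))
    return (n - mu) / sigma


def _chrom_lengths(
    chip: TagTrack,
    mappability: MappabilityTrack,
    chrom_lengths: Mapping[str, int] | None,
) -> dict[str, int]:
    out: dict[str, int] = {}
    for chrom in chip.chroms:
        if chrom_lengths is not None and chrom in chrom_lengths:
            out[chrom] = int(chrom_lengths[chrom])
        else:
            pos, _ = chip.positions(chrom)
            tag_hi = int(pos[-1]) + 1 if len(pos) else 0
            map_hi = mappability.chrom_extent(chrom) if chrom in mappability.chroms else 0
            out[chrom] = max(tag_hi, map_hi)
    return out


def call_hotspots(
    chip: TagTrack,
    input_scaled: TagTrack,
    mappability: MappabilityTrack,
    params: PeakCallerParams = PeakCallerParams(),
    sample: str = "",
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[PeakCall]:
    """Call enrichment peaks on one ChIP sample.

    ``input_scaled`` should already be depth-normalized (see
    :func:`normalize_input`); per window, ``n = max(0, chip - input)``.
    Windows whose target mappable bp is zero are skipped (``p`` undefined).
    Output is sorted by (chrom, start).
    """
    w = params.window_bp
    half_bg = params.background_bp // 2
    peaks: list[PeakCall] = []
    lengths = _chrom_lengths(chip, mappability, chrom_lengths)
    for chrom in sorted(chip.chroms):
        if chrom not in mappability.chroms:
            logger.debug("chromosome %s absent from mappability track; skipped", chrom)
            continue
        clen = lengths[chrom]
        pos, _ = chip.positions(chrom)
        if len(pos) == 0:
            continue
        starts = np.minimum(pos, max(clen - w, 0))
        starts = np.unique(starts)
        ends = starts + w
        chip_n = chip.counts_in_ranges(chrom, starts, ends)
        input_n = input_scaled.counts_in_ranges(chrom, starts, ends)
        n = np.maximum(chip_n - input_n, 0.0)
        centers = starts + w // 2
        bg_starts = np.maximum(centers - half_bg, 0)
        bg_ends = np.minimum(centers + half_bg, clen)
        N = chip.counts_in_ranges(chrom, bg_starts, bg_ends)
        map_w = mappability.mappable_bp_many(chrom, starts, ends)
        map_bg = mappability.mappable_bp_many(chrom, bg_starts, bg_ends)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(map_bg > 0, map_w / np.maximum(map_bg, 1), 0.0)
        valid = (map_w > 0) & (p > 0.0) & (p < 1.0) & (chip_n >= params.min_window_tags)
        n_skipped = int(np.sum(map_w == 0))
        if n_skipped:
            logger.debug(
                "%s: skipped %d windows with zero mappable bp", chrom, n_skipped
            )
        mu = N * p
        sigma = np.sqrt(N * p * (1.0 - p))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where((N > 0) & valid & (sigma > 0), (n - mu) / np.maximum(sigma, 1e-300), 0.0)
        keep = valid & (z > params.z_threshold)
        idx = np.flatnonzero(keep)
        if len(idx) == 0:
            continue
        peaks.extend(
            _merge_windows(
                chrom,
                starts[idx],
                ends[idx],
                n[idx],
                N[idx].astype(np.int64),
                p[idx],
                z[idx],
                sample,
                merge=params.merge_adjacent,
            )
        )
    peaks.sort(key=lambda pk: (pk.interval.chrom, pk.interval.start))
    return peaks


def _merge_windows(
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    n: np.ndarray,
    N: np.ndarray,
    p: np.ndarray,
    z: np.ndarray,
    sample: str,
    merge: bool = True,
) -> list[PeakCall]:
    """Merge overlapping retained windows; each peak carries the statistics
    of its maximum-z window."""
    order = np.argsort(starts, kind="stable")
    out: list[PeakCall] = []
    cur_start = cur_end = None
    best = -1
    for i in order:
        if cur_start is None:
            cur_start, cur_end, best = int(starts[i]), int(ends[i]), i
        elif merge and starts[i] < cur_end:
            cur_end = max(cur_end, int(ends[i]))
            if z[i] > z[best]:
                best = i
        else:
            out.append(
                PeakCall(
                    GenomicInterval(chrom, cur_start, cur_end),
                    float(n[best]),
                    int(N[best]),
                    float(p[best]),
                    float(z[best]),
                    sample,
                )
            )
            cur_start, cur_end, best = int(starts[i]), int(ends[i]), i
    if cur_start is not None:
        out.append(
            PeakCall(
                GenomicInterval(chrom, cur_start, cur_end),
                float(n[best]),
                int(N[best]),
                float(p[best]),
                float(z[best]),
                sample,
            )
        )
    return out


def subtract_null_peaks(
    peaks: Sequence[PeakCall], null_peaks: Sequence[PeakCall]
) -> list[PeakCall]:
    """Exclude peaks overlapping a knockout-null peak by more than 1 bp.

    The boundary is strict: a 1 bp overlap is retained, 2 bp is removed.
    Order of the surviving peaks is preserved; the operation is idempotent.
    """
    null_by_chrom: dict[str, list[GenomicInterval]] = {}
    for npk in null_peaks:
        null_by_chrom.setdefault(npk.interval.chrom, []).append(npk.interval)
    for ivs in null_by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    out = []
    for pk in peaks:
        removed = False
        for null_iv in null_by_chrom.get(pk.interval.chrom, ()):
            if null_iv.start >= pk.interval.end:
                break
            if interval_overlap(pk.interval, null_iv) > 1:
                removed = True
                break
        if not removed:
            out.append(pk)
    return out


# ---------------------------------------------------------------------------
# Peak BED I/O (BED6+: chrom start end name z n N p)


def write_peaks_bed(peaks: Iterable[PeakCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks, 1):
            fh.write(
                f"{pk.interval.chrom}\t{pk.interval.start}\t{pk.interval.end}\t"
                f"peak_{i}\t{pk.z:.4f}\t{pk.n:.4f}\t{pk.N}\t{pk.p:.6e}\n"
            )


def read_peaks_bed(path: str | Path, sample: str = "") -> list[PeakCall]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 fields")
            z = float(f[4]) if len(f) > 4 else 0.0
            n = float(f[5]) if len(f) > 5 else 0.0
            N = int(f[6]) if len(f) > 6 else 0
            p = float(f[7]) if len(f) > 7 else 0.5
            out.append(
                PeakCall(GenomicInterval(f[0], int(f[1]), int(f[2])), n, N, p, z, sample)
            )
    return out
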