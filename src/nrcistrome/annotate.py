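"""Genomic-feature annotation of peaks and enrichment versus genome baseline.

Every base of the genome receives exactly one feature label under fixed
precedence rules: inside a transcript, 5'UTR > 3'UTR > coding exon >
intron; outside, strand-aware upstream bins (from the TSS) and downstream
bins (from the transcript 3' end) out to the largest bin edge, with a base
claimed by two genes' flanks going to the nearer one; everything else is
intergenic.  Peaks are labeled by their midpoint, so peak annotation and
the genome baseline use the identical partition and observed category
fractions are directly comparable to genome base fractions.

Exonic bases of non-coding transcripts (empty CDS) fall in the coding-exon
category, which here simply means "exonic, non-UTR".

Enrichment per category is an exact two-sided binomial test of the
observed peak count against ``n_peaks * baseline_fraction``, BH-corrected
across categories.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .genes import GeneModel
from .peaks import PeakCall

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (1000, 2000, 3000)


def _flank_labels(prefix: str, bin_edges: Sequence[int]) -> list[str]:
    return [f"{prefix}_{edge // 1000}k" for edge in bin_edges]


def category_labels(bin_edges: Sequence[int] = DEFAULT_BIN_EDGES) -> list[str]:
    return (
        ["5'UTR", "3'UTR", "coding_exon", "intron"]
        + _flank_labels("upstream", bin_edges)
        + _flank_labels("downstream", bin_edges)
        + ["intergenic"]
    )


class GenomeAnnotation:
    """Per-bp feature labels for a genome under the precedence rules above."""

    def __init__(
        self,
        gene_models: Sequence[GeneModel],
        chrom_lengths: Mapping[str, int],
        bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
    ):
        self.bin_edges = tuple(sorted(bin_edges))
        self.chrom_lengths = dict(chrom_lengths)
        self.labels = category_labels(self.bin_edges)
        self._code = {lab: i for i, lab in enumerate(self.labels)}
        self._arrays: dict[str, np.ndarray] = {
            c: np.full(int(l), self._code["intergenic"], dtype=np.uint8)
            for c, l in self.chrom_lengths.items()
        }
        self._paint_flanks(gene_models)
        self._paint_intragenic(gene_models)

    # -- construction ------------------------------------------------------

    def _bin_label(self, prefix: str, dist: np.ndarray) -> np.ndarray:
        """Map 1-based flank distances to bin codes."""
        codes = np.empty(len(dist), dtype=np.uint8)
        lo = 0
        for edge, lab in zip(self.bin_edges, _flank_labels(prefix, self.bin_edges)):
            sel = (dist > lo) & (dist <= edge)
            codes[sel] = self._code[lab]
            lo = edge
        return codes

    def _paint_flanks(self, gene_models: Sequence[GeneModel]) -> None:
        reach = self.bin_edges[-1]
        dist_arr = {
            c: np.full(len(a), np.iinfo(np.int32).max, dtype=np.int32)
            for c, a in self._arrays.items()
        }
        for g in gene_models:
            if g.chrom not in self._arrays:
                continue
            arr = self._arrays[g.chrom]
            darr = dist_arr[g.chrom]
            L = len(arr)
            if g.strand == "+":
                regions = (
                    ("upstream", g.tx_start - reach, g.tx_start, g.tx_start, -1),
                    ("downstream", g.tx_end, g.tx_end + reach, g.tx_end - 1, +1),
                )
            else:
                regions = (
                    ("upstream", g.tx_end, g.tx_end + reach, g.tx_end - 1, +1),
                    ("downstream", g.tx_start - reach, g.tx_start, g.tx_start, -1),
                )
            for prefix, lo, hi, anchor, sign in regions:
                lo_c, hi_c = max(lo, 0), min(hi, L)
                if lo_c >= hi_c:
                    continue
                pos = np.arange(lo_c, hi_c, dtype=np.int64)
                dist = (sign * (pos - anchor)).astype(np.int32)
                win = dist < darr[lo_c:hi_c]
                codes = self._bin_label(prefix, dist)
                arr[lo_c:hi_c][win] = codes[win]
                darr[lo_c:hi_c][win] = dist[win]

    def _paint_intragenic(self, gene_models: Sequence[GeneModel]) -> None:
        # increasing precedence: intron < coding_exon < 3'UTR < 5'UTR
        for pass_label in ("intron", "coding_exon", "3'UTR", "5'UTR"):
            code = self._code[pass_label]
            for g in gene_models:
                arr = self._arrays.get(g.chrom)
                if arr is None:
                    continue
                if pass_label == "intron":
                    arr[g.tx_start : g.tx_end] = code  # exons repainted later
                    continue
                for ex in g.exons:
                    if pass_label == "coding_exon":
                        if g.coding:
                            s, e = max(ex.start, g.cds_start), min(ex.end, g.cds_end)
                        else:
                            s, e = ex.start, ex.end
                    elif (pass_label == "5'UTR") == (g.strand == "+"):
                        # 5'UTR on + / 3'UTR on -: exonic bp before cds_start
                        if not g.coding:
                            continue
                        s, e = ex.start, min(ex.end, g.cds_start)
                    else:
                        if not g.coding:
                            continue
                        s, e = max(ex.start, g.cds_end), ex.end
                    if s < e:
                        arr[s:e] = code

    # -- queries -----------------------------------------------------------

    def category_at(self, chrom: str, pos: int) -> str:
        arr = self._arrays.get(chrom)
        if arr is None or not 0 <= pos < len(arr):
            return "intergenic"
        return self.labels[arr[pos]]

    def category_fractions(self) -> dict[str, float]:
        total = sum(len(a) for a in self._arrays.values())
        counts = np.zeros(len(self.labels), dtype=np.int64)
        for arr in self._arrays.values():
            counts += np.bincount(arr, minlength=len(self.labels))
        return {lab: counts[i] / total for i, lab in enumerate(self.labels)}

    def chromosome_fractions(self) -> dict[str, float]:
        total = sum(self.chrom_lengths.values())
        return {c: l / total for c, l in self.chrom_lengths.items()}


def annotate_peak(peak: PeakCall, annotation: GenomeAnnotation) -> str:
    """Feature category of the peak midpoint."""
    return annotation.category_at(peak.interval.chrom, peak.interval.midpoint)


def annotate_peaks(
    peaks: Sequence[PeakCall], annotation: GenomeAnnotation
) -> list[str]:
    return [annotate_peak(pk, annotation) for pk in peaks]


def genome_category_fractions(
    gene_models: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> tuple[dict[str, float], dict[str, float]]:
    """Baseline genome fractions per feature category and per chromosome."""
    ann = GenomeAnnotation(gene_models, chrom_lengths, bin_edges)
    return ann.category_fractions(), ann.chromosome_fractions()


def category_enrichment(
    peak_categories: Sequence[str],
    baseline: Mapping[str, float],
    n_peaks: int | None = None,
) -> pd.DataFrame:
    """Observed-vs-baseline enrichment per category.

    Exact two-sided binomial test of the observed category count against
    ``n_peaks * baseline``; ratio of observed to baseline fraction; BH over
    categories.  A category with zero baseline but observed peaks gets an
    infinite ratio and a test against a half-count continuity floor.
    """
    if n_peaks is None:
        n_peaks = len(peak_categories)
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    rows = []
    for label, base in baseline.items():
        k = sum(1 for c in peak_categories if c == label)
        obs = k / n_peaks
        if base > 0:
            ratio = obs / base
            p = stats.binomtest(k, n_peaks, base, alternative="two-sided").pvalue
        elif k > 0:
            ratio = float("inf")
            floor = 0.5 / n_peaks
            logger.warning(
                "category %s: zero baseline with %d observed peaks; "
                "testing against continuity floor %.3g",
                label,
                k,
                floor,
            )
            p = stats.binomtest(k, n_peaks, floor, alternative="two-sided").pvalue
        else:
            ratio, p = 1.0, 1.0
        rows.append(
            {
                "label": label,
                "observed_count": k,
                "observed_fraction": obs,
                "baseline_fraction": base,
                "ratio": ratio,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
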