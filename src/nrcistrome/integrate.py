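"""Cistrome-transcriptome integration.

Peaks are assigned to their genome-wide nearest transcription start site
(by absolute midpoint-to-TSS distance; ties broken by lexicographic gene
id).  Direct target genes are those with a non-``none`` response type and
at least one assigned peak within +/- 10 kb of the TSS; the "without
ligand" and "with ligand" occupancy sets and their overlap summarize how
binding relates to each response type.

Signed distances follow the gene's strand: positive values lie downstream
of transcription, negative upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel
from .peaks import PeakCall


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: PeakCall
    gene_id: str
    distance: float  # signed bp; +inf sentinel when no gene shares the chromosome

    @property
    def assigned(self) -> bool:
        return math.isfinite(self.distance)


def assign_peaks_to_tss(
    peaks: Sequence[PeakCall], gene_models: Sequence[GeneModel]
) -> list[PeakGeneAssignment]:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Peaks on chromosomes without genes receive a ``+inf`` distance sentinel
    and are excluded from downstream target sets.
    """
    if not gene_models:
        raise ValueError("gene models must be non-empty")
    by_chrom: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    for chrom in {g.chrom for g in gene_models}:
        genes = sorted(
            (g for g in gene_models if g.chrom == chrom),
            key=lambda g: (g.tss, g.gene_id),
        )
        by_chrom[chrom] = (
            np.array([g.tss for g in genes], dtype=np.int64),
            [g.gene_id for g in genes],
            [g.strand for g in genes],
        )
    out = []
    for pk in peaks:
        chrom = pk.interval.chrom
        if chrom not in by_chrom:
            out.append(PeakGeneAssignment(pk, "", math.inf))
            continue
        tss, ids, strands = by_chrom[chrom]
        mid = pk.interval.midpoint
        j = int(np.searchsorted(tss, mid))
        # candidates around the insertion point; include equal-distance ties
        best_i, best_d, best_id = -1, None, None
        for i in range(max(0, j - 1), min(len(tss), j + 1)):
            d = abs(int(tss[i]) - mid)
            if best_d is None or d < best_d or (d == best_d and ids[i] < best_id):
                best_i, best_d, best_id = i, d, ids[i]
        # equal-TSS duplicates adjacent to best candidate
        for i in range(len(tss)):
            d = abs(int(tss[i]) - mid)
            if d == best_d and ids[i] < best_id:
                best_i, best_id = i, ids[i]
        signed = mid - int(tss[best_i])
        if strands[best_i] == "-":
            signed = -signed
        out.append(PeakGeneAssignment(pk, best_id, float(signed)))
    return out


@dataclass
class DirectTargetSet:
    condition: str  # "without_ligand" / "with_ligand"
    genes: set[str]
    window_bp: int = 10_000


def inclusion_exclusion_intersection(size_a: int, size_b: int, size_union: int) -> int:
    """|A ∩ B| from |A|, |B| and |A ∪ B|."""
    size_inter = size_a + size_b - size_union
    if size_inter < 0 or size_inter > min(size_a, size_b):
        raise ValueError("inconsistent set sizes")
    return size_inter


def _occupied_genes(
    assignments: Sequence[PeakGeneAssignment], window_bp: int
) -> set[str]:
    return {
        a.gene_id
        for a in assignments
        if a.assigned and abs(a.distance) <= window_bp
    }


def direct_target_sets(
    assignments_without_ligand: Sequence[PeakGeneAssignment],
    assignments_with_ligand: Sequence[PeakGeneAssignment],
    responses: pd.DataFrame,
    window_bp: int = 10_000,
) -> tuple[DirectTargetSet, DirectTargetSet, dict]:
    """Intersect peak occupancy with differential expression.

    ``responses`` is the classification table (indexed by gene, with a
    ``response_type`` column).  Returns the without-ligand set A, the
    with-ligand set B, and a summary dict with the four set sizes plus a
    per-response-type breakdown of genes occupied without-only / with-only
    / under both conditions.
    """
    de_genes = set(responses.index[responses["response_type"] != "none"])
    occ_without = _occupied_genes(assignments_without_ligand, window_bp)
    occ_with = _occupied_genes(assignments_with_ligand, window_bp)
    set_a = DirectTargetSet("without_ligand", de_genes & occ_without, window_bp)
    set_b = DirectTargetSet("with_ligand", de_genes & occ_with, window_bp)
    union = set_a.genes | set_b.genes
    inter = set_a.genes & set_b.genes
    per_type: dict[str, dict[str, int]] = {}
    for t in sorted(responses.loc[sorted(union), "response_type"].unique()):
        members = {g for g in union if responses.at[g, "response_type"] == t}
        per_type[t] = {
            "without_only": len(members & set_a.genes - set_b.genes),
            "with_only": len(members & set_b.genes - set_a.genes),
            "both": len(members & inter),
            "total": len(members),
        }
    summary = {
        "n_without": len(set_a.genes),
        "n_with": len(set_b.genes),
        "n_intersection": len(inter),
        "n_union": len(union),
        "per_type": per_type,
    }
    assert summary["n_intersection"] == inclusion_exclusion_intersection(
        summary["n_without"], summary["n_with"], summary["n_union"]
    )
    return set_a, set_b, summary


def tss_distance_profile(
    direct_targets: DirectTargetSet,
    assignments: Sequence[PeakGeneAssignment],
    responses: pd.DataFrame,
    window_bp: int = 10_000,
    bin_bp: int = 500,
) -> dict[str, np.ndarray]:
    """Binned signed TSS-distance histogram per response type.

    Bins cover ``[-window_bp, +window_bp]``; counts sum to the number of
    contributing peaks (those assigned to a direct-target gene within the
    window).  Returns ``{"edges": edges, "<type>": counts, ...}``.
    """
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    out: dict[str, np.ndarray] = {"edges": edges}
    dists_by_type: dict[str, list[float]] = {}
    for a in assignments:
        if not a.assigned or abs(a.distance) > window_bp:
            continue
        if a.gene_id not in direct_targets.genes:
            continue
        t = responses.at[a.gene_id, "response_type"]
        dists_by_type.setdefault(t, []).append(a.distance)
    for t, dists in dists_by_type.items():
        counts, _ = np.histogram(dists, bins=edges)
        out[t] = counts
    return out


def assignments_to_frame(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    rows = [
        {
            "chrom": a.peak.interval.chrom,
            "start": a.peak.interval.start,
            "end": a.peak.interval.end,
            "z": a.peak.z,
            "gene_id": a.gene_id,
            "distance": a.distance,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows)
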