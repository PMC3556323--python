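"""Position-weight-matrix construction, IUPAC consensus, region scanning,
background-corrected co-occurrence and motif-similarity trees.

A :class:`PWM` is built from equal-length aligned binding-site sequences
(e.g. literature-validated DR1-type response elements): per-column base
counts with an additive pseudocount give probabilities, and log2 odds
versus a background base composition give the scanning score.  Scanning
slides the matrix along both strands of a region and reports hits scoring
at least a fraction (default 0.8) of the matrix's maximum attainable
log-odds score.  Ambiguous ``N`` bases count 0.25 to each base when
building and contribute zero log-odds when scanning.

Co-occurrence analysis asks, per motif and per region group, what fraction
of regions contain at least one hit; motifs whose hit fraction in
knockout-null regions is not significantly below the wild-type reference
fraction are flagged as background and omitted, mirroring a knockout-based
non-specific-enrichment correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.proportion import proportions_ztest

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC code for every non-empty subset of bases
_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class MotifParams:
    region_bp: int = 400
    score_fraction_threshold: float = 0.8
    consensus_major_threshold: float = 0.6
    consensus_minor_threshold: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "score_fraction_threshold",
            "consensus_major_threshold",
            "consensus_minor_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int
    strand: str
    score: float
    score_fraction: float


class PWM:
    """Position frequency/weight matrix with pseudocounts and log-odds."""

    def __init__(
        self,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A, C, G, T)")
        if counts.shape[1] < 1:
            raise ValueError("matrix must have at least one column")
        self.name = name
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.background = np.asarray(background, dtype=float)
        totals = counts.sum(axis=0) + 4 * self.pseudocount
        self.probabilities = (counts + self.pseudocount) / totals
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.probabilities / self.background[:, None])
        self.max_score = float(self.log_odds.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def reverse_complement(self) -> "PWM":
        rc = self.counts[::-1, ::-1]  # A<->T, C<->G row swap + column reversal
        return PWM(self.name, rc, self.pseudocount, self.background[::-1])


def build_pfm(
    site_sequences: Sequence[str],
    pseudocount: float = 0.25,
    name: str = "motif",
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """Build a PWM from equal-length aligned site sequences.

    ``N`` bases contribute 0.25 of a count to each base.
    """
    if not site_sequences:
        raise ValueError("need at least one site sequence")
    L = len(site_sequences[0])
    counts = np.zeros((4, L), dtype=float)
    for seq in site_sequences:
        if len(seq) != L:
            raise ValueError("site sequences must all have equal length")
        for j, base in enumerate(seq.upper()):
            if base == "N":
                counts[:, j] += 0.25
            elif base in _BASE_INDEX:
                counts[_BASE_INDEX[base], j] += 1.0
            else:
                raise ValueError(f"invalid base {base!r} in site sequence")
    return PWM(name, counts, pseudocount, background)


def consensus_iupac(pwm: PWM, params: MotifParams = MotifParams()) -> str:
    """Degenerate-base consensus of a PWM.

    Per column: the single most probable base if it reaches the major
    threshold, otherwise the IUPAC code covering all bases at or above the
    minor threshold (N when that is all four, or none).
    """
    out = []
    for j in range(pwm.length):
        col = pwm.probabilities[:, j]
        best = int(np.argmax(col))
        if col[best] >= params.consensus_major_threshold:
            out.append(BASES[best])
            continue
        members = frozenset(BASES[i] for i in range(4) if col[i] >= params.consensus_minor_threshold)
        out.append(_IUPAC[members] if members else "N")
    return "".join(out)


def expand_region(
    peak_interval, region_bp: int = 400, chrom_length: int | None = None
):
    """Fixed-width region centered on the peak midpoint.

    The region is shifted (never truncated) to stay within
    ``[0, chrom_length)``; a chromosome shorter than ``region_bp`` is an
    error.
    """
    from .intervals import GenomicInterval

    if chrom_length is not None and chrom_length < region_bp:
        raise ValueError("chromosome shorter than requested region width")
    mid = peak_interval.midpoint
    start = mid - region_bp // 2
    if start < 0:
        start = 0
    if chrom_length is not None and start + region_bp > chrom_length:
        start = chrom_length - region_bp
    return GenomicInterval(peak_interval.chrom, start, start + region_bp)


def _score_matrix(sequence: str, pwm: PWM) -> np.ndarray:
    """Log-odds score at every offset of one strand (N scores 0)."""
    L = pwm.length
    n_offsets = len(sequence) - L + 1
    if n_offsets <= 0:
        return np.array([])
    seq = sequence.upper()
    codes = np.empty(len(seq), dtype=np.int8)
    for i, base in enumerate(seq):
        if base in _BASE_INDEX:
            codes[i] = _BASE_INDEX[base]
        elif base == "N":
            codes[i] = 4
        else:
            raise ValueError(f"invalid base {base!r} in sequence")
    lo = np.vstack([pwm.log_odds, np.zeros(L)])  # row 4: N contributes 0
    scores = np.zeros(n_offsets)
    for j in range(L):
        scores += lo[codes[j : j + n_offsets], j]
    return scores


def scan_region(
    sequence: str,
    pwm: PWM,
    params: MotifParams = MotifParams(),
    region_id: str = "",
) -> list[MotifHit]:
    """Scan one region on both strands; hits meet the score-fraction threshold.

    A minus-strand hit at offset ``o`` means the reverse complement of
    ``sequence[o:o+L]`` matches the motif.
    """
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than motif")
    threshold = params.score_fraction_threshold * pwm.max_score
    hits = []
    rc = pwm.reverse_complement()
    for strand, mat in (("+", pwm), ("-", rc)):
        scores = _score_matrix(sequence, mat)
        for off in np.flatnonzero(scores >= threshold):
            hits.append(
                MotifHit(
                    region_id,
                    int(off),
                    strand,
                    float(scores[off]),
                    float(scores[off] / pwm.max_score),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def region_cooccurrence(
    regions_by_group: Mapping[str, Sequence[str]],
    pwms: Sequence[PWM],
    null_regions: Sequence[str],
    params: MotifParams = MotifParams(),
    reference_group: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Per-motif, per-group fraction of regions containing at least one hit.

    A motif is flagged ``background`` (and omitted from the retained list)
    unless its hit fraction in the ``reference_group`` (default: first
    group) is significantly above its fraction in the knockout-null
    regions by a one-sided two-proportion z-test at ``alpha``.

    Returns ``{"fractions": {motif: {group: fraction}},
    "null_fractions": {motif: fraction}, "retained": [...],
    "background": [...]}`` with ``retained`` sorted by reference fraction,
    descending.
    """
    if not regions_by_group:
        raise ValueError("need at least one region group")
    if reference_group is None:
        reference_group = next(iter(regions_by_group))
    if reference_group not in regions_by_group:
        raise ValueError(f"unknown reference group {reference_group!r}")

    def hit_count(regions: Sequence[str], pwm: PWM) -> int:
        return sum(1 for seq in regions if scan_region(seq, pwm, params))

    fractions: dict[str, dict[str, float]] = {}
    null_fractions: dict[str, float] = {}
    retained, background = [], []
    n_null = len(null_regions)
    for pwm in pwms:
        fractions[pwm.name] = {
            group: hit_count(regions, pwm) / len(regions)
            for group, regions in regions_by_group.items()
        }
        k_ref = hit_count(regions_by_group[reference_group], pwm)
        n_ref = len(regions_by_group[reference_group])
        k_null = hit_count(null_regions, pwm) if n_null else 0
        null_fractions[pwm.name] = k_null / n_null if n_null else 0.0
        if n_null == 0:
            enriched = k_ref > 0
        elif null_fractions[pwm.name] >= k_ref / n_ref:
            enriched = False
        else:
            _, p = proportions_ztest(
                [k_ref, k_null], [n_ref, n_null], alternative="larger"
            )
            enriched = bool(p < alpha)
        (retained if enriched else background).append(pwm.name)
    retained.sort(key=lambda m: -fractions[m][reference_group])
    return {
        "fractions": fractions,
        "null_fractions": null_fractions,
        "retained": retained,
        "background": background,
    }


# ---------------------------------------------------------------------------
# Motif similarity tree


def _best_column_correlation(a: PWM, b: PWM, min_overlap: int = 4) -> float:
    """Best Pearson correlation of aligned probability columns over all
    ungapped offsets and both orientations of ``b``."""
    best = -1.0
    for probs_b in (b.probabilities, b.reverse_complement().probabilities):
        pa, pb = a.probabilities, probs_b
        la, lb = pa.shape[1], pb.shape[1]
        for shift in range(-(lb - min_overlap), la - min_overlap + 1):
            lo_a, hi_a = max(0, shift), min(la, shift + lb)
            if hi_a - lo_a < min_overlap:
                continue
            xa = pa[:, lo_a:hi_a].ravel()
            xb = pb[:, lo_a - shift : hi_a - shift].ravel()
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                r = 1.0 if sa == sb else 0.0
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
            best = max(best, r)
    return best


def motif_distance_matrix(pwms: Sequence[PWM], min_overlap: int = 4) -> np.ndarray:
    n = len(pwms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - _best_column_correlation(
                pwms[i], pwms[j], min_overlap
            )
    return np.clip(d, 0.0, None)


def motif_tree(pwms: Sequence[PWM], min_overlap: int = 4) -> str:
    """Average-linkage similarity tree over PWMs, serialized as newick.

    Pairwise distance is 1 minus the best column correlation (see
    :func:`motif_distance_matrix`).
    """
    if len(pwms) < 2:
        raise ValueError("need at least two PWMs to build a tree")
    d = motif_distance_matrix(pwms, min_overlap)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    root = hierarchy.to_tree(link)
    names = [p.name for p in pwms]

    def newick(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6f}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return f"({newick(root.left, root.dist)},{newick(root.right, root.dist)});"


# ---------------------------------------------------------------------------
# TRANSFAC I/O (via Bio.motifs)


def read_transfac(path: str | Path, pseudocount: float = 0.25) -> list[PWM]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "TRANSFAC")
    out = []
    for rec in records:
        name = rec.get("ID") or rec.get("AC") or "motif"
        counts = np.array([rec.counts[b] for b in BASES], dtype=float)
        out.append(PWM(name, counts, pseudocount))
    return out


def write_transfac(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID  {pwm.name}\nXX\nBF  undefined\nXX\n")
            fh.write("P0      A      C      G      T\n")
            cons = consensus_iupac(pwm)
            for j in range(pwm.length):
                vals = "".join(f"{pwm.counts[i, j]:>7g}" for i in range(4))
                fh.write(f"{j + 1:02d}{vals} {cons[j]}\n")
            fh.write("XX\n//\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
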