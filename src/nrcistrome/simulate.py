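"""Synthetic genome, ChIP/input tag tracks, expression matrix and planted
ground truth for end-to-end testing of the pipeline.

The generator emulates the study design the pipeline targets: a receptor
wild-type and receptor-null genotype, each treated with vehicle or ligand.
It produces

* a toy multi-chromosome genome with non-overlapping coding gene models,
* a uniquely-mappable-region mask covering ``mappable_fraction`` of each
  chromosome (unmappable blocks never intersect planted sites),
* ChIP/input tag tracks: uniform background over mappable bp at
  ``background_rate`` tags/bp, with planted 150 bp sites receiving
  ``enrichment_factor`` times the background density in the conditions
  where they are active, and knockout-null ChIP tracks containing only
  shared artifact (non-specific) sites plus background,
* a log2-scale expression matrix with genes planted in each of the eight
  response types at a configurable fold change and replicate noise,
* PPRE-like motif instances written into the genome sequence at a
  configurable fraction of planted sites,
* a :class:`TruthManifest` recording everything planted.

All randomness flows from ``config.seed`` through ``numpy`` generators;
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import RESPONSE_TYPES, ExpressionMatrix
from .genes import GeneModel, write_bed12
from .intervals import GenomicInterval
from .tracks import MappabilityTrack, TagTrack, write_bed3, write_tags_bed

CHIP_CONDITIONS = ("chip_wt_veh", "chip_wt_lig", "chip_null_veh", "chip_null_lig")
INPUT_CONDITIONS = ("input_wt", "input_null")
SITE_PRESENCE = ("veh_only", "lig_only", "both")


@dataclass(frozen=True)
class ExpressionSimConfig:
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    replicate_sd: float = 0.25
    fold_change: float = 2.0
    replicates: int = 3
    genes_per_type: int = 8

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.replicate_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise standard deviations must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_len_bp: int = 750_000
    n_genes: int = 160
    mappable_fraction: float = 0.9
    total_tags: int | None = None  # default: expected tag mass at background_rate
    background_rate: float = 0.5  # expected tags per mappable bp
    enrichment_factor: float = 10.0
    site_width: int = 150
    site_max_offset: int = 10_000
    n_planted_sites: int = 80
    n_direct_targets: int = 40
    n_null_artifact_sites: int = 12
    site_presence_probs: tuple[float, float, float] = (0.26, 0.61, 0.13)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    motif_consensus: str = "GGGTCAAAGGTCA"
    motif_fraction: float = 0.8

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_len_bp, self.n_genes) <= 0:
            raise ValueError("n_chroms, chrom_len_bp and n_genes must be positive")
        if not 0 < self.mappable_fraction <= 1:
            raise ValueError("mappable_fraction must be in (0, 1]")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_planted_sites < self.n_direct_targets:
            raise ValueError("n_planted_sites must cover n_direct_targets")
        if self.n_direct_targets > 8 * self.expression.genes_per_type:
            raise ValueError("n_direct_targets exceeds planted response-type genes")
        if abs(sum(self.site_presence_probs) - 1) > 1e-9:
            raise ValueError("site_presence_probs must sum to 1")


@dataclass
class PlantedSite:
    chrom: str
    start: int
    end: int
    gene_id: str | None
    presence: str  # veh_only / lig_only / both

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class TruthManifest:
    config: SimulationConfig
    chrom_lengths: dict[str, int]
    response_types: dict[str, str]  # gene_id -> I..VIII / none
    sites: list[PlantedSite]
    artifact_sites: list[PlantedSite]
    motif_positions: list[dict]

    def sites_for_condition(self, condition: str) -> list[PlantedSite]:
        """Enriched sites for one ChIP condition (artifacts included)."""
        if condition in ("chip_null_veh", "chip_null_lig"):
            return list(self.artifact_sites)
        if condition == "chip_wt_veh":
            wanted = ("veh_only", "both")
        elif condition == "chip_wt_lig":
            wanted = ("lig_only", "both")
        elif condition in INPUT_CONDITIONS:
            return []
        else:
            raise ValueError(f"unknown condition {condition!r}")
        return [s for s in self.sites if s.presence in wanted] + list(
            self.artifact_sites
        )

    def direct_target_genes(self, condition: str) -> set[str]:
        """Planted genes expected in the direct-target set of a condition."""
        wanted = ("veh_only", "both") if condition == "without_ligand" else ("lig_only", "both")
        return {
            s.gene_id
            for s in self.sites
            if s.gene_id is not None
            and s.presence in wanted
            and self.response_types.get(s.gene_id, "none") != "none"
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "chrom_lengths": self.chrom_lengths,
            "response_types": self.response_types,
            "sites": [dataclasses.asdict(s) for s in self.sites],
            "artifact_sites": [dataclasses.asdict(s) for s in self.artifact_sites],
            "motif_positions": self.motif_positions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_raw = payload["config"]
        cfg_raw["expression"] = ExpressionSimConfig(**cfg_raw["expression"])
        cfg_raw["site_presence_probs"] = tuple(cfg_raw["site_presence_probs"])
        return cls(
            SimulationConfig(**cfg_raw),
            payload["chrom_lengths"],
            payload["response_types"],
            [PlantedSite(**s) for s in payload["sites"]],
            [PlantedSite(**s) for s in payload["artifact_sites"]],
            payload["motif_positions"],
        )


# ---------------------------------------------------------------------------
# Genome simulation


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    min_len, max_len = 2000, 6000
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = config.chrom_len_bp // n
        if slot < max_len + 400:
            raise ValueError(
                "genes cannot be placed without overlap; "
                "increase chrom_len_bp or reduce n_genes"
            )
        for k in range(n):
            gid += 1
            length = int(rng.integers(min_len, max_len + 1))
            lo = k * slot + 200
            hi = (k + 1) * slot - 200 - length
            tx_start = int(rng.integers(lo, hi + 1))
            tx_end = tx_start + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 6))
            n_seg = 2 * n_exons - 1
            seg_min = 60
            extra = rng.multinomial(length - n_seg * seg_min, np.full(n_seg, 1 / n_seg))
            seg_lens = extra + seg_min
            bounds = np.concatenate([[0], np.cumsum(seg_lens)]) + tx_start
            exons = tuple(
                GenomicInterval(chrom, int(bounds[2 * j]), int(bounds[2 * j + 1]))
                for j in range(n_exons)
            )
            cds_start = int(rng.integers(exons[0].start + 1, exons[0].end))
            cds_end = int(rng.integers(exons[-1].start + 1, exons[-1].end))
            genes.append(
                GeneModel(
                    f"gene{gid:05d}",
                    chrom,
                    strand,
                    tx_start,
                    tx_end,
                    cds_start,
                    cds_end,
                    exons,
                )
            )
    return genes


def _plant_sites(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    response_types: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[list[PlantedSite], list[PlantedSite]]:
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {g.chrom for g in genes}:
        tss_by_chrom[chrom] = np.sort(
            np.array([g.tss for g in genes if g.chrom == chrom])
        )

    def nearest_is(chrom: str, mid: int, own_tss: int) -> bool:
        tss = tss_by_chrom[chrom]
        j = int(np.searchsorted(tss, mid))
        best = min(
            (abs(int(tss[i]) - mid) for i in range(max(0, j - 1), min(len(tss), j + 1))),
        )
        return best == abs(mid - own_tss)

    typed = [g for g in genes if response_types.get(g.gene_id, "none") != "none"]
    untyped = [g for g in genes if response_types.get(g.gene_id, "none") == "none"]
    rng.shuffle(typed)
    rng.shuffle(untyped)
    n_extra = config.n_planted_sites - config.n_direct_targets
    if n_extra > len(untyped):
        raise ValueError("not enough genes to host all planted sites")
    hosts = typed[: config.n_direct_targets] + untyped[:n_extra]
    presence = rng.choice(
        SITE_PRESENCE, size=len(hosts), p=list(config.site_presence_probs)
    )
    sites: list[PlantedSite] = []
    half = config.site_width // 2
    for g, pres in zip(hosts, presence):
        max_off = config.site_max_offset
        for _ in range(200):
            off = int(rng.integers(-max_off, max_off + 1))
            mid = g.tss + off
            start = mid - half
            end = start + config.site_width
            if start < 0 or end > config.chrom_len_bp:
                continue
            if nearest_is(g.chrom, mid, g.tss):
                sites.append(PlantedSite(g.chrom, start, end, g.gene_id, str(pres)))
                break
            max_off = max(500, max_off // 2)
        else:
            raise RuntimeError(f"could not place a site near {g.gene_id}")

    taken = [(s.chrom, s.start, s.end) for s in sites]
    artifacts: list[PlantedSite] = []
    for _ in range(config.n_null_artifact_sites):
        for _ in range(500):
            chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
            start = int(rng.integers(0, config.chrom_len_bp - config.site_width))
            end = start + config.site_width
            clash = any(
                c == chrom and start < e + 1000 and s - 1000 < end
                for c, s, e in taken
            )
            if not clash:
                artifacts.append(PlantedSite(chrom, start, end, None, "artifact"))
                taken.append((chrom, start, end))
                break
        else:
            raise RuntimeError("could not place artifact sites; genome too crowded")
    return sites, artifacts


def _carve_mappability(
    config: SimulationConfig,
    protected: Sequence[PlantedSite],
    rng: np.random.Generator,
) -> MappabilityTrack:
    intervals: list[GenomicInterval] = []
    block = 1000
    n_blocks = int(round((1 - config.mappable_fraction) * config.chrom_len_bp / block))
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        if n_blocks == 0:
            intervals.append(GenomicInterval(chrom, 0, config.chrom_len_bp))
            continue
        slots = np.arange(0, config.chrom_len_bp - block + 1, block)
        bad = np.zeros(len(slots), dtype=bool)
        for s in protected:
            if s.chrom != chrom:
                continue
            lo = max(0, (s.start - block) // block)
            hi = min(len(slots) - 1, s.end // block)
            bad[lo : hi + 1] = True
        candidates = slots[~bad]
        if len(candidates) < n_blocks:
            raise ValueError("cannot carve unmappable blocks around planted sites")
        chosen = np.sort(rng.choice(candidates, size=n_blocks, replace=False))
        cursor = 0
        for c in chosen.tolist():
            if c > cursor:
                intervals.append(GenomicInterval(chrom, cursor, c))
            cursor = c + block
        if cursor < config.chrom_len_bp:
            intervals.append(GenomicInterval(chrom, cursor, config.chrom_len_bp))
    return MappabilityTrack.from_intervals(intervals)


def _assign_types(
    config: SimulationConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> dict[str, str]:
    per_type = config.expression.genes_per_type
    if 8 * per_type > len(genes):
        raise ValueError("not enough genes for the requested planted types")
    ids = [g.gene_id for g in genes]
    rng.shuffle(ids)
    types: dict[str, str] = {gid: "none" for gid in ids}
    cursor = 0
    for t in RESPONSE_TYPES:
        for gid in ids[cursor : cursor + per_type]:
            types[gid] = t
        cursor += per_type
    return types


def simulate_genome(
    config: SimulationConfig, with_sequence: bool = True
) -> tuple[dict[str, str] | None, list[GeneModel], MappabilityTrack, TruthManifest]:
    """Generate the toy genome and its ground-truth manifest.

    Returns ``(sequences, genes, mappability, manifest)``; ``sequences`` is
    ``None`` when ``with_sequence`` is False (everything downstream of
    motif scanning works without it).
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config, rng)
    response_types = _assign_types(config, genes, rng)
    sites, artifacts = _plant_sites(config, genes, response_types, rng)
    mappability = _carve_mappability(config, list(sites) + list(artifacts), rng)
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_len_bp for i in range(config.n_chroms)
    }

    motif_positions: list[dict] = []
    sequences: dict[str, str] | None = None
    if with_sequence:
        seq_arrays = {
            chrom: rng.integers(0, 4, size=config.chrom_len_bp, dtype=np.uint8)
            for chrom in chrom_lengths
        }
        motif = config.motif_consensus.upper()
        codes = np.array([_base_code(b) for b in motif], dtype=np.uint8)
        rc_codes = codes[::-1] ^ 3  # complement: A(0)<->T(3), C(1)<->G(2)
        for i, site in enumerate(sites):
            if rng.random() >= config.motif_fraction:
                continue
            pos = site.start + (config.site_width - len(motif)) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            seq_arrays[site.chrom][pos : pos + len(motif)] = (
                codes if strand == "+" else rc_codes
            )
            motif_positions.append(
                {"chrom": site.chrom, "pos": int(pos), "strand": strand, "site": i}
            )
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        sequences = {
            chrom: lut[arr].tobytes().decode("ascii")
            for chrom, arr in seq_arrays.items()
        }

    manifest = TruthManifest(
        config, chrom_lengths, response_types, sites, artifacts, motif_positions
    )
    return sequences, genes, mappability, manifest


def _base_code(base: str) -> int:
    return {"A": 0, "C": 1, "G": 2, "T": 3}[base]


# ---------------------------------------------------------------------------
# Tag simulation


def simulate_tags(
    mappability: MappabilityTrack,
    manifest: TruthManifest,
    condition: str,
    seed: int | None = None,
) -> TagTrack:
    """Draw one sample's tag track.

    Background tags fall uniformly on mappable bp at
    ``config.background_rate`` expected tags/bp; bp inside sites active in
    ``condition`` carry ``enrichment_factor`` times that weight.  The
    library total is drawn multinomially so the configured total is exact.
    Tags are never placed on unmappable bp.
    """
    if condition not in CHIP_CONDITIONS + INPUT_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config = manifest.config
    if seed is None:
        seed = _condition_seed(config.seed, condition)
    rng = np.random.default_rng(seed)
    active = manifest.sites_for_condition(condition)
    masks: dict[str, np.ndarray] = {
        chrom: np.zeros(clen, dtype=bool)
        for chrom, clen in manifest.chrom_lengths.items()
    }
    for iv in mappability.intervals():
        if iv.chrom in masks:
            masks[iv.chrom][iv.start : iv.end] = True
    w = {chrom: mask.astype(np.float64) for chrom, mask in masks.items()}
    for site in active:
        seg = w[site.chrom][site.start : site.end]
        seg *= config.enrichment_factor
    masses = {chrom: float(arr.sum()) for chrom, arr in w.items()}
    total_mass = sum(masses.values())
    if total_mass <= 0:
        raise ValueError("no mappable bp to place tags on")
    total = config.total_tags
    if total is None:
        total = int(round(config.background_rate * total_mass))
    chroms = sorted(w)
    per_chrom = rng.multinomial(total, [masses[c] / total_mass for c in chroms])
    counts_by_chrom = {}
    for chrom, t_c in zip(chroms, per_chrom.tolist()):
        if t_c == 0:
            continue
        p = w[chrom] / masses[chrom]
        counts = rng.multinomial(t_c, p)
        pos = np.flatnonzero(counts)
        counts_by_chrom[chrom] = (pos, counts[pos])
    return TagTrack.from_counts(counts_by_chrom)


def _condition_seed(master_seed: int, condition: str) -> int:
    offset = (CHIP_CONDITIONS + INPUT_CONDITIONS).index(condition) + 1
    return (int(master_seed) * 1000 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Expression simulation


#: per response type: (shift sign applied to null samples, to wt+ligand)
_TYPE_SHIFTS: dict[str, tuple[int, int]] = {
    "I": (+1, 0),
    "II": (-1, 0),
    "III": (0, +1),
    "IV": (0, -1),
    "V": (+1, +1),
    "VI": (-1, -1),
    "VII": (-1, +1),
    "VIII": (+1, -1),
    "none": (0, 0),
}


def simulate_expression(
    manifest: TruthManifest,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Simulate the log2 expression matrix for the 2x2 design.

    Genes planted with a response type receive ``log2(fold_change)`` shifts
    in the conditions that type prescribes: constitutive types shift both
    knockout conditions (up when the receptor represses), ligand types
    shift wild-type+ligand only, and switch types combine both.  The
    ligand never shifts knockout samples, making every planted ligand
    response receptor-dependent.
    """
    config = config or manifest.config
    expr = config.expression
    if seed is None:
        seed = (int(config.seed) * 1000 + 97) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    gene_ids = sorted(manifest.response_types)
    n = len(gene_ids)
    d = np.log2(expr.fold_change)
    baseline = rng.normal(expr.baseline_mean, expr.baseline_sd, size=n)
    null_shift = np.array(
        [_TYPE_SHIFTS[manifest.response_types[g]][0] for g in gene_ids], dtype=float
    )
    lig_shift = np.array(
        [_TYPE_SHIFTS[manifest.response_types[g]][1] for g in gene_ids], dtype=float
    )
    cond_means = {
        ("wt", "vehicle"): baseline,
        ("wt", "ligand"): baseline + d * lig_shift,
        ("null", "vehicle"): baseline + d * null_shift,
        ("null", "ligand"): baseline + d * null_shift,
    }
    columns = {}
    design_rows = []
    for genotype in ("wt", "null"):
        for treatment in ("vehicle", "ligand"):
            for r in range(1, expr.replicates + 1):
                name = f"{genotype}_{treatment}_r{r}"
                noise = rng.normal(0.0, expr.replicate_sd, size=n)
                columns[name] = cond_means[(genotype, treatment)] + noise
                design_rows.append(
                    {
                        "sample": name,
                        "genotype": genotype,
                        "treatment": treatment,
                        "replicate": r,
                    }
                )
    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(values, pd.DataFrame(design_rows))


# ---------------------------------------------------------------------------
# File output


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_simulation(
    out_dir: str | Path,
    config: SimulationConfig,
    with_sequence: bool = True,
    conditions: Sequence[str] = CHIP_CONDITIONS + INPUT_CONDITIONS,
) -> dict[str, Path]:
    """Run the full generator and write every artifact to ``out_dir``.

    Writes genome.fa, genes.bed (BED12), mappability.bed, per-condition tag
    BED6 files, expression.tsv + design.tsv and manifest.json; returns the
    path of each written file keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences, genes, mappability, manifest = simulate_genome(config, with_sequence)
    paths: dict[str, Path] = {}
    if sequences is not None:
        paths["genome"] = out_dir / "genome.fa"
        write_fasta(sequences, paths["genome"])
    paths["genes"] = out_dir / "genes.bed"
    write_bed12(genes, paths["genes"])
    paths["mappability"] = out_dir / "mappability.bed"
    write_bed3(mappability.intervals(), paths["mappability"])
    for condition in conditions:
        track = simulate_tags(mappability, manifest, condition)
        paths[condition] = out_dir / f"tags_{condition}.bed"
        write_tags_bed(track, paths[condition])
    matrix = simulate_expression(manifest, config)
    paths["expression"] = out_dir / "expression.tsv"
    paths["design"] = out_dir / "design.tsv"
    matrix.to_tsv(paths["expression"], paths["design"])
    paths["manifest"] = out_dir / "manifest.json"
    manifest.to_json(paths["manifest"])
    return paths
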