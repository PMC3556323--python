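"""End-to-end orchestration: simulate (optional), call peaks per condition,
subtract knockout-null peaks, classify expression responses, integrate
peaks with responses, annotate features and scan motifs, then write a
machine-readable summary.

The summary JSON contains the per-response-type gene counts, the four
direct-target set sizes (without-ligand, with-ligand, intersection,
union), per-category feature enrichment and per-motif co-occurrence
fractions, plus the full effective configuration — enough to reproduce or
audit a run from the file alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import yaml

from . import annotate as annotate_mod
from . import simulate as sim
from .expression import (
    ClassifierThresholds,
    ExpressionMatrix,
    classify_all,
    response_type_proportions,
    switch_ratio_summary,
)
from .genes import parse_gene_models
from .integrate import assign_peaks_to_tss, direct_target_sets, assignments_to_frame
from .motifs import (
    MotifParams,
    build_pfm,
    consensus_iupac,
    expand_region,
    region_cooccurrence,
)
from .peaks import (
    PeakCallerParams,
    call_hotspots,
    normalize_input,
    subtract_null_peaks,
    write_peaks_bed,
)
from .tracks import read_mappability, read_tags_bed

logger = logging.getLogger(__name__)

#: aligned validated DR1-type response-element sites used for the default
#: PPRE matrix when no motif library is supplied; position 4 is degenerate.
DEFAULT_PPRE_SITES = (
    "GGGACAAAGGTCA",
    "GGGCCAAAGGTCA",
    "GGGGCAAAGGTCA",
    "GGGTCAAAGGTCA",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: sim.SimulationConfig | None = None
    # file-mode inputs (used when simulate is None)
    genes_path: str | None = None
    mappability_path: str | None = None
    genome_path: str | None = None
    chip_tags: dict[str, str] = field(default_factory=dict)  # condition -> BED path
    input_tags: dict[str, str] = field(default_factory=dict)  # genotype -> BED path
    expression_path: str | None = None
    design_path: str | None = None
    peak_params: PeakCallerParams = field(default_factory=PeakCallerParams)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    integration_window_bp: int = 10_000
    motif_params: MotifParams = field(default_factory=MotifParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sub = dict(raw["simulate"])
            if "expression" in sub:
                sub["expression"] = sim.ExpressionSimConfig(**sub["expression"])
            if "site_presence_probs" in sub:
                sub["site_presence_probs"] = tuple(sub["site_presence_probs"])
            raw["simulate"] = sim.SimulationConfig(**sub)
        for key, klass in (
            ("peak_params", PeakCallerParams),
            ("thresholds", ClassifierThresholds),
            ("motif_params", MotifParams),
        ):
            if key in raw and raw[key] is not None:
                raw[key] = klass(**raw[key])
        return cls(**raw)


def _extract_region_sequences(sequences, peaks, region_bp, chrom_lengths):
    out = []
    for pk in peaks:
        region = expand_region(pk.interval, region_bp, chrom_lengths[pk.interval.chrom])
        out.append(sequences[region.chrom][region.start : region.end])
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline configuration: %s", config)

    # --- stage: inputs (simulated or from files) --------------------------
    if config.simulate is not None:
        sequences, genes, mappability, manifest = sim.simulate_genome(config.simulate)
        chrom_lengths = manifest.chrom_lengths
        chip_tracks = {
            cond: sim.simulate_tags(mappability, manifest, cond)
            for cond in sim.CHIP_CONDITIONS
        }
        input_tracks = {
            "wt": sim.simulate_tags(mappability, manifest, "input_wt"),
            "null": sim.simulate_tags(mappability, manifest, "input_null"),
        }
        matrix = sim.simulate_expression(manifest, config.simulate)
        manifest.to_json(out_dir / "manifest.json")
    else:
        if not (config.genes_path and config.mappability_path):
            raise ValueError("file mode requires genes_path and mappability_path")
        genes = parse_gene_models(config.genes_path)
        mappability = read_mappability(config.mappability_path)
        chrom_lengths = {c: mappability.chrom_extent(c) for c in mappability.chroms}
        chip_tracks = {
            cond: read_tags_bed(path) for cond, path in config.chip_tags.items()
        }
        input_tracks = {
            geno: read_tags_bed(path) for geno, path in config.input_tags.items()
        }
        sequences = None
        if config.genome_path:
            from pyfaidx import Fasta

            fa = Fasta(config.genome_path)
            sequences = {name: str(fa[name][:]) for name in fa.keys()}
        matrix = None
        if config.expression_path and config.design_path:
            matrix = ExpressionMatrix.from_tsv(
                config.expression_path, config.design_path
            )

    # --- stage: peak calling + null subtraction ---------------------------
    called = {}
    for cond, chip in chip_tracks.items():
        genotype = "null" if "null" in cond else "wt"
        inp = input_tracks.get(genotype)
        if inp is None:
            raise ValueError(f"no input track for genotype {genotype!r}")
        scaled = normalize_input(inp, chip.total_tags)
        called[cond] = call_hotspots(
            chip,
            scaled,
            mappability,
            config.peak_params,
            sample=cond,
            chrom_lengths=chrom_lengths,
        )
        write_peaks_bed(called[cond], out_dir / f"peaks_raw_{cond}.bed")
        logger.info("%s: %d raw peaks", cond, len(called[cond]))

    filtered = {}
    for cond in list(called):
        if cond.startswith("chip_null"):
            continue
        null_cond = cond.replace("chip_wt", "chip_null")
        null_peaks = called.get(null_cond, [])
        filtered[cond] = subtract_null_peaks(called[cond], null_peaks)
        write_peaks_bed(filtered[cond], out_dir / f"peaks_{cond}.bed")
        logger.info(
            "%s: %d peaks after null subtraction", cond, len(filtered[cond])
        )

    summary: dict = {
        "seed": config.seed,
        "parameters": {
            "peak_params": dataclasses.asdict(config.peak_params),
            "thresholds": dataclasses.asdict(config.thresholds),
            "integration_window_bp": config.integration_window_bp,
            "motif_params": dataclasses.asdict(config.motif_params),
            "simulate": dataclasses.asdict(config.simulate)
            if config.simulate
            else None,
        },
        "n_peaks": {cond: len(pks) for cond, pks in filtered.items()},
    }

    # --- stage: classification -------------------------------------------
    responses = None
    if matrix is not None:
        responses, counts = classify_all(matrix, config.thresholds)
        responses.to_csv(out_dir / "responses.tsv", sep="\t", index_label="gene_id")
        summary["response_type_counts"] = counts
        summary["response_proportions"] = response_type_proportions(counts)
        summary["switch_ratio"] = switch_ratio_summary(responses)

    # --- stage: integration ----------------------------------------------
    if responses is not None and "chip_wt_veh" in filtered and "chip_wt_lig" in filtered:
        assign_veh = assign_peaks_to_tss(filtered["chip_wt_veh"], genes)
        assign_lig = assign_peaks_to_tss(filtered["chip_wt_lig"], genes)
        assignments_to_frame(assign_veh).to_csv(
            out_dir / "assignments_without_ligand.tsv", sep="\t", index=False
        )
        assignments_to_frame(assign_lig).to_csv(
            out_dir / "assignments_with_ligand.tsv", sep="\t", index=False
        )
        set_a, set_b, target_summary = direct_target_sets(
            assign_veh, assign_lig, responses, config.integration_window_bp
        )
        summary["direct_targets"] = target_summary
        rows = []
        for gene in sorted(set_a.genes | set_b.genes):
            rows.append(
                {
                    "gene_id": gene,
                    "response_type": responses.at[gene, "response_type"],
                    "occ_without": gene in set_a.genes,
                    "occ_with": gene in set_b.genes,
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out_dir / "direct_targets.tsv", sep="\t", index=False)

    # --- stage: feature annotation ----------------------------------------
    annotation = annotate_mod.GenomeAnnotation(genes, chrom_lengths)
    summary["feature_enrichment"] = {}
    for cond, pks in filtered.items():
        if not pks:
            continue
        cats = annotate_mod.annotate_peaks(pks, annotation)
        enr = annotate_mod.category_enrichment(cats, annotation.category_fractions())
        enr.to_csv(out_dir / f"feature_enrichment_{cond}.tsv", sep="\t", index=False)
        summary["feature_enrichment"][cond] = {
            row["label"]: {
                "observed_fraction": row["observed_fraction"],
                "baseline_fraction": row["baseline_fraction"],
                "ratio": row["ratio"] if np.isfinite(row["ratio"]) else None,
                "q": row["q"],
            }
            for row in enr.to_dict("records")
        }

    # --- stage: motif analysis --------------------------------------------
    if sequences is not None:
        ppre = build_pfm(list(DEFAULT_PPRE_SITES), name="PPRE_DR1")
        regions_by_group = {
            cond: _extract_region_sequences(
                sequences, pks, config.motif_params.region_bp, chrom_lengths
            )
            for cond, pks in filtered.items()
            if pks
        }
        null_peaks = called.get("chip_null_veh", []) + called.get("chip_null_lig", [])
        null_regions = _extract_region_sequences(
            sequences, null_peaks, config.motif_params.region_bp, chrom_lengths
        )
        if regions_by_group:
            cooc = region_cooccurrence(
                regions_by_group,
                [ppre],
                null_regions,
                config.motif_params,
                reference_group=sorted(regions_by_group)[0],
            )
            summary["motifs"] = {
                "consensus": {ppre.name: consensus_iupac(ppre, config.motif_params)},
                "cooccurrence": cooc["fractions"],
                "null_fractions": cooc["null_fractions"],
                "retained": cooc["retained"],
                "background": cooc["background"],
            }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    logger.info("summary written to %s", out_dir / "summary.json")
    return summary
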