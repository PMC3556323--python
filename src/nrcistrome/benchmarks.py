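"""Planted-truth recovery benchmarks.

Two standard benchmark configurations exercise the pipeline's detection
stages against the generator's ground truth:

* the *site-recall* benchmark plants >=100 enriched 150 bp sites at
  enrichment factor 10 on a two-chromosome genome and measures the
  fraction recovered by z>60 peak calling after input normalization and
  knockout-null subtraction, plus the fraction of artifact-only peaks the
  null subtraction removes;
* the *response-recovery* benchmark plants 100 genes per response type
  alongside 200 unregulated genes (a deliberately DE-enriched panel; see
  the methods note) at fold change 2.0, replicate sd 0.25 and 3
  replicates, and measures the fraction of planted genes assigned their
  planted type.
"""

from __future__ import annotations

from .expression import classify_all
from .intervals import interval_overlap
from .peaks import call_hotspots, normalize_input, subtract_null_peaks
from .simulate import (
    ExpressionSimConfig,
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_tags,
)


def site_recall_config(seed: int = 0) -> SimulationConfig:
    # Coverage and site density chosen so the expected site z-score sits
    # near 85 with spread ~3: background N per 200 kb window is ~1.5e5
    # (including the planted-site tag mass, ~7 sites per window), giving
    # z ~ (n - mu)/sigma ~ (1075 - 127)/11 for a site at enrichment 10.
    return SimulationConfig(
        seed=seed,
        n_chroms=2,
        chrom_len_bp=1_500_000,
        n_genes=120,
        background_rate=0.8,
        n_planted_sites=110,
        n_direct_targets=40,
        n_null_artifact_sites=12,
        site_presence_probs=(1.0, 0.0, 0.0),  # all sites active without ligand
        enrichment_factor=10.0,
        expression=ExpressionSimConfig(genes_per_type=5),
    )


def peak_recall_benchmark(seed: int = 0) -> dict:
    """Planted-site recall and artifact removal at the z>60 threshold.

    Returns ``recall_pct``, ``artifact_removal_pct``, ``n_sites`` and
    ``n_artifacts``.
    """
    config = site_recall_config(seed)
    _, _, mappability, manifest = simulate_genome(config, with_sequence=False)
    chip = simulate_tags(mappability, manifest, "chip_wt_veh")
    null_chip = simulate_tags(mappability, manifest, "chip_null_veh")
    inp = simulate_tags(mappability, manifest, "input_wt")
    lengths = manifest.chrom_lengths
    peaks = call_hotspots(
        chip, normalize_input(inp, chip.total_tags), mappability, chrom_lengths=lengths
    )
    null_peaks = call_hotspots(
        null_chip,
        normalize_input(inp, null_chip.total_tags),
        mappability,
        chrom_lengths=lengths,
    )
    filtered = subtract_null_peaks(peaks, null_peaks)
    sites = [s for s in manifest.sites]
    recovered = sum(
        1
        for s in sites
        if any(interval_overlap(s.interval, pk.interval) > 0 for pk in filtered)
    )
    surviving_artifact_peaks = sum(
        1
        for pk in filtered
        if any(
            interval_overlap(s.interval, pk.interval) > 1
            for s in manifest.artifact_sites
        )
    )
    n_artifact_peaks_before = sum(
        1
        for pk in peaks
        if any(
            interval_overlap(s.interval, pk.interval) > 1
            for s in manifest.artifact_sites
        )
    )
    removal_pct = (
        100.0 * (1 - surviving_artifact_peaks / n_artifact_peaks_before)
        if n_artifact_peaks_before
        else 100.0
    )
    return {
        "recall_pct": 100.0 * recovered / len(sites),
        "artifact_removal_pct": removal_pct,
        "n_sites": len(sites),
        "n_artifacts": n_artifact_peaks_before,
    }


def response_recovery_config(seed: int = 0) -> SimulationConfig:
    n_genes = 8 * 100 + 200
    return SimulationConfig(
        seed=seed,
        n_chroms=4,
        chrom_len_bp=(n_genes // 4 + 1) * 8000,
        n_genes=n_genes,
        mappable_fraction=1.0,
        n_planted_sites=8,
        n_direct_targets=8,
        n_null_artifact_sites=2,
        expression=ExpressionSimConfig(
            genes_per_type=100, fold_change=2.0, replicate_sd=0.25, replicates=3
        ),
    )


def response_recovery_benchmark(seed: int = 0) -> dict:
    """Fraction of planted genes assigned their planted response type."""
    config = response_recovery_config(seed)
    _, _, _, manifest = simulate_genome(config, with_sequence=False)
    matrix = simulate_expression(manifest, config)
    table, _ = classify_all(matrix)
    planted = {g: t for g, t in manifest.response_types.items() if t != "none"}
    correct = sum(1 for g, t in planted.items() if table.at[g, "response_type"] == t)
    return {"accuracy_pct": 100.0 * correct / len(planted), "n_planted": len(planted)}
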