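"""Run every stage end to end on a simulated dataset and read the summary.

simulate -> call peaks (4 ChIP samples) -> subtract knockout-null peaks ->
classify expression responses -> integrate (direct targets) -> annotate
features -> scan motifs -> summary.json
"""

from nrcistrome import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    seed=1,
    out_dir="scratch/example_pipeline",
    simulate=SimulationConfig(seed=1),
)
summary = run_pipeline(config)

print("peaks per condition:", summary["n_peaks"])
print("response types:", summary["response_type_counts"])
dt = summary["direct_targets"]
print(f"direct targets: without={dt['n_without']} with={dt['n_with']} "
      f"both={dt['n_intersection']} union={dt['n_union']}")
print("PPRE fraction of peak regions:",
      {k: round(v, 2) for k, v in summary["motifs"]["cooccurrence"]["PPRE_DR1"].items()})
print("outputs in scratch/example_pipeline/ (peaks_*.bed, responses.tsv, "
      "direct_targets.tsv, feature_enrichment_*.tsv, summary.json)")
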