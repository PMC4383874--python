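"""End-to-end co-expression scoring on a synthetic experiment set.

Generates a GEO-like collection of microarray experiments with 20 planted
co-regulated modules, runs filtering, per-channel normalization, Hobohm-2
redundancy pruning, gene-gene correlation, pathway-co-membership calibration
and probabilistic channel combination, then benchmarks the scores against the
planted truth.
"""

from assocnet import PipelineConfig, SimulationConfig, run_coexpression_pipeline, simulate_expression

dataset = simulate_expression(SimulationConfig(seed=7))
run = run_coexpression_pipeline(
    dataset.experiments, dataset.probe_map, dataset.gold, PipelineConfig()
)

result = run.results[0]
report = result.report
print(f"organism: {result.organism_id}")
print(
    "arrays single-channel: "
    f"{report['arrays_in_single']} pooled -> {report['arrays_retained_single']} after pruning"
)
print(
    "arrays dual-channel:   "
    f"{report['arrays_in_dual']} pooled -> {report['arrays_retained_dual']} after pruning"
)
print(f"scored gene pairs: {report['edges_combined']}")
print(f"prior (positive fraction of benchmarkable pairs): {report['prior_combined']:.4f}")
print(f"ROC AUC against planted modules: {result.roc.auc:.3f}")
print()
print("The pruning step removes the planted near-duplicate arrays; the AUC")
print("close to 1 means calibrated scores rank within-module pairs above")
print("background pairs almost perfectly on this fixture.")
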