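"""End-to-end orchestration of the co-expression scoring pipeline.

The stages, per organism and channel:

    filter -> normalize -> merge probes -> pool arrays -> Spearman array
    similarity -> Hobohm-2 pruning -> Pearson gene correlation -> calibration
    against pathway co-membership -> per-channel scores -> probabilistic
    combination -> ROC benchmark

The pipeline itself is deterministic: randomness exists only in the synthetic
generators.  The run report records the counts at every stage so the effect
of each filter and of redundancy pruning is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from assocnet.coexpression import (
    PruneConfig,
    array_similarity,
    gene_correlation,
    hobohm2_prune,
    pool_experiments,
)
from assocnet.io import (
    DUAL,
    SINGLE,
    Exclusion,
    ExperimentSet,
    FilterConfig,
    ProbeGeneMap,
    apply_filters,
)
from assocnet.scoring import (
    CalibrationCurve,
    GoldStandard,
    RocResult,
    ScoredNetwork,
    calibrate,
    combine_networks,
    label_pairs,
    roc_benchmark,
    score_pairs,
)


class NoDataError(RuntimeError):
    """No organism survives the inclusion filters (a clean, expected outcome)."""


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one run; nested configs validate themselves."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    window_size: int = 500
    prior_override: float | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "filters": vars(self.filters),
                "prune": vars(self.prune),
                "window_size": self.window_size,
                "prior_override": self.prior_override,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class OrganismResult:
    """One organism's combined network, benchmark and stage report."""

    organism_id: str
    network: ScoredNetwork
    roc: RocResult | None
    curves: Mapping[str, CalibrationCurve]
    report: Mapping[str, object]


@dataclass(frozen=True)
class PipelineRun:
    results: tuple[OrganismResult, ...]
    exclusions: tuple[Exclusion, ...]
    config: PipelineConfig


def _run_channel(
    expset: ExperimentSet,
    pmap: ProbeGeneMap,
    gold: GoldStandard,
    channel: str,
    config: PipelineConfig,
    report: dict,
) -> tuple[ScoredNetwork, CalibrationCurve] | None:
    profiles = pool_experiments(expset, pmap, channel)
    if profiles is None or len(profiles.array_ids) < 2:
        return None
    sims = array_similarity(profiles, config.prune.min_overlap)
    retained = hobohm2_prune(sims, config.prune.threshold_for(channel))
    report[f"arrays_in_{channel}"] = len(profiles.array_ids)
    report[f"arrays_retained_{channel}"] = len(retained)
    if not retained:
        return None
    pairs = gene_correlation(profiles, retained, config.prune.min_overlap)
    report[f"gene_pairs_{channel}"] = len(pairs)
    labeled = label_pairs(pairs, gold)
    report[f"benchmarkable_pairs_{channel}"] = len(labeled.table)
    if len(labeled.table) < config.window_size:
        return None
    curve = calibrate(labeled, config.window_size)
    report[f"prior_{channel}"] = curve.prior
    name = f"coexpression_{channel}"
    return score_pairs(pairs, curve, channel=name), curve


def run_coexpression_pipeline(
    experiments: Iterable[ExperimentSet],
    pmap: ProbeGeneMap,
    gold: GoldStandard,
    config: PipelineConfig | None = None,
) -> PipelineRun:
    """Run the full pipeline over every organism that passes the filters.

    Raises :class:`NoDataError` when nothing survives filtering or no channel
    yields calibratable data.  Identical inputs and config give identical
    output (the pipeline is deterministic).
    """
    config = config or PipelineConfig()
    try:
        retained, exclusions = apply_filters(experiments, pmap, config.filters)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("filter", exc) from exc
    if not retained:
        raise NoDataError("no organism passed the inclusion filters")

    results: list[OrganismResult] = []
    for expset in retained:
        report: dict = {"organism": expset.organism_id, "config_hash": config.config_hash()}
        channel_nets: dict[str, ScoredNetwork] = {}
        curves: dict[str, CalibrationCurve] = {}
        weights: dict[str, int] = {}
        for channel in (SINGLE, DUAL):
            try:
                out = _run_channel(expset, pmap, gold, channel, config, report)
            except Exception as exc:
                raise PipelineStageError(f"coexpression_{channel}", exc) from exc
            if out is None:
                continue
            net, curve = out
            name = f"coexpression_{channel}"
            channel_nets[name] = net
            curves[name] = curve
            weights[name] = report[f"benchmarkable_pairs_{channel}"]
        if not channel_nets:
            continue

        if config.prior_override is not None:
            prior = config.prior_override
        else:
            total = sum(weights.values())
            prior = sum(curves[c].prior * weights[c] for c in curves) / total
        report["prior_combined"] = prior

        try:
            network = combine_networks(channel_nets, prior)
        except Exception as exc:
            raise PipelineStageError("combine", exc) from exc
        report["edges_combined"] = len(network)

        try:
            roc: RocResult | None = roc_benchmark(network, gold)
            report["roc_auc"] = roc.auc
        except ValueError:
            roc = None
        results.append(
            OrganismResult(
                organism_id=expset.organism_id,
                network=network,
                roc=roc,
                curves=curves,
                report=report,
            )
        )
    if not results:
        raise NoDataError("no organism yielded calibratable co-expression data")
    return PipelineRun(results=tuple(results), exclusions=tuple(exclusions), config=config)
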