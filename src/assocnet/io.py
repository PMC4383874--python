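"""Expression-matrix input and pre-analysis inclusion filters.

Experiments arrive as plain tab-separated probe x sample tables together with
a probe-to-gene mapping.  Before any numeric processing three inclusion
filters are applied, in this order:

1. samples with fewer than ``min_mappable_genes_per_sample`` distinct genes
   carrying a non-missing value are dropped,
2. experiments left with fewer than ``min_samples_per_experiment`` samples
   are dropped,
3. organisms left with fewer than ``min_experiments_per_organism``
   experiments are dropped entirely.

Every exclusion is recorded with its reason so a run can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

SINGLE = "single"
DUAL = "dual"
_CHANNELS = (SINGLE, DUAL)


class ParseError(ValueError):
    """Raised for malformed expression-matrix or mapping files."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """One experiment's probe x sample value table.

    ``values`` is a float array of shape ``(len(probe_ids), len(sample_ids))``
    with missing cells stored as NaN.  ``channel`` distinguishes absolute
    single-channel intensities from dual-channel log-ratios; the two kinds
    are normalized differently downstream.
    """

    experiment_id: str
    organism_id: str
    channel: str
    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}, got {self.channel!r}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe_ids must be unique within a matrix")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class ProbeGeneMap:
    """Mapping probe_id -> gene_id; many probes may map to one gene."""

    entries: Mapping[str, str]

    def gene_of(self, probe_id: str) -> str | None:
        return self.entries.get(probe_id)


@dataclass(frozen=True)
class FilterConfig:
    """Inclusion thresholds applied before analysis.

    Defaults: samples need 100 mappable genes, experiments 3 samples,
    organisms 50 experiments.
    """

    min_mappable_genes_per_sample: int = 100
    min_samples_per_experiment: int = 3
    min_experiments_per_organism: int = 50

    def __post_init__(self) -> None:
        for name in (
            "min_mappable_genes_per_sample",
            "min_samples_per_experiment",
            "min_experiments_per_organism",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class ExperimentSet:
    """All experiments of one organism."""

    organism_id: str
    experiments: tuple[ExpressionMatrix, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiments", tuple(self.experiments))
        for exp in self.experiments:
            if exp.organism_id != self.organism_id:
                raise ValueError(
                    f"experiment {exp.experiment_id} has organism "
                    f"{exp.organism_id!r}, set is {self.organism_id!r}"
                )


@dataclass(frozen=True)
class Exclusion:
    """One filtered-out entity: level is 'sample', 'experiment' or 'organism'."""

    level: str
    entity_id: str
    reason: str

    def as_tsv(self) -> str:
        return f"{self.level}\t{self.entity_id}\t{self.reason}"


def read_expression_matrix(
    path: str | Path,
    channel: str,
    experiment_id: str,
    organism_id: str,
) -> ExpressionMatrix:
    """Read a TSV expression table: row 1 sample IDs, column 1 probe IDs.

    Empty cells become NaN.  Ragged rows and duplicate probe IDs raise
    :class:`ParseError` naming the offending line (1-based).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].strip():
        raise ParseError(f"{path}: empty file or blank header (line 1)")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = tuple(h.strip() for h in header[1:])
    if not sample_ids:
        raise ParseError(f"{path}: header has no sample columns (line 1)")

    probe_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}: line {lineno} has {len(cells) - 1} value cells, "
                f"expected {len(sample_ids)}"
            )
        probe = cells[0].strip()
        if probe in seen:
            raise ParseError(f"{path}: duplicate probe ID {probe!r} (line {lineno})")
        seen.add(probe)
        probe_ids.append(probe)
        row = []
        for col, cell in enumerate(cells[1:], start=2):
            cell = cell.strip()
            if cell == "":
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                        f"column {col}"
                    ) from exc
        rows.append(row)

    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(
        experiment_id=experiment_id,
        organism_id=organism_id,
        channel=channel,
        probe_ids=tuple(probe_ids),
        sample_ids=sample_ids,
        values=values,
    )


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a 2-column TSV ``probe_id<TAB>gene_id`` mapping."""
    path = Path(path)
    entries: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(f"{path}: line {lineno} has {len(cells)} columns, expected 2")
        probe, gene = cells[0].strip(), cells[1].strip()
        if probe in entries and entries[probe] != gene:
            raise ParseError(
                f"{path}: probe {probe!r} maps to both {entries[probe]!r} and "
                f"{gene!r} (line {lineno})"
            )
        entries[probe] = gene
    return ProbeGeneMap(entries=entries)


def _mappable_gene_count(m: ExpressionMatrix, pmap: ProbeGeneMap, col: int) -> int:
    genes: set[str] = set()
    for i, probe in enumerate(m.probe_ids):
        gene = pmap.gene_of(probe)
        if gene is not None and np.isfinite(m.values[i, col]):
            genes.add(gene)
    return len(genes)


def apply_filters(
    experiments: Iterable[ExperimentSet],
    pmap: ProbeGeneMap,
    config: FilterConfig | None = None,
) -> tuple[list[ExperimentSet], list[Exclusion]]:
    """Apply the sample -> experiment -> organism inclusion filters.

    Returns the retained sets and a structured log of every exclusion.
    An empty result is legal.
    """
    config = config or FilterConfig()
    log: list[Exclusion] = []
    retained_sets: list[ExperimentSet] = []

    for expset in experiments:
        kept_experiments: list[ExpressionMatrix] = []
        for exp in expset.experiments:
            keep_cols = []
            for col, sample in enumerate(exp.sample_ids):
                n_genes = _mappable_gene_count(exp, pmap, col)
                if n_genes < config.min_mappable_genes_per_sample:
                    log.append(
                        Exclusion(
                            "sample",
                            f"{exp.experiment_id}:{sample}",
                            f"only {n_genes} mappable genes "
                            f"(< {config.min_mappable_genes_per_sample})",
                        )
                    )
                else:
                    keep_cols.append(col)
            if len(keep_cols) < config.min_samples_per_experiment:
                log.append(
                    Exclusion(
                        "experiment",
                        exp.experiment_id,
                        f"only {len(keep_cols)} samples after sample filter "
                        f"(< {config.min_samples_per_experiment})",
                    )
                )
                continue
            if len(keep_cols) < exp.n_samples:
                exp = replace(
                    exp,
                    sample_ids=tuple(exp.sample_ids[c] for c in keep_cols),
                    values=exp.values[:, keep_cols],
                )
            kept_experiments.append(exp)

        if len(kept_experiments) < config.min_experiments_per_organism:
            log.append(
                Exclusion(
                    "organism",
                    expset.organism_id,
                    f"only {len(kept_experiments)} experiments after experiment "
                    f"filter (< {config.min_experiments_per_organism})",
                )
            )
            continue
        retained_sets.append(
            ExperimentSet(organism_id=expset.organism_id, experiments=tuple(kept_experiments))
        )

    return retained_sets, log


def write_exclusion_log(log: Iterable[Exclusion], path: str | Path) -> None:
    Path(path).write_text(
        "".join(e.as_tsv() + "\n" for e in log), encoding="utf-8"
    )
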