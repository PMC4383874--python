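"""Per-channel normalization, probe merging, redundancy pruning, correlation.

The co-expression pipeline treats single- and dual-channel microarrays
separately.  Dual-channel arrays already carry log-ratios and are only
z-normalized per sample.  Single-channel intensities are log2-transformed and
each probe's mean across the experiment's samples is subtracted, turning
absolute intensities into fold-change-like values, before the same per-sample
z-normalization.

After probe-to-gene merging, all surviving arrays of an organism and channel
are pooled, their pairwise Spearman rank correlation is computed, and the
Hobohm-2 algorithm removes redundant arrays (similarity thresholds 0.7 for
single-channel and 0.95 for dual-channel data).  Gene-gene association is then
measured by Pearson correlation over the retained arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from assocnet.io import DUAL, SINGLE, ExperimentSet, ExpressionMatrix, ProbeGeneMap


@dataclass(frozen=True)
class GeneProfileMatrix:
    """Gene x array value matrix for one organism and channel.

    Columns are surviving samples pooled across experiments; each array ID is
    ``experiment_id:sample_id`` so a column traces back to exactly one sample.
    """

    organism_id: str
    channel: str
    gene_ids: tuple[str, ...]
    array_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.gene_ids), len(self.array_ids)):
            raise ValueError("values shape does not match gene/array IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise ValueError("array_ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.array_ids))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric array-array similarity (Spearman rho), NaN where undefined."""

    array_ids: tuple[str, ...]
    sims: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sims, dtype=float)
        object.__setattr__(self, "sims", s)
        n = len(self.array_ids)
        if s.shape != (n, n):
            raise ValueError("sims must be square and match array_ids")
        finite = np.isfinite(s)
        if not np.allclose(np.where(finite, s, 0), np.where(finite.T, s.T, 0), atol=1e-12):
            raise ValueError("sims must be symmetric")


@dataclass(frozen=True)
class PruneConfig:
    """Hobohm-2 thresholds per channel and the minimum pairwise overlap."""

    threshold_single: float = 0.7
    threshold_dual: float = 0.95
    min_overlap: int = 20

    def __post_init__(self) -> None:
        for name in ("threshold_single", "threshold_dual"):
            t = getattr(self, name)
            if not 0 < t <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {t}")

    def threshold_for(self, channel: str) -> float:
        return self.threshold_single if channel == SINGLE else self.threshold_dual


@dataclass(frozen=True)
class GenePairCorrelations:
    """Unordered gene pairs with Pearson r and the pairwise-complete count.

    ``table`` has columns gene_a, gene_b, r, n_arrays with gene_a < gene_b
    lexicographically and no duplicate pairs.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        expected = ["gene_a", "gene_b", "r", "n_arrays"]
        if list(t.columns) != expected:
            raise ValueError(f"table columns must be {expected}")
        if len(t) and not (t["gene_a"] < t["gene_b"]).all():
            raise ValueError("pairs must satisfy gene_a < gene_b")
        if t.duplicated(["gene_a", "gene_b"]).any():
            raise ValueError("duplicate gene pairs")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePairCorrelations":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str}))


def _zscore_columns(values: np.ndarray) -> np.ndarray:
    """Z-normalize each column ignoring NaN; zero-variance columns -> zeros."""
    out = values.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            continue
        sd = col[finite].std()
        if sd == 0:
            col[finite] = 0.0
        else:
            col[finite] = (col[finite] - col[finite].mean()) / sd
        out[:, j] = col
    return out


def normalize_single_channel(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform, subtract each probe's mean, then z-normalize columns.

    Values <= 0 are treated as missing (log2 undefined).  The per-probe mean
    subtraction yields log-fold change versus the probe's average over the
    experiment, making the values comparable to dual-channel log-ratios.
    """
    if m.channel != SINGLE:
        raise ValueError(f"expected single-channel matrix, got {m.channel!r}")
    vals = m.values.copy()
    vals[~np.isfinite(vals) | (vals <= 0)] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.log2(vals)
        row_mean = np.nanmean(vals, axis=1, keepdims=True)
    # all-NaN rows produce NaN means; values there are NaN anyway
    vals = vals - np.where(np.isfinite(row_mean), row_mean, 0.0)
    vals = _zscore_columns(vals)
    return replace(m, values=vals)


def normalize_dual_channel(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-normalize each sample column of a dual-channel (log-ratio) matrix."""
    if m.channel != DUAL:
        raise ValueError(f"expected dual-channel matrix, got {m.channel!r}")
    return replace(m, values=_zscore_columns(m.values.copy()))


def normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Dispatch to the channel-appropriate normalization."""
    return normalize_single_channel(m) if m.channel == SINGLE else normalize_dual_channel(m)


def merge_probes(m: ExpressionMatrix, pmap: ProbeGeneMap) -> ExpressionMatrix:
    """Average each gene's probes (missing-aware); unmapped probes dropped.

    Rows of the result are keyed by gene ID; probes without a mapping do not
    contribute.  A zero-overlap map yields an empty matrix.
    """
    gene_rows: dict[str, list[int]] = {}
    for i, probe in enumerate(m.probe_ids):
        gene = pmap.gene_of(probe)
        if gene is not None:
            gene_rows.setdefault(gene, []).append(i)
    genes = sorted(gene_rows)
    out = np.full((len(genes), m.n_samples), np.nan)
    for gi, gene in enumerate(genes):
        block = m.values[gene_rows[gene], :]
        with np.errstate(invalid="ignore"):
            out[gi] = np.nanmean(block, axis=0)
    return replace(m, probe_ids=tuple(genes), values=out)


def pool_experiments(
    expset: ExperimentSet,
    pmap: ProbeGeneMap,
    channel: str,
) -> GeneProfileMatrix | None:
    """Normalize and probe-merge each experiment of one channel, then pool.

    Columns are concatenated across experiments over the union of genes;
    genes absent from an experiment are missing in its columns.  Returns
    ``None`` when the organism has no experiment of the requested channel.
    """
    frames = []
    for exp in expset.experiments:
        if exp.channel != channel:
            continue
        merged = merge_probes(normalize(exp), pmap)
        if merged.n_probes == 0:
            continue
        df = pd.DataFrame(
            merged.values,
            index=list(merged.probe_ids),
            columns=[f"{exp.experiment_id}:{s}" for s in merged.sample_ids],
        )
        frames.append(df)
    if not frames:
        return None
    pooled = pd.concat(frames, axis=1).sort_index()
    return GeneProfileMatrix(
        organism_id=expset.organism_id,
        channel=channel,
        gene_ids=tuple(pooled.index),
        array_ids=tuple(pooled.columns),
        values=pooled.to_numpy(),
    )


def array_similarity(profiles: GeneProfileMatrix, min_overlap: int = 20) -> SimilarityMatrix:
    """Pairwise Spearman correlation between arrays over shared genes.

    Entries with fewer than ``min_overlap`` pairwise-complete genes, or with
    zero variance in either array, are NaN and treated as below any pruning
    threshold.
    """
    if len(profiles.array_ids) < 2:
        raise ValueError("array_similarity needs at least 2 arrays")
    df = profiles.to_frame()
    sims = df.corr(method="spearman", min_periods=max(min_overlap, 2)).to_numpy()
    np.fill_diagonal(sims, 1.0)
    return SimilarityMatrix(array_ids=profiles.array_ids, sims=sims)


def hobohm2_prune(sims: SimilarityMatrix, threshold: float) -> list[str]:
    """Hobohm-2 redundancy reduction over the array similarity graph.

    Build a graph with an edge wherever similarity exceeds ``threshold`` and
    repeatedly delete the vertex of highest current degree until no edge
    remains.  Degree ties are broken by deleting the lexicographically larger
    array ID, making the output deterministic.  The survivors contain no pair
    above the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n = len(sims.array_ids)
    adj = np.isfinite(sims.sims) & (sims.sims > threshold)
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    ids = sims.array_ids
    while True:
        degrees = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        degrees[~alive] = 0
        max_deg = degrees.max() if n else 0
        if max_deg == 0:
            break
        candidates = [i for i in range(n) if alive[i] and degrees[i] == max_deg]
        victim = max(candidates, key=lambda i: ids[i])
        alive[victim] = False
    return [ids[i] for i in range(n) if alive[i]]


def gene_correlation(
    profiles: GeneProfileMatrix,
    retained: Sequence[str],
    min_overlap: int = 20,
) -> GenePairCorrelations:
    """Pearson correlation for every gene pair over the retained arrays.

    Pairs with fewer than ``min_overlap`` pairwise-complete observations are
    omitted; ``n_arrays`` records the pairwise-complete count.
    """
    if not retained:
        raise ValueError("retained array set is empty")
    retained = list(retained)
    missing = set(retained) - set(profiles.array_ids)
    if missing:
        raise ValueError(f"retained arrays not in profiles: {sorted(missing)[:5]}")
    df = profiles.to_frame()[retained]
    # correlate genes (rows) pairwise-complete
    gdf = df.T
    corr = gdf.corr(method="pearson", min_periods=max(min_overlap, 2))
    present = gdf.notna().to_numpy().astype(np.int64)
    counts = present.T @ present
    genes = list(gdf.columns)
    rows = []
    cm = corr.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = cm[i, j]
            nij = counts[i, j]
            if nij >= min_overlap and np.isfinite(r):
                a, b = genes[i], genes[j]
                if a > b:
                    a, b = b, a
                rows.append((a, b, float(r), int(nij)))
    rows.sort(key=lambda t: (t[0], t[1]))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "n_arrays"])
    if table.empty:
        table = pd.DataFrame({"gene_a": pd.Series(dtype=str), "gene_b": pd.Series(dtype=str),
                              "r": pd.Series(dtype=float), "n_arrays": pd.Series(dtype=int)})
    return GenePairCorrelations(table=table)
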