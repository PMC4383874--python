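"""Calibration of raw correlations into association probabilities.

Raw gene-gene correlations mean different things in different data sets, so
they are calibrated against an external gold standard: a pair of genes counts
as a true functional association when both are annotated to at least one
common pathway.  A sliding window over pairs ranked by correlation estimates
local precision, and isotonic (pool-adjacent-violators) regression makes the
resulting curve monotone.  The calibrated per-channel scores are finally
merged with a prior-corrected noisy-OR: each channel's score is an
independent probability of association above the baseline prior, so the
combined confidence is one minus the product of the corrected failure
probabilities, with the prior restored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from assocnet.coexpression import GenePairCorrelations


@dataclass(frozen=True)
class GoldStandard:
    """Gene -> set of pathway IDs; co-membership defines a positive pair."""

    memberships: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {g: frozenset(p) for g, p in self.memberships.items() if p}
        object.__setattr__(self, "memberships", clean)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GoldStandard":
        """Read a 2-column TSV ``gene_id<TAB>pathway_id`` (multi-row per gene)."""
        members: dict[str, set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            gene, pathway = line.split("\t")[:2]
            members.setdefault(gene.strip(), set()).add(pathway.strip())
        return cls({g: frozenset(p) for g, p in members.items()})

    def label(self, gene_a: str, gene_b: str) -> int | None:
        """1 if the genes share a pathway, 0 if annotated but disjoint,
        None if either gene is unannotated (unbenchmarkable)."""
        pa = self.memberships.get(gene_a)
        pb = self.memberships.get(gene_b)
        if pa is None or pb is None:
            return None
        return 1 if pa & pb else 0


@dataclass(frozen=True)
class LabeledPairs:
    """Benchmarkable pairs: columns gene_a, gene_b, r, label (0/1)."""

    table: pd.DataFrame


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from raw correlation to posterior association probability.

    ``xs``/``ys`` are the knots (raw score, posterior), non-decreasing in both;
    scores outside the knot range are clamped to the boundary posteriors.
    """

    xs: np.ndarray
    ys: np.ndarray
    window_size: int
    prior: float

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)
        if xs.shape != ys.shape or xs.ndim != 1 or xs.size == 0:
            raise ValueError("knots must be non-empty 1-D arrays of equal length")
        if np.any(np.diff(xs) <= 0):
            raise ValueError("knot raw scores must be strictly increasing")
        if np.any(np.diff(ys) < -1e-12):
            raise ValueError("posteriors must be non-decreasing")
        if not 0 <= self.prior <= 1:
            raise ValueError("prior must be in [0, 1]")

    def __call__(self, raw: float | np.ndarray) -> np.ndarray:
        return np.interp(raw, self.xs, self.ys)


@dataclass(frozen=True)
class ScoredNetwork:
    """Edge list with per-channel and combined probabilistic scores.

    ``edges`` holds gene_a, gene_b (gene_a < gene_b), one score column per
    channel (NaN where the channel gave no score) and ``combined``.
    """

    edges: pd.DataFrame
    channels: tuple[str, ...]
    prior: float = 0.0

    def __post_init__(self) -> None:
        needed = ["gene_a", "gene_b", *self.channels, "combined"]
        missing = [c for c in needed if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edges missing columns {missing}")
        if len(self.edges) and not (self.edges["gene_a"] < self.edges["gene_b"]).all():
            raise ValueError("edges must satisfy gene_a < gene_b")

    def __len__(self) -> int:
        return len(self.edges)

    def to_tsv(self, path: str | Path, integer_scores: bool = False) -> None:
        """Write the edge table; ``integer_scores`` renders 0-999 integers."""
        out = self.edges[["gene_a", "gene_b", *self.channels, "combined"]].copy()
        for col in (*self.channels, "combined"):
            if integer_scores:
                out[col] = (
                    out[col].mul(1000).round().clip(upper=999).astype("Int64")
                )
            else:
                out[col] = out[col].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, prior: float = 0.0) -> "ScoredNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        channels = tuple(c for c in df.columns if c not in ("gene_a", "gene_b", "combined"))
        return cls(edges=df, channels=channels, prior=prior)


@dataclass(frozen=True)
class RocResult:
    """ROC points (FPR, TPR) with trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{fpr:.6g}\t{tpr:.6g}" for fpr, tpr in self.points]
        lines.append(f"auc\t{self.auc:.6g}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def label_pairs(pairs: GenePairCorrelations, gold: GoldStandard) -> LabeledPairs:
    """Label pairs by pathway co-membership; unbenchmarkable pairs dropped."""
    t = pairs.table
    labels = [gold.label(a, b) for a, b in zip(t["gene_a"], t["gene_b"])]
    keep = [i for i, lab in enumerate(labels) if lab is not None]
    out = t.iloc[keep][["gene_a", "gene_b", "r"]].copy()
    out["label"] = [labels[i] for i in keep]
    return LabeledPairs(table=out.reset_index(drop=True))


def calibrate(pairs: LabeledPairs, window_size: int = 500) -> CalibrationCurve:
    """Estimate the correlation -> precision curve by sliding window + PAV.

    Pairs are sorted by raw correlation; every full window of ``window_size``
    consecutive pairs contributes a knot (mean correlation, positive
    fraction), and isotonic regression enforces monotonicity.  The prior is
    the global positive fraction of the benchmarkable pairs.
    """
    if window_size < 50:
        raise ValueError(f"window_size must be >= 50, got {window_size}")
    t = pairs.table
    n = len(t)
    if n < window_size:
        raise ValueError(
            f"need at least window_size={window_size} benchmarkable pairs, got {n}"
        )
    order = t.sort_values("r", ascending=True, kind="mergesort")
    r = order["r"].to_numpy(dtype=float)
    y = order["label"].to_numpy(dtype=float)
    prior = float(y.mean())

    win = pd.Series(y).rolling(window_size)
    precision = win.mean().to_numpy()[window_size - 1 :]
    raw = pd.Series(r).rolling(window_size).mean().to_numpy()[window_size - 1 :]

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(raw, precision)

    # collapse duplicate raw scores so knots are strictly increasing
    knots = pd.DataFrame({"x": raw, "y": fitted}).groupby("x", as_index=False).mean()
    return CalibrationCurve(
        xs=knots["x"].to_numpy(),
        ys=np.maximum.accumulate(knots["y"].to_numpy()),
        window_size=window_size,
        prior=prior,
    )


def score_pairs(
    pairs: GenePairCorrelations,
    curve: CalibrationCurve,
    channel: str = "coexpression",
) -> ScoredNetwork:
    """Map each pair's raw correlation through the calibration curve.

    Scores interpolate linearly between knots and clamp at the boundary
    posteriors outside the knot range.  The single filled channel doubles as
    the combined score.
    """
    t = pairs.table
    scores = curve(t["r"].to_numpy(dtype=float))
    edges = pd.DataFrame(
        {
            "gene_a": t["gene_a"].to_numpy(),
            "gene_b": t["gene_b"].to_numpy(),
            channel: scores,
            "combined": scores,
        }
    )
    return ScoredNetwork(edges=edges, channels=(channel,), prior=curve.prior)


def combine_scores(
    channel_scores: Mapping[str, float] | Iterable[float],
    prior: float = 0.0,
) -> float:
    """Prior-corrected noisy-OR combination of channel scores.

    Each score is first floored at the prior and corrected,
    ``s' = (s - prior) / (1 - prior)``; the corrected scores combine as
    ``1 - prod(1 - s')`` and the prior is restored.  With one channel the
    input score is returned unchanged.  The result lies in [prior, 1).
    """
    if isinstance(channel_scores, Mapping):
        scores = [float(v) for v in channel_scores.values()]
    else:
        scores = [float(v) for v in channel_scores]
    if not 0 <= prior < 1:
        raise ValueError(f"prior must be in [0, 1), got {prior}")
    if not scores:
        raise ValueError("no channel scores to combine")
    for s in scores:
        if not 0 <= s <= 1:
            raise ValueError(f"scores must be in [0, 1], got {s}")
    complement = 1.0
    for s in scores:
        s_corr = (max(s, prior) - prior) / (1.0 - prior)
        complement *= 1.0 - s_corr
    return (1.0 - complement) * (1.0 - prior) + prior


def combine_networks(
    channel_networks: Mapping[str, ScoredNetwork],
    prior: float,
) -> ScoredNetwork:
    """Outer-join per-channel edge tables and combine scores per edge.

    An edge scored by only some channels combines the scores it has; the
    channel columns keep NaN where a channel did not score the pair.
    """
    merged: pd.DataFrame | None = None
    channels = tuple(channel_networks)
    for name, net in channel_networks.items():
        part = net.edges[["gene_a", "gene_b", *net.channels]].copy()
        if len(net.channels) != 1 or net.channels[0] != name:
            part = part.rename(columns={net.channels[0]: name})
        merged = part if merged is None else merged.merge(
            part, on=["gene_a", "gene_b"], how="outer"
        )
    assert merged is not None
    combined = [
        combine_scores([s for s in row if np.isfinite(s)], prior)
        for row in merged[list(channels)].to_numpy()
    ]
    merged["combined"] = combined
    merged = merged.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return ScoredNetwork(edges=merged, channels=channels, prior=prior)


def roc_benchmark(network: ScoredNetwork, gold: GoldStandard) -> RocResult:
    """ROC of the combined scores against pathway co-membership labels.

    Tied scores collapse into a single ROC step; the AUC is the trapezoidal
    integral of the curve.
    """
    labels = []
    scores = []
    for a, b, s in zip(
        network.edges["gene_a"], network.edges["gene_b"], network.edges["combined"]
    ):
        lab = gold.label(a, b)
        if lab is not None and np.isfinite(s):
            labels.append(lab)
            scores.append(float(s))
    labels_arr = np.asarray(labels)
    if labels_arr.size == 0 or labels_arr.min() == labels_arr.max():
        raise ValueError("ROC benchmark needs at least one positive and one negative pair")
    fpr, tpr, _ = _roc_curve(labels_arr, np.asarray(scores))
    return RocResult(
        points=tuple((float(f), float(t)) for f, t in zip(fpr, tpr)),
        auc=float(_trapezoid_auc(fpr, tpr)),
    )
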