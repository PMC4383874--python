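"""Synthetic data with known ground truth.

Expression fixtures follow a latent-factor model: each planted module has one
activity value per sample and its member genes load on it with unit weight,
so co-expression of module members is co-regulation by construction.
Background genes carry pure noise.  The generator also plants the nuisance
structure the pipeline must handle: near-duplicate arrays (to exercise
Hobohm-2 pruning), multiple probes per gene (to exercise probe merging) and a
mix of single-channel intensity arrays (positive values ``2**signal``, so the
log2 step inverts them) and dual-channel log-ratio arrays.

The orthology generator builds a balanced species tree with nested,
consistent orthologous groups, then optionally corrupts a fraction of
assignments to give the consistency algorithm something to repair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from assocnet.io import DUAL, SINGLE, ExperimentSet, ExpressionMatrix, ProbeGeneMap
from assocnet.orthology import CladeTree, OrthologGroupSet
from assocnet.scoring import GoldStandard


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the expression generator.

    Defaults plant 20 modules of 10 genes covering all 200 genes, with
    per-gene and per-probe Gaussian noise of sd 0.5 against unit-variance
    module activities, 60 experiments of 4 samples, a 10% rate of
    near-duplicate arrays, up to 2 probes per gene and an even single/dual
    channel mix.
    """

    n_genes: int = 200
    n_modules: int = 20
    module_size: int = 10
    n_experiments: int = 60
    samples_per_experiment: int = 4
    noise_sd: float = 0.5
    duplicate_array_rate: float = 0.1
    duplicate_noise_sd: float = 0.01
    probes_per_gene_max: int = 2
    channel_mix: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_modules",
            "module_size",
            "n_experiments",
            "samples_per_experiment",
            "probes_per_gene_max",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.duplicate_array_rate <= 1:
            raise ValueError("duplicate_array_rate must be in [0, 1]")
        if not 0 <= self.channel_mix <= 1:
            raise ValueError("channel_mix must be in [0, 1]")
        if self.module_size * self.n_modules > self.n_genes:
            raise ValueError(
                f"module_size * n_modules = {self.module_size * self.n_modules} "
                f"exceeds n_genes = {self.n_genes}"
            )


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated experiments plus the planted truth.

    The gold standard's pathways are exactly the planted modules, so the
    calibration/benchmark truth is known by construction.
    """

    experiments: tuple[ExperimentSet, ...]
    probe_map: ProbeGeneMap
    gold: GoldStandard
    truth: Mapping[str, str | None]


def simulate_expression(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate one organism's experiment set under the latent-factor model.

    Per sample, each module draws an activity ~ N(0, 1); a member gene's
    value is that activity plus N(0, noise_sd), a background gene's value is
    noise alone.  Each probe adds independent N(0, noise_sd) on top of its
    gene.  Single-channel experiments are emitted as positive intensities
    ``2**(probe value + probe baseline)``; dual-channel experiments as the
    log-ratio values themselves.  With probability ``duplicate_array_rate`` a
    sample is emitted twice, the copy perturbed by N(0, duplicate_noise_sd).
    Fully reproducible from ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    organism = "org1"

    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    module_of: dict[str, str | None] = {g: None for g in gene_ids}
    for m in range(config.n_modules):
        for j in range(config.module_size):
            module_of[gene_ids[m * config.module_size + j]] = f"M{m:02d}"

    # global probe layout: 1..probes_per_gene_max probes per gene
    probe_map_entries: dict[str, str] = {}
    probes_of: dict[str, list[str]] = {}
    for g in gene_ids:
        n_probes = int(rng.integers(1, config.probes_per_gene_max + 1))
        probes = [f"{g}_p{k}" for k in range(n_probes)]
        probes_of[g] = probes
        for p in probes:
            probe_map_entries[p] = g
    all_probes = [p for g in gene_ids for p in probes_of[g]]
    baseline = {p: float(rng.normal(8.0, 2.0)) for p in all_probes}

    experiments: list[ExpressionMatrix] = []
    for e in range(config.n_experiments):
        channel = SINGLE if rng.random() < config.channel_mix else DUAL
        cols: list[np.ndarray] = []
        sample_ids: list[str] = []
        for s in range(config.samples_per_experiment):
            activity = rng.normal(0.0, 1.0, size=config.n_modules)
            gene_signal = {}
            for g in gene_ids:
                mod = module_of[g]
                base = activity[int(mod[1:])] if mod is not None else 0.0
                gene_signal[g] = base + rng.normal(0.0, config.noise_sd)
            col = np.array(
                [
                    gene_signal[probe_map_entries[p]] + rng.normal(0.0, config.noise_sd)
                    for p in all_probes
                ]
            )
            cols.append(col)
            sample_ids.append(f"s{s:02d}")
            if rng.random() < config.duplicate_array_rate:
                dup = col + rng.normal(0.0, config.duplicate_noise_sd, size=col.shape)
                cols.append(dup)
                sample_ids.append(f"s{s:02d}dup")
        values = np.column_stack(cols)
        if channel == SINGLE:
            values = 2.0 ** (values + np.array([baseline[p] for p in all_probes])[:, None])
        experiments.append(
            ExpressionMatrix(
                experiment_id=f"E{e:03d}",
                organism_id=organism,
                channel=channel,
                probe_ids=tuple(all_probes),
                sample_ids=tuple(sample_ids),
                values=values,
            )
        )

    gold = GoldStandard(
        {g: frozenset([m]) for g, m in module_of.items() if m is not None}
    )
    return SyntheticDataset(
        experiments=(ExperimentSet(organism_id=organism, experiments=tuple(experiments)),),
        probe_map=ProbeGeneMap(entries=probe_map_entries),
        gold=gold,
        truth=dict(module_of),
    )


def simulate_orthology(
    n_species: int = 8,
    depth: int = 3,
    n_families: int = 10,
    corruption_rate: float = 0.0,
    seed: int = 0,
) -> tuple[CladeTree, OrthologGroupSet, OrthologGroupSet]:
    """Balanced species tree with nested ortholog groups and optional noise.

    Clades split the species in half down to ``depth`` levels (or single
    species).  Each family has 1-3 paralogs per species; the consistent truth
    is built top-down, with each parent group's restriction to a child clade
    randomly kept whole or split in two.  A ``corruption_rate`` fraction of
    non-root assignments is then reassigned to a random other group of the
    same clade.  Returns (tree, corrupted groups, uncorrupted truth).
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    species = [f"sp{i}" for i in range(n_species)]

    nodes: dict[str, tuple[str | None, frozenset[str]]] = {}
    clade_children: dict[str, list[str]] = {}

    def build(clade: str, parent: str | None, members: list[str], level: int) -> None:
        nodes[clade] = (parent, frozenset(members))
        if level >= depth - 1 or len(members) <= 1:
            return
        half = len(members) // 2
        for idx, part in enumerate((members[:half], members[half:])):
            if part:
                child = f"{clade}.{idx}"
                clade_children.setdefault(clade, []).append(child)
                build(child, clade, part, level + 1)

    build("C", None, species, 0)
    tree = CladeTree(nodes=nodes)

    protein_species: dict[str, str] = {}
    family_members: dict[int, list[str]] = {}
    for fam in range(n_families):
        members = []
        for sp in species:
            for k in range(int(rng.integers(1, 4))):
                pid = f"{sp}_f{fam}_{k}"
                protein_species[pid] = sp
                members.append(pid)
        family_members[fam] = members

    # truth: nested refinement built top-down
    assignments: dict[str, dict[str, str]] = {}
    root_groups: dict[str, list[str]] = {
        f"C:f{fam}": list(family_members[fam]) for fam in family_members
    }
    assignments["C"] = {p: g for g, ms in root_groups.items() for p in ms}
    frontier: dict[str, dict[str, list[str]]] = {"C": root_groups}
    order = sorted(nodes, key=lambda c: len(tree.ancestors(c)))
    for clade in order:
        if clade == "C":
            continue
        parent = tree.parent(clade)
        parent_groups = frontier[parent]
        covered = tree.species_of(clade)
        my_groups: dict[str, list[str]] = {}
        for pg, members in sorted(parent_groups.items()):
            here = [p for p in members if protein_species[p] in covered]
            if not here:
                continue
            if len(here) > 1 and rng.random() < 0.5:
                cut = int(rng.integers(1, len(here)))
                parts = [here[:cut], here[cut:]]
            else:
                parts = [here]
            for idx, part in enumerate(parts):
                my_groups[f"{clade}:{pg.split(':', 1)[1]}.{idx}"] = part
        frontier[clade] = my_groups
        assignments[clade] = {p: g for g, ms in my_groups.items() for p in ms}

    truth = OrthologGroupSet(
        assignments={c: dict(a) for c, a in assignments.items()},
        protein_species=dict(protein_species),
    )

    corrupted = {c: dict(a) for c, a in assignments.items()}
    if corruption_rate > 0:
        for clade in sorted(corrupted):
            if clade == "C":
                continue
            group_ids = sorted(set(corrupted[clade].values()))
            if len(group_ids) < 2:
                continue
            for protein in sorted(corrupted[clade]):
                if rng.random() < corruption_rate:
                    others = [g for g in group_ids if g != corrupted[clade][protein]]
                    corrupted[clade][protein] = others[int(rng.integers(len(others)))]
    corrupted_set = OrthologGroupSet(
        assignments=corrupted, protein_species=dict(protein_species)
    )
    return tree, corrupted_set, truth
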