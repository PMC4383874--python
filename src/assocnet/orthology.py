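"""Hierarchical orthologous groups: consistency repair and interolog transfer.

Orthologous groups are given per clade of a species tree, at increasing
phylogenetic resolution toward the leaves.  The hierarchy is *self-consistent*
when proteins grouped together at a clade are also grouped together at every
ancestor clade.  Independently computed per-clade assignments routinely
violate this, so :func:`enforce_consistency` repairs the hierarchy by
iteratively merging ancestor groups (``merge_up``) or splitting descendant
groups (``split_down``) until a fixpoint is reached.

A consistent hierarchy supports interolog transfer: a scored interaction in a
source species propagates to a target species through the orthologous groups
at the lowest clade covering both species.  When either group contains
multiple target-species members (in-paralogs) the transferred score is
divided by ``(n_a * n_b) ** gamma``, a configurable paralogy penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from assocnet.scoring import ScoredNetwork, combine_scores


@dataclass(frozen=True)
class CladeTree:
    """Rooted clade hierarchy; each clade covers a set of species.

    ``nodes`` maps clade_id -> (parent_id or None, frozenset of species).
    The single root covers all species, children cover subsets of their
    parent, and sibling species sets are disjoint.
    """

    nodes: Mapping[str, tuple[str | None, frozenset[str]]]

    def __post_init__(self) -> None:
        roots = [c for c, (p, _) in self.nodes.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        children: dict[str, list[str]] = {}
        for clade, (parent, species) in self.nodes.items():
            if parent is not None:
                if parent not in self.nodes:
                    raise ValueError(f"clade {clade!r} has unknown parent {parent!r}")
                if not species <= self.nodes[parent][1]:
                    raise ValueError(
                        f"clade {clade!r} species are not a subset of parent {parent!r}"
                    )
                children.setdefault(parent, []).append(clade)
        for parent, kids in children.items():
            seen: set[str] = set()
            for kid in kids:
                overlap = seen & self.nodes[kid][1]
                if overlap:
                    raise ValueError(
                        f"sibling clades under {parent!r} share species {sorted(overlap)}"
                    )
                seen |= self.nodes[kid][1]

    @property
    def root(self) -> str:
        return next(c for c, (p, _) in self.nodes.items() if p is None)

    def species_of(self, clade: str) -> frozenset[str]:
        return self.nodes[clade][1]

    def parent(self, clade: str) -> str | None:
        return self.nodes[clade][0]

    def ancestors(self, clade: str) -> list[str]:
        """Strict ancestors, nearest first."""
        out = []
        p = self.parent(clade)
        while p is not None:
            out.append(p)
            p = self.parent(p)
        return out

    def depth(self, clade: str) -> int:
        return len(self.ancestors(clade))

    def all_species(self) -> frozenset[str]:
        return self.species_of(self.root)

    def lowest_common_clade(self, species_a: str, species_b: str) -> str:
        """The smallest clade covering both species (unique in a nested tree)."""
        for sp in (species_a, species_b):
            if sp not in self.all_species():
                raise ValueError(f"species {sp!r} not in tree")
        covering = [
            c for c, (_, spp) in self.nodes.items() if species_a in spp and species_b in spp
        ]
        assert covering, "rooted tree always has a common clade"
        return min(covering, key=lambda c: (len(self.species_of(c)), c))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CladeTree":
        """Read 3-column TSV ``clade_id<TAB>parent_id<TAB>species,species,...``;
        an empty or ``-`` parent marks the root."""
        nodes: dict[str, tuple[str | None, frozenset[str]]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            clade, parent, species = (line.split("\t") + ["", ""])[:3]
            parent_id = parent.strip() or None
            if parent_id == "-":
                parent_id = None
            spp = frozenset(s.strip() for s in species.split(",") if s.strip())
            nodes[clade.strip()] = (parent_id, spp)
        return cls(nodes=nodes)

    def to_tsv(self, path: str | Path) -> None:
        lines = []
        for clade, (parent, species) in self.nodes.items():
            lines.append(f"{clade}\t{parent or '-'}\t{','.join(sorted(species))}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class OrthologGroupSet:
    """Per-clade partitions of proteins plus each protein's species."""

    assignments: Mapping[str, Mapping[str, str]]  # clade -> protein -> group
    protein_species: Mapping[str, str]

    def validate_against(self, tree: CladeTree) -> None:
        for clade, assignment in self.assignments.items():
            if clade not in tree.nodes:
                raise ValueError(f"unknown clade {clade!r} in group assignments")
            covered = tree.species_of(clade)
            for protein in assignment:
                sp = self.protein_species.get(protein)
                if sp is None:
                    raise ValueError(f"protein {protein!r} has no species")
                if sp not in covered:
                    raise ValueError(
                        f"protein {protein!r} (species {sp!r}) assigned at clade "
                        f"{clade!r} which does not cover it"
                    )

    def groups_at(self, clade: str) -> dict[str, set[str]]:
        """Group -> member proteins at one clade."""
        out: dict[str, set[str]] = {}
        for protein, group in self.assignments.get(clade, {}).items():
            out.setdefault(group, set()).add(protein)
        return out

    def partition_signature(self) -> dict[str, frozenset[frozenset[str]]]:
        """Clade -> set of member sets, label-independent (for comparisons)."""
        return {
            clade: frozenset(frozenset(m) for m in self.groups_at(clade).values())
            for clade in self.assignments
        }

    @classmethod
    def from_tsv(cls, path: str | Path, protein_species: Mapping[str, str]) -> "OrthologGroupSet":
        """Read 3-column TSV ``clade_id<TAB>group_id<TAB>protein_id``."""
        assignments: dict[str, dict[str, str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            clade, group, protein = line.split("\t")[:3]
            assignments.setdefault(clade.strip(), {})[protein.strip()] = group.strip()
        return cls(assignments=assignments, protein_species=dict(protein_species))

    def to_tsv(self, path: str | Path) -> None:
        lines = []
        for clade in sorted(self.assignments):
            for protein, group in sorted(self.assignments[clade].items()):
                lines.append(f"{clade}\t{group}\t{protein}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class Violation:
    """A group whose members are split across groups at an ancestor clade."""

    clade: str
    group: str
    ancestor: str
    witnesses: tuple[str, str]  # two proteins separated at the ancestor


@dataclass(frozen=True)
class TransferConfig:
    """Interolog-transfer knobs.

    ``gamma`` is the paralogy-penalty exponent: a transferred score is divided
    by ``(n_a * n_b) ** gamma`` where n_a, n_b count the target-species
    members of the two orthologous groups.  Edges below
    ``min_transferred_score`` are dropped.
    """

    gamma: float = 0.5
    min_transferred_score: float = 0.15

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 <= self.min_transferred_score <= 1:
            raise ValueError("min_transferred_score must be in [0, 1]")


def is_consistent(
    groups: OrthologGroupSet, tree: CladeTree
) -> tuple[bool, list[Violation]]:
    """Check hierarchy self-consistency.

    True iff for every clade and every ancestor, each group's proteins that
    are assigned at the ancestor fall into a single ancestor group.  Proteins
    unassigned at the ancestor are ignored.
    """
    groups.validate_against(tree)
    violations: list[Violation] = []
    for clade in groups.assignments:
        for ancestor in tree.ancestors(clade):
            anc_assign = groups.assignments.get(ancestor, {})
            if not anc_assign:
                continue
            for group, members in sorted(groups.groups_at(clade).items()):
                anc_groups: dict[str, str] = {}
                for protein in sorted(members):
                    anc_group = anc_assign.get(protein)
                    if anc_group is not None:
                        anc_groups[protein] = anc_group
                distinct = sorted(set(anc_groups.values()))
                if len(distinct) > 1:
                    by_group = {g: [p for p, ag in anc_groups.items() if ag == g] for g in distinct}
                    witnesses = (by_group[distinct[0]][0], by_group[distinct[1]][0])
                    violations.append(Violation(clade, group, ancestor, witnesses))
    return (not violations, violations)


def _relabel(
    assignments: dict[str, dict[str, str]],
    original: OrthologGroupSet,
) -> dict[str, dict[str, str]]:
    """Give repaired groups stable IDs: keep an original ID when the member
    set is unchanged, otherwise derive one from the smallest member."""
    out: dict[str, dict[str, str]] = {}
    for clade, assignment in assignments.items():
        members_by_group: dict[str, set[str]] = {}
        for protein, group in assignment.items():
            members_by_group.setdefault(group, set()).add(protein)
        original_sets = {
            frozenset(m): g for g, m in original.groups_at(clade).items()
        }
        taken = set()
        mapping: dict[str, str] = {}
        for group, members in sorted(members_by_group.items(), key=lambda kv: min(kv[1])):
            orig = original_sets.get(frozenset(members))
            if orig is not None and orig not in taken:
                new_id = orig
            else:
                new_id = f"{clade}|{min(members)}"
                while new_id in taken:
                    new_id += "+"
            mapping[group] = new_id
            taken.add(new_id)
        out[clade] = {p: mapping[g] for p, g in assignment.items()}
    return out


def enforce_consistency(
    groups: OrthologGroupSet,
    tree: CladeTree,
    strategy: str = "merge_up",
) -> OrthologGroupSet:
    """Repair the hierarchy until :func:`is_consistent` holds.

    ``merge_up`` walks clades leaves-to-root and union-merges the ancestor
    groups that share any descendant group's proteins: ancestor groups only
    grow.  ``split_down`` walks root-to-leaves and splits each group by its
    proteins' ancestor-group membership: descendant groups only shrink.
    Proteins unassigned at an ancestor never force a change; under
    ``split_down`` they stay with the sibling sub-group of the
    lexicographically smallest ancestor group.  Passes repeat until a
    fixpoint, so the result is idempotent.
    """
    if strategy not in ("merge_up", "split_down"):
        raise ValueError(f"unknown strategy {strategy!r}")
    groups.validate_against(tree)
    assign: dict[str, dict[str, str]] = {
        clade: dict(a) for clade, a in groups.assignments.items()
    }
    clades = sorted(assign, key=lambda c: tree.depth(c))
    if strategy == "merge_up":
        clades = clades[::-1]  # leaves first

    changed = True
    while changed:
        changed = False
        for clade in clades:
            for ancestor in tree.ancestors(clade):
                anc = assign.get(ancestor)
                if not anc:
                    continue
                if strategy == "merge_up":
                    # merge ancestor groups linked by any group at `clade`
                    for members in _groups_of(assign[clade]).values():
                        anc_ids = sorted(
                            {anc[p] for p in members if p in anc}
                        )
                        if len(anc_ids) > 1:
                            target = anc_ids[0]
                            for protein, g in anc.items():
                                if g in anc_ids[1:]:
                                    anc[protein] = target
                            changed = True
                else:
                    # split groups at `clade` by ancestor membership
                    new_assign: dict[str, str] = {}
                    for group, members in sorted(_groups_of(assign[clade]).items()):
                        keys = sorted({anc[p] for p in members if p in anc})
                        if len(keys) <= 1:
                            for p in members:
                                new_assign[p] = group
                            continue
                        changed = True
                        default_key = keys[0]
                        for p in sorted(members):
                            key = anc.get(p, default_key)
                            new_assign[p] = f"{group}\x00{key}"
                    assign[clade] = new_assign
    result = OrthologGroupSet(
        assignments=_relabel(assign, groups),
        protein_species=dict(groups.protein_species),
    )
    ok, violations = is_consistent(result, tree)
    assert ok, f"fixpoint not consistent: {violations[:3]}"
    return result


def _groups_of(assignment: Mapping[str, str]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for protein, group in assignment.items():
        out.setdefault(group, set()).add(protein)
    return out


@dataclass(frozen=True)
class TransferSkip:
    """An edge that could not be transferred, with the reason."""

    gene_a: str
    gene_b: str
    reason: str

    def as_tsv(self) -> str:
        return f"{self.gene_a}\t{self.gene_b}\t{self.reason}"


def transfer_interactions(
    source: ScoredNetwork,
    source_species: str,
    target_species: str,
    groups: OrthologGroupSet,
    tree: CladeTree,
    config: TransferConfig | None = None,
) -> tuple[ScoredNetwork, list[TransferSkip]]:
    """Transfer scored edges from one species to another via orthologous groups.

    Each source edge is mapped at the lowest clade covering both species: the
    two proteins' groups are looked up, their target-species members
    enumerated, and every cross pair receives the source score divided by
    ``(n_a * n_b) ** gamma``.  Transfers landing on the same target pair merge
    by noisy-OR; self-pairs and scores below the configured floor are dropped.
    Untransferable edges are returned in the skip log.
    """
    config = config or TransferConfig()
    ok, violations = is_consistent(groups, tree)
    if not ok:
        raise ValueError(
            f"ortholog groups are not self-consistent ({len(violations)} violations); "
            "run enforce_consistency first"
        )
    clade = tree.lowest_common_clade(source_species, target_species)
    assignment = groups.assignments.get(clade, {})
    members_by_group = _groups_of(assignment)
    target_members = {
        g: sorted(
            p for p in members if groups.protein_species.get(p) == target_species
        )
        for g, members in members_by_group.items()
    }

    skips: list[TransferSkip] = []
    accumulated: dict[tuple[str, str], list[float]] = {}
    for a, b, score in zip(
        source.edges["gene_a"], source.edges["gene_b"], source.edges["combined"]
    ):
        ga, gb = assignment.get(a), assignment.get(b)
        if ga is None or gb is None:
            skips.append(TransferSkip(a, b, f"no group at clade {clade}"))
            continue
        ta, tb = target_members.get(ga, []), target_members.get(gb, [])
        if not ta or not tb:
            skips.append(TransferSkip(a, b, "no ortholog in target species"))
            continue
        penalty = (len(ta) * len(tb)) ** (-config.gamma)
        transferred = float(score) * penalty
        for x in ta:
            for y in tb:
                if x == y:
                    continue
                key = (x, y) if x < y else (y, x)
                accumulated.setdefault(key, []).append(transferred)

    rows = []
    for (x, y), scores in sorted(accumulated.items()):
        merged = combine_scores(scores, prior=0.0) if len(scores) > 1 else scores[0]
        if merged >= config.min_transferred_score:
            rows.append((x, y, merged, merged))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "transferred", "combined"])
    if edges.empty:
        edges = pd.DataFrame(
            {
                "gene_a": pd.Series(dtype=str),
                "gene_b": pd.Series(dtype=str),
                "transferred": pd.Series(dtype=float),
                "combined": pd.Series(dtype=float),
            }
        )
    return ScoredNetwork(edges=edges, channels=("transferred",)), skips
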