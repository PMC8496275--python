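"""Fitch-parsimony amino-acid substitution mapping on a species tree.

Per codon, the minimum number of amino-acid changes is computed by the
Fitch algorithm on a rooted binary tree; one deterministic resolution
assigns each change to a branch (ambiguous placements are flagged).  The
map supports multiple-hit summaries and 2x2 region-heterogeneity
chi-square tests (substituted vs unsubstituted codons across two named
regions, e.g. N-terminal vs C-terminal of the encoded protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .contingency import chi_square_2x2
from .siteclass import GENETIC_CODE, translate


@dataclass
class TreeNode:
    name: str                    # branch id (leaf label or internal id)
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for ch in self.children:
            yield from ch.postorder()
        yield self

    def leaves(self) -> list[str]:
        return [nd.name for nd in self.postorder() if nd.is_leaf]


@dataclass
class GeneTree:
    """A rooted tree with unique leaf labels and stable branch ids.

    Internal nodes get deterministic ids ``node_<k>`` in postorder unless
    labeled in the Newick source.
    """

    root: TreeNode
    branch_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.root.leaves()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        counter = [0]
        lengths: dict[str, float] = {}

        def convert(nd) -> TreeNode:
            children = [convert(ch) for ch in nd.child_nodes()]
            if not children:
                name = nd.taxon.label if nd.taxon else nd.label
            else:
                name = nd.label
            if not name:
                name = f"node_{counter[0]}"
                counter[0] += 1
            out = TreeNode(name=name, children=children)
            lengths[name] = (nd.edge.length
                             if nd.edge.length is not None else 1.0)
            return out

        root = convert(tree.seed_node)
        return cls(root=root, branch_lengths=lengths)

    @classmethod
    def from_file(cls, path) -> "GeneTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def leaves(self) -> list[str]:
        return self.root.leaves()


@dataclass
class BranchEvent:
    branch: str       # branch leading to this node
    codon: int
    from_aa: str
    to_aa: str
    ambiguous: bool   # placement/state involved an arbitrary Fitch choice


@dataclass
class SubstitutionMap:
    """Per-branch and per-codon amino-acid substitution tallies."""

    events: list[BranchEvent]
    per_codon_score: np.ndarray    # Fitch parsimony score per codon
    excluded_codons: list[int]     # codons with a gap in any species

    @property
    def total(self) -> int:
        return int(self.per_codon_score.sum())

    def per_branch(self) -> dict[str, list[BranchEvent]]:
        out: dict[str, list[BranchEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.branch, []).append(ev)
        return out

    def codons_hit(self) -> np.ndarray:
        return np.flatnonzero(self.per_codon_score >= 1)

    def to_tsv(self) -> str:
        lines = ["branch\tcodon\tfrom\tto\tambiguous"]
        for ev in sorted(self.events, key=lambda e: (e.codon, e.branch)):
            lines.append(f"{ev.branch}\t{ev.codon + 1}\t{ev.from_aa}\t"
                         f"{ev.to_aa}\t{int(ev.ambiguous)}")
        return "\n".join(lines) + "\n"


def _fitch_column(tree: GeneTree, states: dict[str, str]
                  ) -> tuple[int, list[BranchEvent], bool]:
    """Fitch score and one deterministic branch resolution for a column.

    Bottom-up: set intersection where possible, else union (one change).
    Top-down: a node keeps the parental state when it is in the node's
    set, else takes the alphabetically smallest member (change recorded on
    the branch to that node).  Ambiguity is flagged when the chosen state
    was not forced.
    """
    sets: dict[int, frozenset] = {}
    score = 0
    for nd in tree.root.postorder():
        if nd.is_leaf:
            sets[id(nd)] = frozenset(states[nd.name])
        else:
            s = sets[id(nd.children[0])]
            for ch in nd.children[1:]:
                inter = s & sets[id(ch)]
                if inter:
                    s = inter
                else:
                    s = s | sets[id(ch)]
                    score += 1
            sets[id(nd)] = s

    events: list[BranchEvent] = []
    any_ambiguous = False

    def assign(nd: TreeNode, parent_state: str | None) -> None:
        nonlocal any_ambiguous
        s = sets[id(nd)]
        if parent_state is not None and parent_state in s:
            state = parent_state
        else:
            state = min(s)
            if len(s) > 1:
                any_ambiguous = True
        if parent_state is not None and state != parent_state:
            events.append(BranchEvent(branch=nd.name, codon=-1,
                                      from_aa=parent_state, to_aa=state,
                                      ambiguous=len(s) > 1))
        for ch in nd.children:
            assign(ch, state)

    root_set = sets[id(tree.root)]
    assign(tree.root, None)
    if len(root_set) > 1:
        any_ambiguous = True
    return score, events, any_ambiguous


def fitch_count(tree: GeneTree, aa_alignment: dict[str, str]
                ) -> SubstitutionMap:
    """Map amino-acid substitutions per codon onto the tree by parsimony.

    ``aa_alignment`` maps each leaf label to its amino-acid sequence (all
    equal length).  Codons with a gap ('-') or 'X' in any species are
    excluded from the map.  The per-codon score is the Fitch minimum; the
    event list is one deterministic resolution achieving it.
    """
    leaves = tree.leaves()
    missing = [lf for lf in leaves if lf not in aa_alignment]
    if missing:
        raise ValueError(f"no sequence for leaves {missing}")
    lengths = {len(aa_alignment[lf]) for lf in leaves}
    if len(lengths) != 1:
        raise ValueError("amino-acid sequences must be aligned (equal length)")
    n_codons = lengths.pop()

    events: list[BranchEvent] = []
    scores = np.zeros(n_codons, dtype=int)
    excluded: list[int] = []
    for c in range(n_codons):
        states = {lf: aa_alignment[lf][c] for lf in leaves}
        if any(s in "-X*" for s in states.values()):
            excluded.append(c)
            continue
        if len(set(states.values())) == 1:
            continue
        score, col_events, _amb = _fitch_column(tree, states)
        scores[c] = score
        for ev in col_events:
            ev.codon = c
        events.extend(col_events)
    return SubstitutionMap(events=events, per_codon_score=scores,
                           excluded_codons=excluded)


def multiple_hit_summary(smap: SubstitutionMap
                         ) -> tuple[int, int, float | None]:
    """(codons hit >=1, codons hit >=2, fraction multiply hit)."""
    hit = int(np.sum(smap.per_codon_score >= 1))
    multi = int(np.sum(smap.per_codon_score >= 2))
    return hit, multi, (multi / hit if hit else None)


@dataclass
class RegionPartition:
    """Named codon intervals, 1-based inclusive as configured.

    Default layout: N_terminal, RNA_binding, C_terminal.
    """

    regions: dict[str, tuple[int, int]]

    def codons(self, name: str) -> np.ndarray:
        lo, hi = self.regions[name]
        return np.arange(lo - 1, hi)  # to 0-based

    def __post_init__(self) -> None:
        spans = sorted(self.regions.values())
        for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
            if b >= c:
                raise ValueError("regions must be disjoint")

    @classmethod
    def default_three_region(cls, n1: int = 136, n2: int = 303,
                             n_codons: int = 373) -> "RegionPartition":
        return cls({"N_terminal": (1, n1), "RNA_binding": (n1 + 1, n2),
                    "C_terminal": (n2 + 1, n_codons)})


def region_heterogeneity_test(smap: SubstitutionMap,
                              partition: RegionPartition,
                              region_a: str, region_b: str
                              ) -> tuple[float, float, tuple[int, int, int, int]]:
    """Chi-square for unequal substitution density in two regions.

    Builds the 2x2 table (substituted, unsubstituted) x (region A, B) over
    codons present in the map (gap-excluded codons removed from both
    margins) and applies the Pearson chi-square without continuity
    correction, df = 1.  Returns (statistic, p, cells).
    """
    excluded = set(smap.excluded_codons)
    cells = []
    for name in (region_a, region_b):
        codons = [c for c in partition.codons(name)
                  if c not in excluded and c < smap.per_codon_score.size]
        if not codons:
            raise ValueError(f"region {name!r} is empty")
        sub = int(np.sum(smap.per_codon_score[codons] >= 1))
        cells.append((sub, len(codons) - sub))
    a, b = cells[0]
    c, d = cells[1]
    stat, p = chi_square_2x2(a, b, c, d)
    return stat, p, (a, b, c, d)


def region_heterogeneity_from_counts(sub_a: int, total_a: int,
                                     sub_b: int, total_b: int
                                     ) -> tuple[float, float]:
    """Generic 2x2 heterogeneity chi-square from published-style counts."""
    return chi_square_2x2(sub_a, total_a - sub_a, sub_b, total_b - sub_b)
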