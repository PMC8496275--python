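"""Synthetic data generators with complete truth logs.

Every generator is seed-deterministic and records each planted event
(variant, fixation, or tree substitution) exactly once, so downstream
classification, polarization, lineage assignment and parsimony mapping can
be validated against known truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalsim import SimulationConfig, simulate_replicate
from .seqdata import (INGROUP, OUTGROUP, RegionAnnotation, SampleAlignment,
                      build_codon_map)
from .siteclass import (BASES, GENETIC_CODE, PREFERRED, PreferenceTable,
                        translate)
from .substmap import GeneTree, TreeNode

SYN = "synonymous"
NONSYN = "nonsynonymous"
INTRON = "intron"


@dataclass
class TruthLog:
    """Complete record of planted events.

    Each entry is a dict with at least ``kind`` plus event-specific keys
    (column/codon, ancestral/derived states, carriers or branch).
    """

    entries: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.entries.append(kw)

    def of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.entries if e["kind"] == kind]

    def to_tsv(self) -> str:
        keys = sorted({k for e in self.entries for k in e})
        lines = ["\t".join(keys)]
        for e in self.entries:
            lines.append("\t".join(str(e.get(k, "")) for k in keys))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Population alignments from the coalescent
# ---------------------------------------------------------------------------

def _mutation_candidates(ancestral: np.ndarray, ann: RegionAnnotation,
                         code=None) -> dict[str, list[tuple[int, list[str]]]]:
    """Per class, the columns where a single-base change of that class is
    possible, with the usable derived bases."""
    code = code or GENETIC_CODE
    cmap = build_codon_map(ann, ancestral.size)
    pools: dict[str, list[tuple[int, list[str]]]] = {
        SYN: [], NONSYN: [], INTRON: []}
    for col in ann.intron_columns():
        alts = [b for b in BASES if b != ancestral[col]]
        pools[INTRON].append((int(col), alts))
    for ci in range(cmap.n_codons):
        cols = cmap.columns_of(ci)
        codon = "".join(ancestral[cols])
        if translate(codon, code) == "*":
            continue
        for p, col in enumerate(cols):
            syn_alts, nonsyn_alts = [], []
            for b in BASES:
                if b == codon[p]:
                    continue
                mut = codon[:p] + b + codon[p + 1:]
                if code[mut] == "*":
                    continue
                (syn_alts if code[mut] == code[codon]
                 else nonsyn_alts).append(b)
            if syn_alts:
                pools[SYN].append((int(col), syn_alts))
            if nonsyn_alts:
                pools[NONSYN].append((int(col), nonsyn_alts))
    return pools


def random_coding_sequence(n_codons: int, rng: np.random.Generator,
                           code=None) -> str:
    """Random stop-free codon sequence."""
    code = code or GENETIC_CODE
    sense = sorted(c for c, aa in code.items() if aa != "*")
    return "".join(rng.choice(sense) for _ in range(n_codons))


def make_population_alignment(cfg: SimulationConfig, ancestral_seq: str,
                              ann: RegionAnnotation,
                              class_mix: dict[str, float] | None = None,
                              outgroup_divergence: int = 0,
                              n_outgroup_species: int = 1,
                              seed: int | None = None
                              ) -> tuple[SampleAlignment, TruthLog]:
    """Thread one coalescent replicate onto a codon-structured sequence.

    Segregating variants from the simulated genealogy are assigned to
    alignment columns drawn by the requested class mix (synonymous /
    nonsynonymous / intron proportions), each with a derived base of the
    matching effect; outgroup sequences start from the ancestral state
    with ``outgroup_divergence`` additional fixed changes.  Raises when a
    class runs out of eligible columns.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ancestral = np.array(list(ancestral_seq.upper()), dtype="U1")
    if ancestral.size != cfg.L:
        raise ValueError("ancestral sequence length must equal cfg.L")
    class_mix = class_mix or {SYN: 0.35, NONSYN: 0.15, INTRON: 0.5}
    classes = sorted(class_mix)
    probs = np.asarray([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    pools = _mutation_candidates(ancestral, ann)
    for key in pools:
        rng.shuffle(pools[key])
    used_columns: set[int] = set()

    def draw_site(cls: str) -> tuple[int, list[str]]:
        # a column may be eligible for more than one class; enforce the
        # infinite-sites assumption globally
        while pools[cls]:
            col, alts = pools[cls].pop()
            if col not in used_columns:
                used_columns.add(col)
                return col, alts
        raise ValueError(
            f"requested more {cls} variants than available sites")

    params = dict(cfg.fixed_params)
    theta_locus = params.get(
        "theta_locus", params.get("theta_per_site", 0.0) * cfg.L)
    model = cfg.build_model(params)
    sample = simulate_replicate(cfg.n, theta_locus, cfg.R, model, rng)

    truth = TruthLog()
    matrix = np.tile(ancestral, (cfg.n + n_outgroup_species, 1))

    for mask in sample.masks:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        col, alts = draw_site(cls)
        derived = str(rng.choice(alts))
        carriers = [i for i in range(cfg.n) if mask >> i & 1]
        for i in carriers:
            matrix[i, col] = derived
        truth.add(kind="polymorphism", column=col, site_class=cls,
                  ancestral=str(ancestral[col]), derived=derived,
                  carriers=tuple(carriers), frequency=len(carriers) / cfg.n)

    for _ in range(outgroup_divergence):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        col, alts = draw_site(cls)
        derived = str(rng.choice(alts))
        matrix[cfg.n:, col] = derived
        truth.add(kind="outgroup_divergence", column=col, site_class=cls,
                  ancestral=str(ancestral[col]), derived=derived,
                  carriers=tuple(range(cfg.n, cfg.n + n_outgroup_species)),
                  frequency=1.0)

    labels = [f"pop_{i}" for i in range(cfg.n)]
    species_of = {lab: "popA" for lab in labels}
    roles = {"popA": INGROUP}
    for k in range(n_outgroup_species):
        lab = f"out{k + 1}"
        labels.append(lab)
        species_of[lab] = lab
        roles[lab] = OUTGROUP
    aln = SampleAlignment(labels=labels, species_of=species_of,
                          matrix=matrix, roles=roles)
    return aln, truth


# ---------------------------------------------------------------------------
# Codon evolution along a tree
# ---------------------------------------------------------------------------

def _neighbors(codon: str, code=None) -> tuple[list[str], list[str]]:
    """Single-base synonymous and nonsynonymous (non-stop) neighbors."""
    code = code or GENETIC_CODE
    syn, nonsyn = [], []
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1:]
            if code[mut] == "*":
                continue
            (syn if code[mut] == code[codon] else nonsyn).append(mut)
    return syn, nonsyn


def evolve_on_tree(tree: GeneTree, ancestral_codons: list[str],
                   syn_rate: float, nonsyn_rate: float,
                   pref: PreferenceTable | None = None,
                   pref_bias: float = 0.5,
                   seed: int | None = None
                   ) -> tuple[dict[str, list[str]], TruthLog]:
    """Markov codon substitution along branches with logged events.

    Per codon and branch, synonymous and nonsynonymous event counts are
    Poisson with means ``rate * branch_length``; a synonymous event moves
    to a preferred single-base neighbor with probability ``pref_bias``
    when one exists (and to an unpreferred neighbor otherwise), a
    nonsynonymous event moves to a uniform nonsynonymous neighbor.  Every
    applied event is logged with its branch and codon.
    """
    if syn_rate < 0 or nonsyn_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    truth = TruthLog()
    tips: dict[str, list[str]] = {}

    def walk(node: TreeNode, seq: list[str]) -> None:
        for child in node.children:
            t = tree.branch_lengths.get(child.name, 1.0)
            cseq = list(seq)
            for ci in range(len(cseq)):
                n_syn = rng.poisson(syn_rate * t)
                n_non = rng.poisson(nonsyn_rate * t)
                kinds = ["syn"] * n_syn + ["nonsyn"] * n_non
                rng.shuffle(kinds)
                for kind in kinds:
                    syn_nb, nonsyn_nb = _neighbors(cseq[ci])
                    if kind == "syn":
                        if not syn_nb:
                            continue
                        if pref is not None:
                            pref_nb = [c for c in syn_nb
                                       if pref.of(c) == PREFERRED]
                            unpref_nb = [c for c in syn_nb
                                         if pref.of(c) != PREFERRED]
                            if pref_nb and (not unpref_nb
                                            or rng.random() < pref_bias):
                                pool = pref_nb
                            else:
                                pool = unpref_nb or pref_nb
                        else:
                            pool = syn_nb
                    else:
                        if not nonsyn_nb:
                            continue
                        pool = nonsyn_nb
                    new = str(rng.choice(pool))
                    truth.add(kind=kind, branch=child.name, codon=ci,
                              from_codon=cseq[ci], to_codon=new,
                              from_aa=translate(cseq[ci]),
                              to_aa=translate(new))
                    cseq[ci] = new
            if child.is_leaf:
                tips[child.name] = cseq
            walk(child, cseq)

    walk(tree.root, list(ancestral_codons))
    return tips, truth


# ---------------------------------------------------------------------------
# Direct MK fixtures
# ---------------------------------------------------------------------------

# 4-fold codon whose 3rd-position changes are synonymous and whose
# 2nd-position change G->T (Gly->Val) is nonsynonymous and stop-free
_BASE_CODON = "GGG"
_SYN_DERIVED = "GGA"
_NONSYN_DERIVED = "GTG"


def make_mk_fixture(counts: tuple[int, int, int, int], n_per_species: int,
                    seed: int | None = None, pad_codons: int = 2
                    ) -> tuple[SampleAlignment, RegionAnnotation]:
    """Three-species coding alignment with an exact planted MK table.

    ``counts`` = (syn_poly, nonsyn_poly, syn_fixed, nonsyn_fixed).
    Polymorphic variants are singletons planted alternately in the two
    ingroup populations (popA, popB); fixed differences separate both
    ingroups from the single-sequence outgroup.  Running
    ``classify_sites_mk({popA, popB}, {out})`` + ``build_mk_table`` on the
    result recovers ``counts`` exactly.
    """
    syn_poly, nonsyn_poly, syn_fixed, nonsyn_fixed = counts
    if min(counts) < 0:
        raise ValueError("counts must be non-negative")
    if (syn_poly or nonsyn_poly) and n_per_species < 2:
        raise ValueError("polymorphism requires n_per_species >= 2")
    rng = np.random.default_rng(seed)
    n_codons = sum(counts) + pad_codons
    L = 3 * n_codons
    n_rows = 2 * n_per_species + 1
    matrix = np.tile(np.array(list(_BASE_CODON * n_codons), dtype="U1"),
                     (n_rows, 1))

    rows_a = list(range(n_per_species))
    rows_b = list(range(n_per_species, 2 * n_per_species))
    codon_order = rng.permutation(n_codons - pad_codons)

    def plant(codon_idx: int, derived_codon: str, rows: list[int]) -> None:
        cols = slice(3 * codon_idx, 3 * codon_idx + 3)
        for r in rows:
            matrix[r, cols] = list(derived_codon)

    k = 0
    for j in range(syn_poly):
        rows = [rng.choice(rows_a if j % 2 == 0 else rows_b)]
        plant(codon_order[k], _SYN_DERIVED, rows)
        k += 1
    for j in range(nonsyn_poly):
        rows = [rng.choice(rows_a if j % 2 == 0 else rows_b)]
        plant(codon_order[k], _NONSYN_DERIVED, rows)
        k += 1
    for _ in range(syn_fixed):
        plant(codon_order[k], _SYN_DERIVED, rows_a + rows_b)
        k += 1
    for _ in range(nonsyn_fixed):
        plant(codon_order[k], _NONSYN_DERIVED, rows_a + rows_b)
        k += 1

    labels = ([f"popA_{i}" for i in range(n_per_species)]
              + [f"popB_{i}" for i in range(n_per_species)] + ["out_0"])
    species_of = {lab: lab.split("_")[0] for lab in labels}
    roles = {"popA": INGROUP, "popB": INGROUP, "out": OUTGROUP}
    aln = SampleAlignment(labels=labels, species_of=species_of,
                          matrix=matrix, roles=roles)
    from .seqdata import Segment, EXON
    ann = RegionAnnotation(segments=[Segment(0, L, EXON, 0)], L=L)
    return aln, ann
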