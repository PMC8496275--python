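"""The codon-flux (CF) test for selection on synonymous codon usage.

Fixed synonymous substitutions on a focal lineage are assigned by
two-outgroup parsimony and labeled toward-preferred or toward-unpreferred;
they are compared against the numbers of sites available for each
direction (codons currently preferred are opportunities for unpreferred
change and vice versa) in a 2x2 contingency test, analogous to a dN/dS
comparison but for major-codon usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contingency import chi_square_2x2, fisher_exact_2x2
from .seqdata import SampleAlignment, CodonColumnMap
from .siteclass import (BASES, NONE, NOT_APPLICABLE, PREFERRED,
                        TO_PREFERRED, TO_UNPREFERRED, UNPREFERRED,
                        GENETIC_CODE, PreferenceTable,
                        preference_direction_codons, translate)

NO_PREFERENCE = "No preference"
PREF_FAVORED = "Preferred codons favored"
UNPREF_FAVORED = "Unpreferred codons favored"


@dataclass
class LineageFixation:
    codon_index: int
    column: int
    ancestral_codon: str
    derived_codon: str
    synonymous: bool
    direction: str


@dataclass
class FixationAssignment:
    fixations: list[LineageFixation]
    unassigned: list[tuple[int, str]]  # (column or codon, reason)

    def synonymous_directions(self) -> tuple[int, int]:
        """(toward_unpreferred, toward_preferred) counts."""
        u = sum(1 for f in self.fixations
                if f.synonymous and f.direction == TO_UNPREFERRED)
        p = sum(1 for f in self.fixations
                if f.synonymous and f.direction == TO_PREFERRED)
        return u, p


def assign_lineage_fixations(aln: SampleAlignment, focal_species: str,
                             outgroup_species: list[str],
                             codon_map: CodonColumnMap,
                             pref: PreferenceTable | None = None,
                             code: dict[str, str] | None = None
                             ) -> FixationAssignment:
    """Assign fixed differences to the focal lineage by outgroup parsimony.

    A fixed difference belongs to the focal lineage iff the focal sample is
    fixed for one state and both outgroups share the alternative state;
    disagreeing outgroups leave the change unassigned (logged).  Codons
    differing at more than one position between the focal consensus and
    the shared outgroup state are unassigned (path ambiguity).  Changes
    are labeled synonymous/nonsynonymous and, when a preference table is
    supplied, toward preferred/unpreferred.
    """
    if len(outgroup_species) != 2:
        raise ValueError("two outgroup species required")
    code = code or GENETIC_CODE
    focal = aln.submatrix(focal_species)
    out_subs = [aln.submatrix(sp) for sp in outgroup_species]

    fixations: list[LineageFixation] = []
    unassigned: list[tuple[int, str]] = []

    for ci in range(codon_map.n_codons):
        cols = codon_map.columns_of(ci)
        # focal must be fixed and gap/N-free over the codon
        f_codons = {"".join(row) for row in focal[:, cols]}
        if len(f_codons) != 1:
            continue
        f_codon = next(iter(f_codons))
        if any(ch not in BASES for ch in f_codon):
            continue
        # shared outgroup state per column
        out_state = []
        ok = True
        for col in cols:
            states = set()
            for sub in out_subs:
                obs = {b for b in sub[:, col] if b in BASES}
                if len(obs) != 1:
                    ok = False
                    break
                states |= obs
            if not ok or len(states) != 1:
                ok = False
                break
            out_state.append(next(iter(states)))
        if not ok:
            unassigned.append((ci, "outgroups disagree or lack coverage"))
            continue
        anc_codon = "".join(out_state)
        if anc_codon == f_codon:
            continue
        diffs = [p for p in range(3) if anc_codon[p] != f_codon[p]]
        if len(diffs) > 1:
            unassigned.append((ci, "codon differs at multiple positions"))
            continue
        if translate(anc_codon, code) == "*" or translate(f_codon, code) == "*":
            unassigned.append((ci, "stop codon involved"))
            continue
        syn = translate(anc_codon, code) == translate(f_codon, code)
        direction = NONE
        if syn and pref is not None:
            direction = preference_direction_codons(anc_codon, f_codon, pref)
        fixations.append(LineageFixation(
            codon_index=ci, column=int(cols[diffs[0]]),
            ancestral_codon=anc_codon, derived_codon=f_codon,
            synonymous=syn, direction=direction))
    return FixationAssignment(fixations=fixations, unassigned=unassigned)


def count_cf_sites(consensus_codons: list[str],
                   pref: PreferenceTable) -> tuple[int, int]:
    """Opportunity counts: (unpreferred_sites, preferred_sites).

    A codon currently preferred is a site at which a change toward an
    unpreferred codon could occur; a codon currently unpreferred whose
    family contains a preferred codon is a site for preferred change.
    Not-applicable families (Met, Trp) contribute to neither.
    """
    unpref_sites = pref_sites = 0
    for codon in consensus_codons:
        if any(ch not in BASES for ch in codon):
            continue
        status = pref.of(codon)
        if status == PREFERRED:
            unpref_sites += 1
        elif status == UNPREFERRED and pref.family_has_preferred(codon):
            pref_sites += 1
    return unpref_sites, pref_sites


@dataclass
class CFTable:
    """2x2 codon-flux table: substitutions vs available sites per direction."""

    lineage: str
    unpreferred_subs: int
    preferred_subs: int
    unpreferred_sites: int
    preferred_sites: int
    test_used: str = "chi_square"
    p: float | None = None
    direction_of_departure: str = ""

    def __post_init__(self) -> None:
        for x in (self.unpreferred_subs, self.preferred_subs,
                  self.unpreferred_sites, self.preferred_sites):
            if x < 0:
                raise ValueError("CF cells must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.unpreferred_subs, self.preferred_subs,
                self.unpreferred_sites, self.preferred_sites)

    def to_tsv(self) -> str:
        p = "" if self.p is None else f"{self.p:.3g}"
        return ("\tUnpreferred\tPreferred\tP-value\tDirection\n"
                f"Fixed substitutions\t{self.unpreferred_subs}\t"
                f"{self.preferred_subs}\t\t\n"
                f"Sites\t{self.unpreferred_sites}\t{self.preferred_sites}\t"
                f"{p}\t{self.direction_of_departure}\n")


def cf_test(table: CFTable, method: str = "chi_square") -> CFTable:
    """Run the 2x2 CF comparison and fill in p and departure direction.

    Default is the Pearson chi-square without continuity correction;
    ``method='fisher'`` uses the two-tailed Fisher exact test.  A zero
    margin yields p = 1 and "No preference".  The departure direction
    compares per-site substitution rates and is reported only for p < 0.05.
    """
    a, b, c, d = table.cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        table.p = 1.0
        table.test_used = method
        table.direction_of_departure = NO_PREFERENCE
        return table
    if method == "chi_square":
        _, p = chi_square_2x2(a, b, c, d)
    elif method == "fisher":
        p = fisher_exact_2x2(a, b, c, d)
    else:
        raise ValueError(f"unknown CF test method {method!r}")
    table.p = p
    table.test_used = method
    if p >= 0.05:
        table.direction_of_departure = NO_PREFERENCE
    else:
        rate_unpref = a / c
        rate_pref = b / d
        table.direction_of_departure = (
            PREF_FAVORED if rate_pref > rate_unpref else UNPREF_FAVORED)
    return table


def cf_table_for_lineage(aln: SampleAlignment, focal_species: str,
                         outgroup_species: list[str],
                         codon_map: CodonColumnMap, pref: PreferenceTable,
                         method: str = "chi_square") -> CFTable:
    """Full CF pipeline for one lineage: assign, count sites, test."""
    assignment = assign_lineage_fixations(aln, focal_species,
                                          outgroup_species, codon_map, pref)
    u_subs, p_subs = assignment.synonymous_directions()
    consensus = aln.consensus(focal_species)
    codons = [codon_map.codon_string(consensus, c)
              for c in range(codon_map.n_codons)]
    u_sites, p_sites = count_cf_sites(codons, pref)
    table = CFTable(lineage=focal_species, unpreferred_subs=u_subs,
                    preferred_subs=p_subs, unpreferred_sites=u_sites,
                    preferred_sites=p_sites)
    return cf_test(table, method=method)
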