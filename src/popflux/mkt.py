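"""McDonald-Kreitman tables: site classification, construction, filtering.

A site is polymorphic when any listed species segregates more than one
nucleotide in its population sample; it is fixed divergent when all alleles
of one species differ from all alleles of the other listed species.  A site
that is both counts as polymorphic only.  Cross-tabulating these against
synonymous/nonsynonymous site classes gives the 2x2 MK table, tested with
the Fisher exact test.  The FWW low-frequency filter removes polymorphic
variants below a frequency threshold from the polymorphism cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contingency import fisher_exact_2x2
from .seqdata import SampleAlignment
from .siteclass import (BASES, NONSYNONYMOUS, SYNONYMOUS, PolarizeResult,
                        SiteClassTable)

POLYMORPHIC = "polymorphic"
FIXED_DIVERGENT = "fixed_divergent"
INVARIANT = "invariant"


@dataclass
class SiteMKClass:
    column: int
    status: str                  # polymorphic / fixed_divergent / invariant
    divergent_species: str | None = None


@dataclass
class MKClassification:
    sites: list[SiteMKClass]
    excluded: list[tuple[int, str]] = field(default_factory=list)
    polymorphism_species: tuple[str, ...] = ()
    divergence_description: str = ""

    def of_status(self, status: str) -> list[SiteMKClass]:
        return [s for s in self.sites if s.status == status]


def classify_sites_mk(aln: SampleAlignment,
                      ingroup_species: set[str] | list[str],
                      outgroup_species: set[str] | list[str]
                      ) -> MKClassification:
    """Label every column polymorphic, fixed divergent, or invariant.

    Polymorphism is scored within every listed species' sample (in the
    typical design the outgroups are single sequences, so polymorphism
    effectively comes from the ingroup set); fixed divergence requires the
    allele set of one species (ingroup or outgroup) to be disjoint from
    the union over the remaining species.
    Columns where any species has only gaps/N are excluded and logged.
    """
    ingroup_species = sorted(ingroup_species)
    outgroup_species = sorted(outgroup_species)
    all_species = ingroup_species + list(
        s for s in outgroup_species if s not in ingroup_species)
    rows = {sp: aln.rows_for(sp) for sp in all_species}

    sites: list[SiteMKClass] = []
    excluded: list[tuple[int, str]] = []
    for col in range(aln.L):
        alleles: dict[str, set[str]] = {}
        missing = None
        for sp in all_species:
            colvals = aln.matrix[rows[sp], col]
            obs = {b for b in colvals if b in BASES}
            if not obs:
                missing = sp
                break
            alleles[sp] = obs
        if missing is not None:
            excluded.append((col, f"species {missing} all gap/N"))
            continue

        poly = any(len(alleles[sp]) > 1 for sp in all_species)
        if poly:
            sites.append(SiteMKClass(col, POLYMORPHIC))
            continue
        divergent = None
        for sp in all_species:
            others = set().union(*(alleles[o] for o in all_species
                                   if o != sp))
            if alleles[sp].isdisjoint(others):
                divergent = sp
                break
        if divergent is not None:
            sites.append(SiteMKClass(col, FIXED_DIVERGENT, divergent))
        else:
            sites.append(SiteMKClass(col, INVARIANT))
    return MKClassification(
        sites=sites, excluded=excluded,
        polymorphism_species=tuple(ingroup_species),
        divergence_description=" vs ".join(
            ["+".join(ingroup_species), "+".join(outgroup_species)]),
    )


@dataclass
class MKTable:
    """2x2 McDonald-Kreitman table with counting provenance."""

    syn_poly: int
    nonsyn_poly: int
    syn_fixed: int
    nonsyn_fixed: int
    species_in_polymorphism: tuple[str, ...] = ()
    divergence_lineage: str = ""
    filter_applied: str = "none"

    def __post_init__(self) -> None:
        for x in (self.syn_poly, self.nonsyn_poly,
                  self.syn_fixed, self.nonsyn_fixed):
            if x < 0:
                raise ValueError("MK cells must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.syn_poly, self.nonsyn_poly,
                self.syn_fixed, self.nonsyn_fixed)

    def fisher_p(self, mode: str = "two_tailed") -> float:
        return fisher_exact_2x2(*self.cells, mode=mode)

    def to_tsv(self) -> str:
        lines = ["\tSynonymous\tNonsynonymous\tP-value",
                 f"Polymorphic\t{self.syn_poly}\t{self.nonsyn_poly}\t",
                 (f"Fixed divergent\t{self.syn_fixed}\t{self.nonsyn_fixed}"
                  f"\t{self.fisher_p():.3g}")]
        return "\n".join(lines) + "\n"


def build_mk_table(classification: MKClassification,
                   site_table: SiteClassTable,
                   filter_applied: str = "none") -> MKTable:
    """Cross-tabulate MK site status with synonymous/nonsynonymous class.

    Sites whose column class is neither synonymous nor nonsynonymous
    (introns, invariant exon columns, excluded codons) do not enter the
    table.
    """
    counts = {(POLYMORPHIC, SYNONYMOUS): 0, (POLYMORPHIC, NONSYNONYMOUS): 0,
              (FIXED_DIVERGENT, SYNONYMOUS): 0,
              (FIXED_DIVERGENT, NONSYNONYMOUS): 0}
    for site in classification.sites:
        if site.status == INVARIANT:
            continue
        cls = str(site_table.column_class[site.column])
        if cls not in (SYNONYMOUS, NONSYNONYMOUS):
            continue
        counts[(site.status, cls)] += 1
    return MKTable(
        syn_poly=counts[(POLYMORPHIC, SYNONYMOUS)],
        nonsyn_poly=counts[(POLYMORPHIC, NONSYNONYMOUS)],
        syn_fixed=counts[(FIXED_DIVERGENT, SYNONYMOUS)],
        nonsyn_fixed=counts[(FIXED_DIVERGENT, NONSYNONYMOUS)],
        species_in_polymorphism=classification.polymorphism_species,
        divergence_lineage=classification.divergence_description,
        filter_applied=filter_applied,
    )


def fww_filter(classification: MKClassification,
               polarized: PolarizeResult | None = None,
               minor_freqs: dict[int, float] | None = None,
               min_freq: float = 0.15,
               frequency: str = "derived") -> MKClassification:
    """Remove low-frequency polymorphisms (frequency < min_freq).

    With ``frequency='derived'`` the derived-allele frequency from
    ``polarized`` is used and unpolarized polymorphic sites are excluded
    and logged; with ``frequency='minor'`` a map column -> minor-allele
    frequency is used.  Fixed-divergent sites are never touched.
    """
    if frequency == "derived":
        if polarized is None:
            raise ValueError("derived-frequency mode needs polarized variants")
        freq_of = {v.column: v.derived_freq for v in polarized.variants}
    elif frequency == "minor":
        if minor_freqs is None:
            raise ValueError("minor-frequency mode needs minor_freqs")
        freq_of = dict(minor_freqs)
    else:
        raise ValueError(f"unknown frequency mode {frequency!r}")

    kept: list[SiteMKClass] = []
    excluded = list(classification.excluded)
    for site in classification.sites:
        if site.status != POLYMORPHIC:
            kept.append(site)
            continue
        f = freq_of.get(site.column)
        if f is None:
            excluded.append((site.column,
                             "polymorphic site without frequency "
                             f"({frequency} mode)"))
            continue
        if f < min_freq:
            continue  # filtered out
        kept.append(site)
    return MKClassification(
        sites=kept, excluded=excluded,
        polymorphism_species=classification.polymorphism_species,
        divergence_description=classification.divergence_description,
    )
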