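"""Site classification, Nei-Gojobori site counting, polarization, codon preference.

Columns of an in-frame alignment are labeled synonymous / nonsynonymous /
intron / excluded; per-codon fractional site counts give the effective
lengths used for per-site rates; outgroup comparison polarizes each
biallelic variant into ancestral and derived states; a codon-preference
table classifies synonymous changes as toward preferred or unpreferred
codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Data import CodonTable

from .seqdata import SampleAlignment, CodonColumnMap, AlignmentError

# Standard genetic code, stops included as '*'.
_STD = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    GENETIC_CODE[_stop] = "*"

BASES = ("A", "C", "G", "T")

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
INTRON = "intron"
EXCLUDED = "excluded"
INVARIANT = "invariant"

TO_PREFERRED = "to_preferred"
TO_UNPREFERRED = "to_unpreferred"
NONE = "none"


def translate(codon: str, code: dict[str, str] | None = None) -> str:
    code = code or GENETIC_CODE
    try:
        return code[codon]
    except KeyError:
        raise AlignmentError(f"cannot translate codon {codon!r}") from None


# ---------------------------------------------------------------------------
# Nei-Gojobori fractional site counting
# ---------------------------------------------------------------------------

def count_sites(codon: str,
                code: dict[str, str] | None = None) -> tuple[float, float]:
    """Nei-Gojobori (equal-weight) synonymous/nonsynonymous site counts.

    Each codon position contributes the fraction of its three possible
    single-base changes that are synonymous; mutations to stop codons count
    as nonsynonymous, so the two counts always sum to 3.  Raises for stop
    codons (callers exclude and log them).
    """
    code = code or GENETIC_CODE
    aa = translate(codon, code)
    if aa == "*":
        raise AlignmentError(f"stop codon {codon!r} has no site counts")
    syn = 0.0
    for pos in range(3):
        s = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if code[mutant] == aa:
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


def count_sites_sequence(codons: list[str],
                         code: dict[str, str] | None = None
                         ) -> tuple[float, float]:
    """Total fractional site counts over a gap-free codon sequence."""
    syn = nonsyn = 0.0
    for c in codons:
        s, n = count_sites(c, code)
        syn += s
        nonsyn += n
    return syn, nonsyn


# ---------------------------------------------------------------------------
# Column classification
# ---------------------------------------------------------------------------

@dataclass
class SiteClassTable:
    """Per-column class labels plus per-codon fractional site counts.

    ``column_class`` holds one of synonymous/nonsynonymous/intron/excluded
    for variable or non-coding columns and ``invariant`` for monomorphic
    exon columns (which enter effective lengths through the fractional
    counts but carry no variants).
    """

    column_class: np.ndarray
    syn_sites: np.ndarray      # per codon, NaN when codon excluded
    nonsyn_sites: np.ndarray   # per codon, NaN when codon excluded
    intron_effective: int
    log: list[str] = field(default_factory=list)

    def columns_in_class(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.column_class == cls)

    def effective_length(self, cls: str) -> float:
        if cls == SYNONYMOUS:
            return float(np.nansum(self.syn_sites))
        if cls == NONSYNONYMOUS:
            return float(np.nansum(self.nonsyn_sites))
        if cls == INTRON:
            return float(self.intron_effective)
        raise ValueError(f"no effective length for class {cls!r}")


def _codon_rows(matrix: np.ndarray, cols: np.ndarray) -> list[str]:
    """Codon strings for every row; rows with N are dropped, any '-' keeps
    the gap marker so callers can exclude the codon."""
    out = []
    for row in matrix[:, cols]:
        out.append("".join(row))
    return out


def classify_columns(aln: SampleAlignment, codon_map: CodonColumnMap,
                     species: list[str] | None = None,
                     code: dict[str, str] | None = None) -> SiteClassTable:
    """Label every alignment column and compute fractional codon sites.

    A variable exon column is synonymous iff all observed codon variants at
    its codon (holding the other two positions at their observed context)
    encode the same amino acid; codons segregating at more than one
    position, with mixed synonymous/nonsynonymous effects, or containing a
    stop or gap in any analyzed row are excluded and logged.  Unmapped
    columns are intron.  Deterministic and independent of row order.
    """
    code = code or GENETIC_CODE
    if species is None:
        rows = np.arange(aln.n)
    else:
        rows = np.concatenate([aln.rows_for(sp) for sp in species])
    mat = aln.matrix[rows]

    L = aln.L
    column_class = np.empty(L, dtype=object)
    n_codons = codon_map.n_codons
    syn_sites = np.full(n_codons, np.nan)
    nonsyn_sites = np.full(n_codons, np.nan)
    log: list[str] = []

    unmapped = np.flatnonzero(codon_map.codon_index < 0)
    column_class[unmapped] = INTRON
    # intron effective length: columns with complete data in analyzed rows
    intron_eff = 0
    for col in unmapped:
        if np.all(np.isin(mat[:, col], BASES)):
            intron_eff += 1

    for c in range(n_codons):
        cols = codon_map.columns_of(c)
        codons = _codon_rows(mat, cols)
        if any("-" in cd for cd in codons):
            column_class[cols] = EXCLUDED
            log.append(f"codon {c}: gap in an analyzed row; excluded")
            continue
        clean = [cd for cd in codons if "N" not in cd]
        if not clean:
            column_class[cols] = EXCLUDED
            log.append(f"codon {c}: no gap/N-free codons; excluded")
            continue
        if any(translate(cd, code) == "*" for cd in set(clean)):
            column_class[cols] = EXCLUDED
            log.append(f"codon {c}: stop codon observed; excluded (warning)")
            continue
        # fractional sites averaged over analyzed rows
        fr = [count_sites(cd, code) for cd in clean]
        syn_sites[c] = float(np.mean([f[0] for f in fr]))
        nonsyn_sites[c] = float(np.mean([f[1] for f in fr]))

        variable = [p for p in range(len(cols))
                    if len({cd[p] for cd in clean}) > 1]
        column_class[cols] = INVARIANT
        if not variable:
            continue
        if len(variable) > 1:
            for p in variable:
                column_class[cols[p]] = EXCLUDED
            log.append(f"codon {c}: segregating at {len(variable)} positions; "
                       "variable columns excluded")
            continue
        p = variable[0]
        aas = {translate(cd, code) for cd in set(clean)}
        n_alleles = len({cd[p] for cd in clean})
        if len(aas) == 1:
            column_class[cols[p]] = SYNONYMOUS
        elif len(aas) == n_alleles:
            column_class[cols[p]] = NONSYNONYMOUS
        else:
            column_class[cols[p]] = EXCLUDED
            log.append(f"codon {c}: mixed synonymous/nonsynonymous effects "
                       "at one position; column excluded")

    return SiteClassTable(column_class=column_class.astype("U13"),
                          syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
                          intron_effective=intron_eff, log=log)


# ---------------------------------------------------------------------------
# Codon preference tables
# ---------------------------------------------------------------------------

PREFERRED = "preferred"
UNPREFERRED = "unpreferred"
NOT_APPLICABLE = "not_applicable"


@dataclass
class PreferenceTable:
    """Codon -> preferred/unpreferred/not_applicable, tagged with a species.

    Single-codon families (Met, Trp) are not_applicable; every other
    family must contain at least one preferred codon.
    """

    status: dict[str, str]
    species: str = "unspecified"
    code: dict[str, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.code is None:
            self.code = GENETIC_CODE
        sense = [c for c, aa in self.code.items() if aa != "*"]
        missing = [c for c in sense if c not in self.status]
        if missing:
            raise AlignmentError(f"preference table misses codons {missing}")
        fam: dict[str, list[str]] = {}
        for c in sense:
            fam.setdefault(self.code[c], []).append(c)
        for aa, codons in fam.items():
            stats = {self.status[c] for c in codons}
            if len(codons) == 1:
                if stats != {NOT_APPLICABLE}:
                    raise AlignmentError(
                        f"single-codon family {aa} must be not_applicable")
            elif NOT_APPLICABLE not in stats and PREFERRED not in stats:
                raise AlignmentError(
                    f"family {aa} has no preferred codon")

    def of(self, codon: str) -> str:
        return self.status[codon]

    def is_preferred(self, codon: str) -> bool:
        return self.status.get(codon) == PREFERRED

    def family_has_preferred(self, codon: str) -> bool:
        aa = self.code[codon]
        return any(self.status.get(c) == PREFERRED
                   for c, a in self.code.items() if a == aa)

    @classmethod
    def from_tsv(cls, path, species: str = "unspecified") -> "PreferenceTable":
        """TSV columns: codon, amino_acid, status."""
        status = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("codon"):
                    continue
                codon, _aa, st = line.split("\t")[:3]
                status[codon.upper()] = st
        return cls(status=status, species=species)

    @classmethod
    def drosophila_default(cls) -> "PreferenceTable":
        """Major-codon preference table for D. melanogaster (C/G-ending
        major codons from codon-usage surveys of highly expressed genes)."""
        path = resources.files("popflux") / "data" / "dmel_preference.tsv"
        return cls.from_tsv(str(path), species="D. melanogaster")


def preference_direction_codons(anc_codon: str, der_codon: str,
                                pref: PreferenceTable) -> str:
    """Direction of a synonymous ancestral->derived codon change."""
    a, d = pref.of(anc_codon), pref.of(der_codon)
    if NOT_APPLICABLE in (a, d) or a == d:
        return NONE
    if d == PREFERRED:
        return TO_PREFERRED
    return TO_UNPREFERRED


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

@dataclass
class PolarizedVariant:
    """A biallelic ingroup variant with outgroup-inferred ancestral state."""

    column: int
    ancestral: str
    derived: str
    derived_count: int
    n: int
    site_class: str = ""
    direction: str = NONE
    anc_codon: str | None = None
    der_codon: str | None = None

    @property
    def derived_freq(self) -> float:
        return self.derived_count / self.n


@dataclass
class PolarizeResult:
    variants: list[PolarizedVariant]
    unpolarized: list[tuple[int, str]]  # (column, reason)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self):
        return len(self.variants)

    def sfs(self, n: int) -> np.ndarray:
        """Derived-allele (unfolded) site-frequency spectrum, length n+1."""
        out = np.zeros(n + 1, dtype=int)
        for v in self.variants:
            out[v.derived_count] += 1
        return out


def preference_direction(variant: PolarizedVariant,
                         pref: PreferenceTable) -> str:
    """Preference direction for an already-polarized synonymous variant."""
    if variant.site_class != SYNONYMOUS or variant.anc_codon is None:
        return NONE
    return preference_direction_codons(variant.anc_codon, variant.der_codon,
                                       pref)


def polarize(aln: SampleAlignment, outgroup_species: list[str],
             focal_species: str | None = None,
             site_table: SiteClassTable | None = None,
             codon_map: CodonColumnMap | None = None,
             pref: PreferenceTable | None = None,
             require_all_outgroups: bool = True) -> PolarizeResult:
    """Polarize every biallelic focal-population variant against outgroups.

    The ancestral state is the outgroup state when all covering outgroup
    sequences are unanimous and that state matches one ingroup allele;
    variants failing this (or with a third outgroup state, or no outgroup
    coverage) are flagged unpolarized and excluded.  Columns with missing
    data inside the focal sample are dropped listwise.
    """
    if focal_species is None:
        ingroups = aln.ingroup_species()
        if len(ingroups) != 1:
            raise AlignmentError(
                "focal_species required when more than one ingroup present")
        focal_species = ingroups[0]
    focal = aln.submatrix(focal_species)
    out_rows = np.concatenate([aln.rows_for(sp) for sp in outgroup_species])
    outmat = aln.matrix[out_rows]
    n = focal.shape[0]

    consensus = aln.consensus(focal_species) if codon_map is not None else None

    variants: list[PolarizedVariant] = []
    unpolarized: list[tuple[int, str]] = []
    for col in range(aln.L):
        fcol = focal[:, col]
        if not np.all(np.isin(fcol, BASES)):
            continue  # listwise deletion within the population sample
        alleles, counts = np.unique(fcol, return_counts=True)
        if alleles.size < 2:
            continue
        if alleles.size > 2:
            unpolarized.append((col, "more than two ingroup alleles"))
            continue
        ocol = outmat[:, col]
        obases = ocol[np.isin(ocol, BASES)]
        if obases.size == 0:
            unpolarized.append((col, "no outgroup coverage"))
            continue
        ostates = set(obases)
        if len(ostates) > 1:
            unpolarized.append((col, "outgroups not unanimous"))
            continue
        if require_all_outgroups and obases.size < len(out_rows):
            unpolarized.append((col, "outgroup partially missing"))
            continue
        anc = obases[0]
        if anc not in alleles:
            unpolarized.append((col, "outgroup state matches neither allele"))
            continue
        derived = alleles[alleles != anc][0]
        i = int(counts[alleles == derived][0])
        v = PolarizedVariant(column=col, ancestral=str(anc),
                             derived=str(derived), derived_count=i, n=n)
        if site_table is not None:
            v.site_class = str(site_table.column_class[col])
        if codon_map is not None and codon_map.codon_index[col] >= 0:
            cols = codon_map.columns_of(codon_map.codon_index[col])
            ctx = consensus[cols].copy()
            pos = int(np.flatnonzero(cols == col)[0])
            ctx[pos] = anc
            v.anc_codon = "".join(ctx)
            ctx[pos] = derived
            v.der_codon = "".join(ctx)
            if pref is not None and v.site_class == SYNONYMOUS:
                v.direction = preference_direction_codons(
                    v.anc_codon, v.der_codon, pref)
        variants.append(v)
    return PolarizeResult(variants=variants, unpolarized=unpolarized)
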