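"""Alignment containers, frame validation, and codon coordinate maps.

Everything downstream (site classification, summary statistics, MK and
codon-flux tables, parsimony maps) counts events on the coordinate system
defined here: a multi-species nucleotide alignment with exon/intron
annotation and a column -> codon map.  Coordinates are 0-based, half-open
internally; human-facing reports render 1-based inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

VALID_CHARS = frozenset("ACGTN-")

INGROUP = "ingroup_population"
OUTGROUP = "outgroup"


class AlignmentError(ValueError):
    """Raised for malformed alignments or annotations."""


@dataclass
class SampleAlignment:
    """A multi-sample, multi-species nucleotide alignment.

    Parameters
    ----------
    labels
        Sample identifiers, one per row, in file order.
    species_of
        Map from sample label to species name; must cover every label.
    matrix
        ``(n, L)`` array of single characters from ``{A,C,G,T,N,-}``.
    roles
        Map from species name to ``"ingroup_population"`` or ``"outgroup"``.
    """

    labels: list[str]
    species_of: dict[str, str]
    matrix: np.ndarray
    roles: dict[str, str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.labels) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.labels)} labels for {self.matrix.shape[0]} rows"
            )
        missing = [lab for lab in self.labels if lab not in self.species_of]
        if missing:
            raise AlignmentError(f"labels without species assignment: {missing}")
        bad = set(np.unique(self.matrix)) - VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid alignment characters: {sorted(bad)}")
        for sp in set(self.species_of[lab] for lab in self.labels):
            if sp not in self.roles:
                raise AlignmentError(f"species {sp!r} has no assigned role")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def rows_for(self, species: str) -> np.ndarray:
        """Row indices belonging to one species, in file order."""
        idx = [i for i, lab in enumerate(self.labels)
               if self.species_of[lab] == species]
        if not idx:
            raise AlignmentError(f"no rows for species {species!r}")
        return np.asarray(idx, dtype=int)

    def species(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            sp = self.species_of[lab]
            if sp not in seen:
                seen.append(sp)
        return seen

    def ingroup_species(self) -> list[str]:
        return [s for s in self.species() if self.roles.get(s) == INGROUP]

    def outgroup_species(self) -> list[str]:
        return [s for s in self.species() if self.roles.get(s) == OUTGROUP]

    def submatrix(self, species: str) -> np.ndarray:
        return self.matrix[self.rows_for(species)]

    def consensus(self, species: str) -> np.ndarray:
        """Majority base per column for one species (ties broken A<C<G<T;
        gap/N ignored unless a column is all gap/N, which yields 'N')."""
        sub = self.submatrix(species)
        out = np.full(self.L, "N", dtype="U1")
        for j in range(self.L):
            col = sub[:, j]
            bases, counts = np.unique(col[np.isin(col, list("ACGT"))],
                                      return_counts=True)
            if bases.size:
                out[j] = bases[np.argmax(counts)]
        return out

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels):
                fh.write(f">{lab}\n{''.join(self.matrix[i])}\n")


def read_alignment(fasta_path, species_map: dict[str, str],
                   roles: dict[str, str]) -> SampleAlignment:
    """Read a FASTA alignment into a validated :class:`SampleAlignment`.

    Row order follows the file.  Lowercase bases are upcased.  A ragged
    alignment or a character outside ``{A,C,G,T,N,-}`` is a hard error
    naming the offending record/column.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        ref = len(records[0].seq)
        for r in records:
            if len(r.seq) != ref:
                raise AlignmentError(
                    f"record {r.id!r} has length {len(r.seq)}, expected {ref}"
                )
    labels = []
    rows = []
    for r in records:
        if r.id not in species_map:
            raise AlignmentError(f"record {r.id!r} missing from species_map")
        seq = str(r.seq).upper()
        for j, ch in enumerate(seq):
            if ch not in VALID_CHARS:
                raise AlignmentError(
                    f"record {r.id!r}: invalid character {ch!r} at column {j}"
                )
        labels.append(r.id)
        rows.append(list(seq))
    matrix = np.asarray(rows, dtype="U1")
    return SampleAlignment(labels=labels, species_of=dict(species_map),
                           matrix=matrix, roles=dict(roles))


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

EXON = "exon"
INTRON = "intron"


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    kind: str
    phase: int = 0  # position-in-codon of the segment's first column (exons)


@dataclass
class RegionAnnotation:
    """Ordered, non-overlapping exon/intron segments over ``[0, L)``.

    ``phase`` on an exon is the position-in-codon (0/1/2) of its first
    column and must chain consistently across successive exons.
    """

    segments: list[Segment]
    L: int | None = None

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        prev_end = 0
        for s in segs:
            if s.kind not in (EXON, INTRON):
                raise AlignmentError(f"unknown segment kind {s.kind!r}")
            if s.start < prev_end or s.start >= s.end:
                raise AlignmentError(
                    f"segments must be sorted and non-overlapping: {s}"
                )
            if s.kind == EXON and s.phase not in (0, 1, 2):
                raise AlignmentError(f"exon phase must be 0/1/2: {s}")
            prev_end = s.end
        if self.L is not None and prev_end > self.L:
            raise AlignmentError("annotation extends beyond alignment length")
        self.segments = segs

    def exons(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == EXON]

    def introns(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == INTRON]

    def exon_columns(self) -> np.ndarray:
        cols = [np.arange(s.start, s.end) for s in self.exons()]
        return np.concatenate(cols) if cols else np.empty(0, dtype=int)

    def intron_columns(self) -> np.ndarray:
        cols = [np.arange(s.start, s.end) for s in self.introns()]
        return np.concatenate(cols) if cols else np.empty(0, dtype=int)

    @classmethod
    def from_tsv(cls, path, L: int | None = None) -> "RegionAnnotation":
        """BED-like TSV: columns start, end, kind[, phase]; 0-based half-open."""
        segs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                start, end, kind = int(parts[0]), int(parts[1]), parts[2]
                phase = int(parts[3]) if len(parts) > 3 and parts[3] else 0
                segs.append(Segment(start, end, kind, phase))
        return cls(segments=segs, L=L)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#start\tend\tkind\tphase\n")
            for s in self.segments:
                fh.write(f"{s.start}\t{s.end}\t{s.kind}\t{s.phase}\n")


# ---------------------------------------------------------------------------
# Frame validation
# ---------------------------------------------------------------------------

@dataclass
class IndelRecord:
    label: str
    exon_offset: int       # offset within concatenated exon columns
    columns: tuple[int, int]  # alignment-column range, half-open
    length: int

    @property
    def in_frame(self) -> bool:
        return self.length % 3 == 0

    def human(self) -> str:
        lo, hi = self.columns
        status = "in-frame" if self.in_frame else "FRAME-BREAKING"
        return (f"{self.label}: exonic gap of {self.length} at columns "
                f"{lo + 1}..{hi} ({status})")


@dataclass
class ValidationReport:
    """Per-sequence exonic gap-run audit.

    Passes iff every exonic gap run in every sequence has a length that is
    a multiple of three (indels add or remove whole codons).
    """

    indels: list[IndelRecord] = field(default_factory=list)
    length_issues: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return (not self.length_issues
                and all(r.in_frame for r in self.indels))

    def violations(self) -> list[IndelRecord]:
        return [r for r in self.indels if not r.in_frame]

    def to_json(self) -> str:
        return json.dumps({
            "passed": self.passed,
            "indels": [
                {"label": r.label, "columns": list(r.columns),
                 "length": r.length, "in_frame": r.in_frame}
                for r in self.indels
            ],
            "length_issues": self.length_issues,
        }, indent=2)


def validate_frame(aln: SampleAlignment,
                   ann: RegionAnnotation) -> ValidationReport:
    """Check that coding-region gaps keep every sequence in frame.

    For each row, gap runs restricted to exon columns are located; any run
    whose length is not a multiple of 3 fails the report.  The ungapped
    exon length of each row must also be a multiple of 3.  Diagnostic:
    never raises for content problems.
    """
    exon_cols = ann.exon_columns()
    report = ValidationReport()
    for i, lab in enumerate(aln.labels):
        row = aln.matrix[i, exon_cols]
        ungapped = int(np.sum(row != "-"))
        if ungapped % 3 != 0:
            report.length_issues.append(
                f"{lab}: ungapped exon length {ungapped} is not a multiple of 3"
            )
        # locate gap runs in concatenated-exon coordinates
        j = 0
        while j < row.size:
            if row[j] == "-":
                k = j
                while k < row.size and row[k] == "-":
                    k += 1
                report.indels.append(IndelRecord(
                    label=lab, exon_offset=j,
                    columns=(int(exon_cols[j]), int(exon_cols[k - 1]) + 1),
                    length=k - j,
                ))
                j = k
            else:
                j += 1
    return report


# ---------------------------------------------------------------------------
# Codon column map
# ---------------------------------------------------------------------------

@dataclass
class CodonColumnMap:
    """Map alignment columns to codon indices and positions-in-codon.

    ``codon_index[c] == -1`` and ``codon_pos[c] == -1`` for intron /
    unannotated columns.  Codon indices are contiguous over concatenated
    exons; a codon may span a splice boundary.
    """

    codon_index: np.ndarray
    codon_pos: np.ndarray

    @property
    def n_codons(self) -> int:
        mapped = self.codon_index[self.codon_index >= 0]
        return int(mapped.max()) + 1 if mapped.size else 0

    def columns_of(self, codon: int) -> np.ndarray:
        return np.flatnonzero(self.codon_index == codon)

    def mapped_columns(self) -> np.ndarray:
        return np.flatnonzero(self.codon_index >= 0)

    def codon_string(self, row: np.ndarray, codon: int) -> str:
        return "".join(row[self.columns_of(codon)])


def build_codon_map(ann: RegionAnnotation, L: int) -> CodonColumnMap:
    """Assign codon index / position-in-codon to every exon column.

    The first exon's phase gives the position-in-codon of its first column;
    phases of later exons must chain with the cumulative exon length, else
    a frame inconsistency error is raised.
    """
    codon_index = np.full(L, -1, dtype=int)
    codon_pos = np.full(L, -1, dtype=int)
    exons = ann.exons()
    if not exons:
        return CodonColumnMap(codon_index, codon_pos)
    offset = exons[0].phase  # columns already consumed of codon 0
    cum = 0
    for s in exons:
        expected_phase = (offset + cum) % 3
        if s.phase != expected_phase:
            raise AlignmentError(
                f"exon at {s.start}: declared phase {s.phase} but chain "
                f"gives {expected_phase}"
            )
        for col in range(s.start, s.end):
            k = offset + cum
            codon_index[col] = k // 3
            codon_pos[col] = k % 3
            cum += 1
    return CodonColumnMap(codon_index, codon_pos)
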