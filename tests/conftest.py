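import numpy as np
import pytest

from popflux.seqdata import (EXON, INGROUP, OUTGROUP, RegionAnnotation,
                             SampleAlignment, Segment)
from popflux.siteclass import PreferenceTable


def alignment_from_rows(rows, species_of, roles):
    """Build a SampleAlignment from {label: sequence-string} pairs."""
    labels = list(rows)
    matrix = np.asarray([list(rows[lab]) for lab in labels], dtype="U1")
    return SampleAlignment(labels=labels, species_of=species_of,
                           matrix=matrix, roles=roles)


def population_alignment(seqs_by_species, roles=None):
    """Alignment where seqs_by_species maps species -> list of sequences."""
    rows, species_of = {}, {}
    default_roles = {}
    for sp, seqs in seqs_by_species.items():
        for i, s in enumerate(seqs):
            lab = f"{sp}_{i}"
            rows[lab] = s
            species_of[lab] = sp
        default_roles[sp] = INGROUP
    if roles is None:
        roles = default_roles
    return alignment_from_rows(rows, species_of, roles)


@pytest.fixture
def coding_annotation():
    def make(L):
        return RegionAnnotation(segments=[Segment(0, L, EXON, 0)], L=L)
    return make


@pytest.fixture(scope="session")
def dmel_pref():
    return PreferenceTable.drosophila_default()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
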