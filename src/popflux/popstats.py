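"""Classical summary statistics of polymorphism and divergence.

Watterson's theta, nucleotide diversity pi, uncorrected divergence,
singleton counts, Tajima's D, and Fay & Wu's H (unnormalized), computed per
site class on an annotated alignment.  All statistics use listwise
deletion: a column with a gap or N in any row of the population sample is
dropped from S, pi and the SFS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqdata import SampleAlignment
from .siteclass import (BASES, INTRON, NONSYNONYMOUS, SYNONYMOUS,
                        SiteClassTable, PolarizeResult)


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (power=1) or b_n with 1/i^2 (power=2)."""
    return float(sum(1.0 / i ** power for i in range(1, n)))


def watterson_theta(S: int, n: int, L_effective: float) -> float:
    """Watterson's theta per site: S / (a_n * L_effective)."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2")
    if L_effective <= 0:
        raise ValueError("L_effective must be positive")
    if S == 0:
        return 0.0
    return S / (harmonic(n) * L_effective)


def _complete_columns(sub: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Columns (subset of cols) where every row is a plain base."""
    keep = [c for c in cols if np.all(np.isin(sub[:, c], BASES))]
    return np.asarray(keep, dtype=int)


def pi(aln: SampleAlignment, species: str,
       columns: np.ndarray | None = None,
       L_effective: float | None = None) -> tuple[float, float]:
    """Nucleotide diversity: (pi_per_site, pi_total).

    Average number of pairwise differences over all C(n,2) sequence pairs,
    restricted to ``columns`` (default: all), using only columns complete
    within the species sample.  ``pi_per_site`` divides by ``L_effective``
    (default: the number of complete columns used).
    """
    sub = aln.submatrix(species)
    n = sub.shape[0]
    if n < 2:
        raise ValueError("pi requires n >= 2")
    if columns is None:
        columns = np.arange(aln.L)
    cols = _complete_columns(sub, columns)
    if cols.size == 0:
        return 0.0, 0.0
    total = 0.0
    npairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(sub[i, cols] != sub[j, cols]))
    pi_total = total / npairs
    L = L_effective if L_effective is not None else float(cols.size)
    return pi_total / L, pi_total


def segregating_sites(aln: SampleAlignment, species: str,
                      columns: np.ndarray | None = None) -> int:
    """Number of segregating (complete, >1 allele) sites in the sample."""
    sub = aln.submatrix(species)
    if columns is None:
        columns = np.arange(aln.L)
    cols = _complete_columns(sub, columns)
    S = 0
    for c in cols:
        if np.unique(sub[:, c]).size > 1:
            S += 1
    return S


def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n)
    a2 = harmonic(n, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi_total: float, n: int) -> float | None:
    """Tajima's D: (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Returns None when S == 0 (the statistic is undefined).
    """
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2")
    if S == 0:
        return None
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return None
    return (pi_total - S / k["a1"]) / math.sqrt(var)


def theta_pi_from_sfs(sfs: np.ndarray, n: int) -> float:
    """pi computed from the unfolded SFS (identical to pairwise pi)."""
    i = np.arange(1, n)
    return float(np.sum(sfs[1:n] * 2.0 * i * (n - i)) / (n * (n - 1)))


def theta_h_from_sfs(sfs: np.ndarray, n: int) -> float:
    i = np.arange(1, n)
    return float(np.sum(sfs[1:n] * 2.0 * i * i) / (n * (n - 1)))


def fay_wu_h(sfs: np.ndarray | PolarizeResult, n: int) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H from a polarized SFS.

    ``sfs[i]`` is the number of variants with derived-allele count i;
    entries at i=0 or i=n would indicate unpolarized or fixed input and
    are rejected.
    """
    if isinstance(sfs, PolarizeResult):
        sfs = sfs.sfs(n)
    sfs = np.asarray(sfs)
    if sfs.size < n + 1:
        padded = np.zeros(n + 1, dtype=sfs.dtype)
        padded[:sfs.size] = sfs
        sfs = padded
    if sfs[0] != 0 or sfs[n] != 0:
        raise ValueError("SFS contains entries at i=0 or i=n; "
                         "polarize and filter fixed differences first")
    return theta_pi_from_sfs(sfs, n) - theta_h_from_sfs(sfs, n)


def divergence(aln: SampleAlignment, species_a: str, species_b: str,
               columns: np.ndarray | None = None,
               L_effective: float | None = None) -> float:
    """Mean uncorrected inter-species divergence per effective site.

    Averages the proportion of differing sites over all between-species
    sequence pairs at the given columns; no multiple-hit correction.
    """
    sub_a = aln.submatrix(species_a)
    sub_b = aln.submatrix(species_b)
    if columns is None:
        columns = np.arange(aln.L)
    both = np.vstack([sub_a, sub_b])
    cols = _complete_columns(both, columns)
    if cols.size == 0:
        raise ValueError("no comparable sites between "
                         f"{species_a!r} and {species_b!r}")
    L = L_effective if L_effective is not None else float(cols.size)
    total = 0.0
    for ra in sub_a:
        for rb in sub_b:
            total += int(np.sum(ra[cols] != rb[cols]))
    return total / (sub_a.shape[0] * sub_b.shape[0]) / L


def singleton_fraction(minor_counts: list[int] | np.ndarray
                       ) -> tuple[int, float | None]:
    """Count and fraction of variants whose minor-allele count is 1.

    Accepts a list of per-variant minor (folded) allele counts; the
    fraction is None when there are no variants.
    """
    counts = np.asarray(minor_counts, dtype=int)
    S = counts.size
    singles = int(np.sum(counts == 1))
    return singles, (singles / S if S else None)


def minor_counts(aln: SampleAlignment, species: str,
                 columns: np.ndarray | None = None) -> list[int]:
    """Folded minor-allele counts at every segregating complete site."""
    sub = aln.submatrix(species)
    if columns is None:
        columns = np.arange(aln.L)
    cols = _complete_columns(sub, columns)
    out = []
    for c in cols:
        _, cnt = np.unique(sub[:, c], return_counts=True)
        if cnt.size > 1:
            out.append(int(np.sort(cnt)[:-1].sum()))
    return out


# ---------------------------------------------------------------------------
# Per-class summary
# ---------------------------------------------------------------------------

@dataclass
class ClassSummary:
    site_class: str
    S: int
    singletons: int
    theta_w_per_site: float
    pi_per_site: float
    divergence_per_site: float | None
    L_effective: float


@dataclass
class SummaryStatistics:
    """Per-site-class diversity/divergence plus whole-region SFS tests."""

    species: str
    n: int
    classes: dict[str, ClassSummary]
    tajima_D: float | None
    fay_wu_H: float | None
    notes: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        rows = []
        for cls, cs in self.classes.items():
            rows.append({"class": cls, "S": cs.S, "singletons": cs.singletons,
                         "theta": cs.theta_w_per_site, "pi": cs.pi_per_site,
                         "div": cs.divergence_per_site,
                         "L_eff": cs.L_effective})
        return pd.DataFrame(rows).set_index("class")


def summarize(aln: SampleAlignment, site_table: SiteClassTable,
              species: str, divergence_to: str | None = None,
              div_site_table: SiteClassTable | None = None,
              polarized: PolarizeResult | None = None) -> SummaryStatistics:
    """Compute the per-class summary table for one population sample.

    Synonymous and nonsynonymous rates use fractional (Nei-Gojobori)
    effective lengths; intron rates use intact intron columns.  Divergence
    uses ``div_site_table`` (a classification over both species; defaults
    to ``site_table``).  Tajima's D uses all complete sites; Fay & Wu's H
    additionally needs polarized variants.
    """
    sub = aln.submatrix(species)
    n = sub.shape[0]
    classes = {}
    if div_site_table is None:
        div_site_table = site_table
    # variable columns of each class drive S; invariant exon columns are
    # shared context, the fractional lengths apportion them
    for cls in (SYNONYMOUS, NONSYNONYMOUS, INTRON):
        var_cols = site_table.columns_in_class(cls)
        L_eff = site_table.effective_length(cls)
        S = segregating_sites(aln, species, var_cols)
        singles, _ = singleton_fraction(minor_counts(aln, species, var_cols))
        _, pi_tot = pi(aln, species, var_cols)
        theta = watterson_theta(S, n, L_eff) if L_eff > 0 else 0.0
        pi_site = pi_tot / L_eff if L_eff > 0 else 0.0
        div = None
        if divergence_to is not None:
            dL = div_site_table.effective_length(cls)
            if dL > 0:
                div = divergence(aln, species, divergence_to,
                                 div_site_table.columns_in_class(cls),
                                 L_effective=dL)
        classes[cls] = ClassSummary(cls, S, singles, theta, pi_site, div,
                                    L_eff)

    all_cols = np.arange(aln.L)
    S_all = segregating_sites(aln, species, all_cols)
    _, pi_all = pi(aln, species, all_cols)
    D = tajimas_d(S_all, pi_all, n)
    H = fay_wu_h(polarized, n) if polarized is not None else None
    return SummaryStatistics(species=species, n=n, classes=classes,
                             tajima_D=D, fay_wu_H=H)
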