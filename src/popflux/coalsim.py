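"""Exact back-in-time coalescent simulation with recombination and demography.

A Hudson-style ancestral-recombination-graph simulator for a neutral locus:
lineages carry intervals of ancestral material over [0, 1); coalescence
occurs at rate k(k-1)/2 rescaled by a piecewise-exponential population-size
history; recombination splits a lineage at rate (R/2) times its breakable
span; infinite-sites mutations fall as a Poisson process of rate
theta_locus/2 per lineage per unit ancestral span.  Each mutation records
the set of sampled sequences carrying the derived allele, so the polarized
site-frequency spectrum, haplotypes and all downstream statistics are exact
functions of the realized genealogy.

Time is measured in units of 2*N0 generations; theta = 4*N0*mu*L and
R = 4*N0*r*L (3*N0 scaling for X linkage is applied upstream via
:func:`effective_R`).

Empirical p-values against simulated null distributions follow the
inclusive-tail convention, and Bonferroni adjustment divides the family
alpha by the number of tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .popstats import harmonic, tajimas_d, fay_wu_h, theta_pi_from_sfs

EQUILIBRIUM = "equilibrium"
EXPONENTIAL_GROWTH = "exponential_growth"
THREE_EPOCH_BOTTLENECK = "three_epoch_bottleneck"


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    start: float        # epoch start, coalescent time units, backward
    size: float         # relative population size at epoch start
    growth_rate: float  # exponential rate within epoch (backward shrink)


@dataclass
class DemographicModel:
    """Piecewise-exponential population-size history (backward in time).

    Within an epoch starting at ``t0`` with relative size ``s`` and growth
    rate ``g``, the size at time ``t`` is ``s * exp(-g * (t - t0))`` so the
    pairwise coalescence rate is ``exp(g*(t-t0)) / s``.
    """

    kind: str
    epochs: list[Epoch]

    def __post_init__(self) -> None:
        if not self.epochs or self.epochs[0].start != 0.0:
            raise ValueError("first epoch must start at time 0")
        prev = -1.0
        for e in self.epochs:
            if e.start <= prev:
                raise ValueError("epoch start times must strictly increase")
            if e.size <= 0:
                raise ValueError("relative sizes must be positive")
            prev = e.start

    @classmethod
    def equilibrium(cls) -> "DemographicModel":
        return cls(EQUILIBRIUM, [Epoch(0.0, 1.0, 0.0)])

    @classmethod
    def exponential_growth(cls, growth_rate: float) -> "DemographicModel":
        """Present size 1, shrinking backward at ``growth_rate``."""
        return cls(EXPONENTIAL_GROWTH, [Epoch(0.0, 1.0, growth_rate)])

    @classmethod
    def three_epoch(cls, t1: float, s1: float, t2: float, s2: float
                    ) -> "DemographicModel":
        """Present size 1; size s1 between t1 and t2; s2 before t2."""
        return cls(THREE_EPOCH_BOTTLENECK,
                   [Epoch(0.0, 1.0, 0.0), Epoch(t1, s1, 0.0),
                    Epoch(t2, s2, 0.0)])

    def coal_waiting_time(self, t: float, k: int, exp_draw: float) -> float:
        """Waiting time from ``t`` to the next coalescence of k lineages.

        ``exp_draw`` is a standard-exponential variate; the time change is
        inverted analytically epoch by epoch.
        """
        if k < 2:
            return math.inf
        base = k * (k - 1) / 2.0
        E = exp_draw
        cur = t
        for i, e in enumerate(self.epochs):
            end = (self.epochs[i + 1].start if i + 1 < len(self.epochs)
                   else math.inf)
            if end <= cur:
                continue
            t0 = max(cur, e.start)
            rate0 = base / e.size  # rate at epoch start before growth factor
            g = e.growth_rate
            if g == 0.0:
                span = end - t0
                need = E / rate0
                if need <= span:
                    return t0 + need - t
                E -= span * rate0
            else:
                # integral of rate0*exp(g*(u - e.start)) du from t0 to end
                a0 = math.exp(g * (t0 - e.start))
                if math.isinf(end):
                    avail = math.inf
                else:
                    avail = rate0 / g * (math.exp(g * (end - e.start)) - a0)
                if E <= avail or math.isinf(end):
                    dt = math.log(a0 + g * E / rate0) / g - (t0 - e.start)
                    return t0 + dt - t
                E -= avail
            cur = end
        raise RuntimeError("demography exhausted without coalescence")


@dataclass
class PriorSpec:
    """Independent uniform prior bounds, keyed by parameter name.

    ``theta_per_site`` is required for null-distribution draws; demographic
    parameter names must match the model factory arguments
    (``growth_rate`` or ``t1``, ``s1``, ``t2``, ``s2``).
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"prior {name}: lo > hi")
        th = self.bounds.get("theta_per_site")
        if th is not None and th[0] <= 0:
            raise ValueError("theta bounds must be positive")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {name: float(rng.uniform(lo, hi))
                for name, (lo, hi) in self.bounds.items()}


@dataclass
class SimulationConfig:
    n: int
    L: int
    R: float
    model_kind: str = EQUILIBRIUM
    priors: PriorSpec | None = None
    fixed_params: dict = field(default_factory=dict)
    replicates: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if self.R < 0:
            raise ValueError("R must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def build_model(self, params: dict[str, float]) -> DemographicModel:
        if self.model_kind == EQUILIBRIUM:
            return DemographicModel.equilibrium()
        if self.model_kind == EXPONENTIAL_GROWTH:
            return DemographicModel.exponential_growth(params["growth_rate"])
        if self.model_kind == THREE_EPOCH_BOTTLENECK:
            return DemographicModel.three_epoch(
                params["t1"], params["s1"], params["t2"], params["s2"])
        raise ValueError(f"unknown model kind {self.model_kind!r}")


def effective_R(Ne: float, r_per_bp: float, L: int,
                x_linked: bool = False) -> float:
    """Population recombination parameter for a region of L base pairs.

    ``R = 3*Ne*r*L`` for X-linked loci (three X chromosomes per mating
    pair), else ``4*Ne*r*L``.
    """
    if Ne <= 0 or r_per_bp < 0 or L <= 0:
        raise ValueError("Ne and L must be positive, r non-negative")
    factor = 3.0 if x_linked else 4.0
    return factor * Ne * r_per_bp * L


# ---------------------------------------------------------------------------
# ARG simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSample:
    """One coalescent replicate: infinite-sites mutations with truth.

    ``positions`` are locus coordinates in [0, 1); ``masks[j]`` is the
    bitmask of samples carrying the derived allele of mutation j.
    """

    n: int
    positions: list[float]
    masks: list[int]
    params: dict[str, float] = field(default_factory=dict)

    @property
    def S(self) -> int:
        return len(self.positions)

    def derived_counts(self) -> np.ndarray:
        return np.asarray([bin(m).count("1") for m in self.masks], dtype=int)

    def sfs(self) -> np.ndarray:
        out = np.zeros(self.n + 1, dtype=int)
        for i in self.derived_counts():
            out[i] += 1
        return out

    def pi_total(self) -> float:
        return theta_pi_from_sfs(self.sfs(), self.n)

    def tajimas_d(self) -> float | None:
        return tajimas_d(self.S, self.pi_total(), self.n)

    def fay_wu_h(self) -> float | None:
        if self.S == 0:
            return None
        return fay_wu_h(self.sfs(), self.n)

    def haplotypes(self) -> np.ndarray:
        """0/1 matrix (n x S), columns ordered by position."""
        order = np.argsort(self.positions)
        H = np.zeros((self.n, self.S), dtype=np.int8)
        for col, j in enumerate(order):
            m = self.masks[j]
            for i in range(self.n):
                if m >> i & 1:
                    H[i, col] = 1
        return H


# a lineage is a list of (left, right, mask) segments, sorted, non-overlapping
def _merge_lineages(segs1, segs2, full_mask):
    """Coalesce two lineages; drop material that reaches its local MRCA."""
    points = sorted({p for s in segs1 + segs2 for p in (s[0], s[1])})
    merged = []
    for lo, hi in zip(points[:-1], points[1:]):
        mask = 0
        for s in segs1 + segs2:
            if s[0] <= lo and s[1] >= hi:
                mask |= s[2]
        if mask == 0 or mask == full_mask:
            continue
        if merged and merged[-1][1] == lo and merged[-1][2] == mask:
            merged[-1] = (merged[-1][0], hi, mask)
        else:
            merged.append((lo, hi, mask))
    return merged


def simulate_replicate(n: int, theta_locus: float, R: float,
                       model: DemographicModel,
                       rng: np.random.Generator,
                       params: dict[str, float] | None = None
                       ) -> SimulatedSample:
    """Simulate one ARG realization and its infinite-sites mutations."""
    full_mask = (1 << n) - 1
    lineages: list[list[tuple[float, float, int]]] = [
        [(0.0, 1.0, 1 << i)] for i in range(n)
    ]
    t = 0.0
    positions: list[float] = []
    masks: list[int] = []
    mut_rate = theta_locus / 2.0

    while len(lineages) > 1:
        k = len(lineages)
        spans = np.asarray([segs[-1][1] - segs[0][0] for segs in lineages])
        rec_rate = (R / 2.0) * float(spans.sum())
        dt_rec = (rng.exponential(1.0 / rec_rate) if rec_rate > 0
                  else math.inf)
        dt_coal = model.coal_waiting_time(t, k, rng.exponential())
        dt = min(dt_rec, dt_coal)

        # drop mutations over the interval (t, t + dt)
        lengths = np.asarray([sum(s[1] - s[0] for s in segs)
                              for segs in lineages])
        total_len = float(lengths.sum())
        n_mut = rng.poisson(mut_rate * dt * total_len) if total_len > 0 else 0
        for _ in range(n_mut):
            li = int(rng.choice(k, p=lengths / total_len))
            segs = lineages[li]
            seg_lens = np.asarray([s[1] - s[0] for s in segs])
            si = int(rng.choice(len(segs), p=seg_lens / seg_lens.sum()))
            lo, hi, mask = segs[si]
            positions.append(float(rng.uniform(lo, hi)))
            masks.append(mask)

        t += dt
        if dt_rec < dt_coal:
            li = int(rng.choice(k, p=spans / spans.sum()))
            segs = lineages[li]
            left_edge, right_edge = segs[0][0], segs[-1][1]
            bp = float(rng.uniform(left_edge, right_edge))
            left, right = [], []
            for lo, hi, mask in segs:
                if hi <= bp:
                    left.append((lo, hi, mask))
                elif lo >= bp:
                    right.append((lo, hi, mask))
                else:
                    left.append((lo, bp, mask))
                    right.append((bp, hi, mask))
            if left and right:
                lineages[li] = left
                lineages.append(right)
            # else: breakpoint outside ancestral material; no-op
        else:
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            merged = _merge_lineages(lineages[i], lineages[j], full_mask)
            lineages[j] = lineages[-1]
            lineages.pop()
            if merged:
                lineages[i] = merged
            else:
                lineages[i] = lineages[-1]
                lineages.pop()

    return SimulatedSample(n=n, positions=positions, masks=masks,
                           params=dict(params or {}))


# ---------------------------------------------------------------------------
# Null distributions and empirical p-values
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    values: np.ndarray
    n_defined: int
    n_undefined: int
    param_draws: list[dict[str, float]]


def null_distribution(cfg: SimulationConfig, statistic_fn,
                      rng: np.random.Generator | None = None
                      ) -> NullDistribution:
    """Simulate the null distribution of a statistic under the config.

    Per replicate, parameters are drawn from the priors (overridden by
    ``cfg.fixed_params``), one ARG is simulated, and ``statistic_fn``
    (SimulatedSample -> float or None) is evaluated.  Undefined values
    (None, e.g. S = 0 for Tajima's D) are skipped and recorded; the
    denominator of downstream p-values is the defined count.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    values = []
    draws = []
    undefined = 0
    for _ in range(cfg.replicates):
        params = cfg.priors.draw(rng) if cfg.priors else {}
        params.update(cfg.fixed_params)
        theta_locus = params.get(
            "theta_locus", params.get("theta_per_site", 0.0) * cfg.L)
        model = cfg.build_model(params)
        sample = simulate_replicate(cfg.n, theta_locus, cfg.R, model, rng,
                                    params)
        val = statistic_fn(sample)
        draws.append(params)
        if val is None:
            undefined += 1
        else:
            values.append(float(val))
    if not values:
        raise RuntimeError("statistic undefined in every replicate")
    return NullDistribution(values=np.sort(np.asarray(values)),
                            n_defined=len(values), n_undefined=undefined,
                            param_draws=draws)


@dataclass
class EmpiricalPValue:
    """Inclusive-tail empirical p-value against a simulated null."""

    extreme: int
    total: int
    tail: str

    @property
    def p(self) -> float:
        return self.extreme / self.total

    @property
    def bounded(self) -> bool:
        """True when no null value was as extreme as the observation."""
        return self.extreme == 0

    def render(self) -> str:
        if self.bounded:
            return f"< {1.0 / self.total:.4g}"
        return f"{self.p:.4g}"


def empirical_pvalue(observed: float, null_values: np.ndarray,
                     tail: str) -> EmpiricalPValue:
    """Proportion of null values as extreme as the observation, inclusive.

    ``tail='lower'`` counts null values <= observed (for negative
    statistics); ``tail='upper'`` counts >= observed.  A zero count is
    reported as "< 1/N".
    """
    null_values = np.asarray(null_values)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    if tail == "lower":
        extreme = int(np.sum(null_values <= observed))
    elif tail == "upper":
        extreme = int(np.sum(null_values >= observed))
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return EmpiricalPValue(extreme=extreme, total=int(null_values.size),
                           tail=tail)


@dataclass
class EmpiricalTestResult:
    statistic: str
    observed: float
    tail: str
    scenario: str
    pvalue: EmpiricalPValue
    cutoff: float | None = None

    @property
    def reject(self) -> bool | None:
        if self.cutoff is None:
            return None
        return self.pvalue.p < self.cutoff


def bonferroni(p_values: list[float], k: int | None = None,
               family_alpha: float = 0.025) -> tuple[float, list[bool]]:
    """Bonferroni-adjusted decisions: per-test cutoff = family_alpha / k.

    Rejection uses strict inequality (p exactly at the cutoff is not
    rejected).  ``k`` defaults to the number of p-values.
    """
    if k is None:
        k = len(p_values)
    if k < 1:
        raise ValueError("need at least one test")
    cutoff = family_alpha / k
    return cutoff, [p < cutoff for p in p_values]
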