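"""Analytic model of premature stop-codon accumulation over dark-zone divisions.

The chain, for a V gene of length L nt mutating at mu substitutions per
nucleotide per division:

    p_m     = L * mu                    per-division mutation probability
    p_point = q * p_m                   stop by point mutation per division
    p_del   from (mutation load, deletion fraction) correlations:
              divisions n_i = load_i / p_m,
              retain_i = (1 - fraction_i)^(1/n_i),
              retain = mean(retain_i), p_del = 1 - retain
    p_fs    = p_del * frameshift_fraction   (indels not a multiple of 3)
    p_stop  = p_point + p_fs
    E       = sum_k P(k) * (1 - (1 - p_stop)^k)

where P(k) is the snapshot probability that a dark-zone cell has completed k
divisions.  Because a population doubles with each division, a snapshot of a
cohort dividing up to D times contains cells in proportion 2^k, giving
P(k) = 2^k / (2^(D+1) - 1).

Two rounding modes are provided.  "full" carries full precision through the
chain.  "printed" rounds each intermediate to its conventional reported
precision (p_point and retain to 3 decimals) before the next step, which is
the mode that reproduces hand-calculated report chains exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MutationRates",
    "DeletionObservation",
    "DEFAULT_DELETION_OBSERVATIONS",
    "DivisionDistribution",
    "per_division_mutation_probability",
    "point_stop_probability_per_division",
    "estimate_deletion_rate",
    "frameshift_stop_probability",
    "combined_stop_probability",
    "snapshot_division_distribution",
    "expected_stop_frequency",
    "ExpectationReport",
    "expectation_chain",
]

DEFAULT_FRAMESHIFT_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class DeletionObservation:
    """A (mean point-mutation load, fraction of cells with a deletion) pair
    from in-vivo mutation/deletion correlation data."""

    mutation_load: float
    deletion_fraction: float

    def __post_init__(self):
        if self.mutation_load <= 0:
            raise ValueError("mutation_load must be positive")
        if not (0.0 <= self.deletion_fraction < 1.0):
            raise ValueError("deletion_fraction must be in [0, 1)")


#: High / medium / low mutation-load cohorts from published in-vivo
#: point-mutation vs deletion correlations.
DEFAULT_DELETION_OBSERVATIONS = (
    DeletionObservation(20, 0.40),
    DeletionObservation(15, 0.15),
    DeletionObservation(5, 0.05),
)


def per_division_mutation_probability(length: int, mu: float) -> float:
    """p_m = L * mu, the linear per-division mutation probability.

    Valid only while L * mu < 1 (the linear probability interpretation
    breaks down otherwise).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    p_m = length * mu
    if p_m >= 1:
        raise ValueError(
            f"L*mu = {p_m:.3g} >= 1: per-division probability interpretation breaks down"
        )
    return p_m


def point_stop_probability_per_division(q: float, p_m: float) -> float:
    """p_point = q * p_m."""
    for name, v in (("q", q), ("p_m", p_m)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    return q * p_m


def estimate_deletion_rate(observations: Iterable[DeletionObservation],
                           p_m: float,
                           division_rounding: bool = True,
                           ) -> tuple[float, float]:
    """Estimate the per-division deletion probability.

    Each observation's mutation load is converted to a division count
    ``n = load / p_m`` (rounded to the nearest integer by default), the
    per-division retention ``(1 - deletion_fraction)^(1/n)`` is taken, and
    the retentions are averaged arithmetically.

    Returns
    -------
    (retain_prob, p_del)
        Mean per-division probability of *not* acquiring a deletion, and its
        complement.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("at least one observation is required")
    if p_m <= 0:
        raise ValueError("p_m must be positive")
    retains = []
    for o in obs:
        n = o.mutation_load / p_m
        if division_rounding:
            n = max(1, round(n))
        retains.append((1.0 - o.deletion_fraction) ** (1.0 / n))
    retain = sum(retains) / len(retains)
    return retain, 1.0 - retain


def frameshift_stop_probability(p_del: float,
                                frameshift_fraction: float = DEFAULT_FRAMESHIFT_FRACTION,
                                ) -> float:
    """p_fs = p_del * frameshift_fraction (indels of length not divisible by
    3 are assumed to cause an eventual stop)."""
    for name, v in (("p_del", p_del), ("frameshift_fraction", frameshift_fraction)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    return p_del * frameshift_fraction


def combined_stop_probability(p_point: float, p_fs: float) -> float:
    """p_stop = p_point + p_fs (linear combination of the two routes)."""
    for name, v in (("p_point", p_point), ("p_fs", p_fs)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    p = p_point + p_fs
    if p > 1.0:
        raise ValueError(f"p_point + p_fs = {p:.3g} exceeds 1")
    return p


@dataclass(frozen=True)
class DivisionDistribution:
    """P(k divisions completed) for a snapshot cohort, k = 0..D."""

    probs: Mapping[int, float]

    def __post_init__(self):
        probs = {int(k): float(v) for k, v in self.probs.items()}
        if any(k < 0 for k in probs):
            raise ValueError("division counts must be non-negative")
        if any(v < 0 for v in probs.values()):
            raise ValueError("probabilities must be non-negative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"division probabilities sum to {total}, not 1")
        object.__setattr__(self, "probs", probs)

    @property
    def max_divisions(self) -> int:
        return max(self.probs)

    def mean(self) -> float:
        return sum(k * p for k, p in self.probs.items())

    def items(self):
        return sorted(self.probs.items())


def snapshot_division_distribution(max_divisions: int) -> DivisionDistribution:
    """Snapshot distribution over completed divisions, weighted 2^k.

    A population observed mid-expansion contains 2^k cells for every founder
    that completed k of at most D divisions, so
    P(k) = 2^k / (2^(D+1) - 1).  For D=2 this is 1/7, 2/7, 4/7
    (14%/29%/57%); for D=3, 7%/13%/27%/53% to the nearest percent.
    """
    D = int(max_divisions)
    if D < 0:
        raise ValueError("max divisions must be >= 0")
    denom = 2 ** (D + 1) - 1
    return DivisionDistribution({k: (2 ** k) / denom for k in range(D + 1)})


def expected_stop_frequency(dist: DivisionDistribution, p_stop: float) -> float:
    """Expected fraction of a snapshot cohort carrying a premature stop.

    E = sum_k P(k) * (1 - (1 - p_stop)^k): the chance of surviving k
    divisions stop-free is (1 - p_stop)^k.
    """
    if not (0.0 <= p_stop <= 1.0):
        raise ValueError("p_stop must be in [0, 1]")
    return sum(p * (1.0 - (1.0 - p_stop) ** k) for k, p in dist.probs.items())


@dataclass(frozen=True)
class MutationRates:
    """Bundle of the analytic model's per-division rates."""

    length: int
    point_rate_mu: float = 1e-3
    q: float = 0.0
    deletion_prob_per_division: float = 0.0
    frameshift_fraction: float = DEFAULT_FRAMESHIFT_FRACTION

    @property
    def p_m(self) -> float:
        return per_division_mutation_probability(self.length, self.point_rate_mu)

    @property
    def p_point(self) -> float:
        return point_stop_probability_per_division(self.q, self.p_m)

    @property
    def p_fs(self) -> float:
        return frameshift_stop_probability(self.deletion_prob_per_division,
                                           self.frameshift_fraction)

    @property
    def p_stop(self) -> float:
        return combined_stop_probability(self.p_point, self.p_fs)


@dataclass(frozen=True)
class ExpectationReport:
    """Every intermediate of the analytic chain, in one rounding mode."""

    rounding: str
    length: int
    mu: float
    q: float
    p_m: float
    p_point: float
    retain_prob: float
    p_del: float
    p_fs: float
    p_stop: float
    max_divisions: int
    distribution: dict = field(default_factory=dict)
    expected_frequency: float = 0.0

    def to_dict(self) -> dict:
        return {
            "rounding": self.rounding,
            "length": self.length,
            "mu": self.mu,
            "q": self.q,
            "p_m": self.p_m,
            "p_point": self.p_point,
            "retain_prob": self.retain_prob,
            "p_del": self.p_del,
            "p_fs": self.p_fs,
            "p_stop": self.p_stop,
            "max_divisions": self.max_divisions,
            "distribution": {str(k): v for k, v in sorted(self.distribution.items())},
            "expected_frequency": self.expected_frequency,
        }


def expectation_chain(q: float,
                      length: int = 393,
                      mu: float = 1e-3,
                      deletion_observations: Sequence[DeletionObservation] = DEFAULT_DELETION_OBSERVATIONS,
                      max_divisions: int = 2,
                      frameshift_fraction: float = DEFAULT_FRAMESHIFT_FRACTION,
                      rounding: str = "full",
                      division_rounding: bool = True,
                      ) -> ExpectationReport:
    """Run the full analytic chain from q to the expected cohort frequency.

    ``rounding="printed"`` rounds p_point, retain and p_fs to 3 decimals
    before they feed the next step (matching hand-reported chains);
    ``rounding="full"`` never rounds.
    """
    if rounding not in ("full", "printed"):
        raise ValueError("rounding must be 'full' or 'printed'")
    printed = rounding == "printed"

    p_m = per_division_mutation_probability(length, mu)
    p_point = point_stop_probability_per_division(q, p_m)
    if printed:
        p_point = round(p_point, 3)
    if deletion_observations:
        retain, p_del = estimate_deletion_rate(deletion_observations, p_m,
                                               division_rounding=division_rounding)
        if printed:
            retain = round(retain, 3)
            p_del = round(1.0 - retain, 3)
    else:
        retain, p_del = 1.0, 0.0
    p_fs = frameshift_stop_probability(p_del, frameshift_fraction)
    if printed:
        p_fs = round(p_fs, 3)
    p_stop = combined_stop_probability(p_point, p_fs)
    dist = snapshot_division_distribution(max_divisions)
    e = expected_stop_frequency(dist, p_stop)
    if printed:
        e = round(e, 3)
    return ExpectationReport(
        rounding=rounding, length=length, mu=mu, q=q, p_m=p_m, p_point=p_point,
        retain_prob=retain, p_del=p_del, p_fs=p_fs, p_stop=p_stop,
        max_divisions=max_divisions, distribution=dict(dist.probs),
        expected_frequency=e,
    )
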