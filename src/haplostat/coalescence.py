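"""Expected time to reciprocal monophyly and the lineage-sorting verdict.

After a split, a neutral locus is expected to attain reciprocal
monophyly after about 1.665 * Ne generations for a haploid, uniparentally
inherited (organelle) locus and 1.665 * 2 Ne generations for a nuclear
locus. With the isolation-with-migration scalings theta = 4 Ne mu and
mu = U G (U the per-locus per-year mutation rate, G the generation time
in years), these become calendar times

    organelle:  T = 1.665 * theta / (4 U)
    nuclear:    T = 1.665 * theta / (2 U)

independent of G. U is taken as the geometric mean across loci of the
per-locus rates (per-site rate times locus length). Comparing the
resulting expected-monophyly window against an independently estimated
divergence-time window separates the two readings of non-monophyly: if
expected coalescence fits inside the divergence window, incomplete
lineage sorting alone can explain shared polymorphism; if it strictly
exceeds it, persistent para/polyphyly is predicted and — when migration
estimates are bounded away from zero — hybridization/introgression is
additionally implicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LocusRate",
    "RateSpec",
    "ImEstimates",
    "MonophylyWindow",
    "IlsVerdict",
    "per_locus_rate_interval",
    "expected_monophyly_time",
    "monophyly_window",
    "effective_size",
    "migrants_per_generation",
    "ils_verdict",
]

#: Expected number of Ne-units of time to reciprocal monophyly.
MONOPHYLY_CONSTANT = 1.665


@dataclass(frozen=True)
class LocusRate:
    """Per-site mutation-rate interval and length for one locus."""

    locus_name: str
    per_site_rate_low: float  # substitutions / site / year
    per_site_rate_high: float
    locus_length: int  # sites

    def __post_init__(self) -> None:
        if not 0 < self.per_site_rate_low <= self.per_site_rate_high:
            raise ValueError("rate interval must satisfy 0 < low <= high")
        if self.locus_length <= 0:
            raise ValueError("locus length must be positive")

    @property
    def per_locus_low(self) -> float:
        return self.per_site_rate_low * self.locus_length

    @property
    def per_locus_high(self) -> float:
        return self.per_site_rate_high * self.locus_length


@dataclass(frozen=True)
class RateSpec:
    """Mutation-rate intervals for all loci plus an optional generation time."""

    loci: tuple[LocusRate, ...]
    generation_time: float | None = None  # years

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("RateSpec requires at least one locus")
        if self.generation_time is not None and self.generation_time <= 0:
            raise ValueError("generation time must be positive")


@dataclass(frozen=True)
class ImEstimates:
    """Isolation-with-migration point estimates consumed as inputs.

    Scaled sizes theta = 4 Ne mu; migration entries map a direction label
    to (hpd_low, point, hpd_high) on the m = m/mu scale.
    """

    theta_1: float
    theta_2: float
    theta_a: float
    migration: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    t_split: float | None = None

    def __post_init__(self) -> None:
        for th in (self.theta_1, self.theta_2, self.theta_a):
            if th < 0:
                raise ValueError("theta estimates must be non-negative")
        for key, (lo, point, hi) in self.migration.items():
            if not lo <= point <= hi:
                raise ValueError(f"migration HPD for {key!r} must bracket the point")


@dataclass(frozen=True)
class MonophylyWindow:
    """Expected time-to-monophyly interval for one genome, in years."""

    genome: str  # "organelle" | "nuclear"
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.t_low <= self.t_high:
            raise ValueError("window must satisfy 0 <= t_low <= t_high")


@dataclass(frozen=True)
class IlsVerdict:
    monophyly: MonophylyWindow
    divergence: tuple[float, float]  # years
    relation: str  # overlap | expected_exceeds | expected_below
    migration_nonzero: dict[str, bool]
    verdict: str


def per_locus_rate_interval(spec: RateSpec) -> tuple[float, float]:
    """Endpoint-wise geometric mean across loci of per-locus yearly rates."""
    n = len(spec.loci)
    low = 1.0
    high = 1.0
    for locus in spec.loci:
        low *= locus.per_locus_low
        high *= locus.per_locus_high
    return low ** (1.0 / n), high ** (1.0 / n)


def expected_monophyly_time(theta: float, u: float, genome: str) -> float:
    """Expected years to reciprocal monophyly for one theta and rate U."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if u <= 0:
        raise ValueError("U must be positive")
    if genome == "organelle":
        return MONOPHYLY_CONSTANT * theta / (4.0 * u)
    if genome == "nuclear":
        return MONOPHYLY_CONSTANT * theta / (2.0 * u)
    raise ValueError(f"unknown genome {genome!r}")


def monophyly_window(
    thetas: list[float], u_interval: tuple[float, float], genome: str
) -> MonophylyWindow:
    """Window of expected monophyly times over a theta set and U interval.

    The lower endpoint pairs the smallest theta with the fastest rate,
    the upper endpoint the largest theta with the slowest rate.
    """
    if not thetas:
        raise ValueError("theta set must be non-empty")
    u_low, u_high = u_interval
    if not 0 < u_low <= u_high:
        raise ValueError("U interval must satisfy 0 < low <= high")
    t_low = expected_monophyly_time(min(thetas), u_high, genome)
    t_high = expected_monophyly_time(max(thetas), u_low, genome)
    return MonophylyWindow(genome=genome, t_low=t_low, t_high=t_high)


def effective_size(theta: float, u: float, g: float) -> float:
    """Ne = theta / (4 U G)."""
    if u <= 0 or g <= 0:
        raise ValueError("U and G must be positive")
    return theta / (4.0 * u * g)


def migrants_per_generation(m: float, theta: float) -> float:
    """Effective migrants per generation 2 Ne m = m * theta / 2."""
    if m < 0 or theta < 0:
        raise ValueError("m and theta must be non-negative")
    return m * theta / 2.0


def ils_verdict(
    mono: MonophylyWindow,
    divergence: tuple[float, float],
    im: ImEstimates | None = None,
    m_threshold: float = 0.0,
) -> IlsVerdict:
    """Compare expected-monophyly and divergence windows; classify the
    non-monophyly mechanism.

    ``overlap``: monophyly is attainable within the divergence time, so
    incomplete lineage sorting alone can explain the pattern.
    ``expected_exceeds``: the whole monophyly window postdates the
    divergence window (t_low > div_high) — lineage sorting is expected to
    be incomplete and paraphyly persists. ``expected_below``: monophyly is
    expected well before the divergence window. Any migration HPD whose
    lower bound exceeds ``m_threshold`` additionally implicates
    hybridization/introgression.
    """
    div_low, div_high = divergence
    if div_low > div_high:
        raise ValueError("inverted divergence window")
    if mono.t_low > div_high:
        relation = "expected_exceeds"
        verdict = "ILS expected to persist; paraphyly predicted"
    elif mono.t_high < div_low:
        relation = "expected_below"
        verdict = "monophyly expected well before divergence window"
    else:
        relation = "overlap"
        verdict = "monophyly attainable within divergence time; ILS alone can explain pattern"
    migration_nonzero: dict[str, bool] = {}
    if im is not None:
        for key, (lo, _, _) in im.migration.items():
            migration_nonzero[key] = lo > m_threshold
        if any(migration_nonzero.values()):
            verdict += "; hybridization/introgression implicated"
    return IlsVerdict(
        monophyly=mono,
        divergence=(div_low, div_high),
        relation=relation,
        migration_nonzero=migration_nonzero,
        verdict=verdict,
    )
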