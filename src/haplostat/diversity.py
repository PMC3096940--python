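"""Per-population and pooled sequence diversity statistics.

Implements the classical haplotype-level summary surface: nucleotide
diversity pi (mean pairwise differences per site) with Nei's sampling
variance, haplotype (gene) diversity with its variance, and Tajima's D
with the beta-distribution approximation for significance.

All statistics are computed on the *expanded* sample (each haplotype
repeated by its observed frequency) over the usable sites retained by
complete deletion, and are undefined (returned as NaN) for units with
fewer than two sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqio import HaplotypeTable, PopulationMap

__all__ = [
    "TajimaConstants",
    "DiversityStats",
    "nucleotide_diversity",
    "haplotype_diversity",
    "tajimas_d",
    "summarize_population",
    "mean_pairwise_differences",
]


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent constants of Tajima's D."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 3:
            raise ValueError("Tajima constants require n >= 3")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass(frozen=True)
class DiversityStats:
    """One row of the per-unit diversity report."""

    unit: str
    n: int
    H: int | None
    S: int | None
    k_bar: float
    pi: float
    pi_se: float
    hd: float
    hd_se: float
    tajima_d: float
    tajima_p: float

    def is_defined(self) -> bool:
        return self.n >= 2


def _seq_array(seqs: list[str]) -> np.ndarray:
    if not seqs:
        raise ValueError("empty sequence set")
    arr = np.array([list(s) for s in seqs], dtype="U1")
    return arr


def _site_pair_diffs(arr: np.ndarray) -> tuple[float, int]:
    """Total pairwise differences summed over all C(n,2) pairs, and S.

    Uses per-site allele counts: at a site with state counts c_a the number
    of differing pairs is (n^2 - sum c_a^2) / 2; summing over sites equals
    the sum of Hamming distances over all pairs.
    """
    n, L = arr.shape
    total = 0.0
    S = 0
    for j in range(L):
        _, counts = np.unique(arr[:, j], return_counts=True)
        if len(counts) > 1:
            S += 1
            total += (n * n - float((counts.astype(float) ** 2).sum())) / 2.0
    return total, S


def mean_pairwise_differences(seqs: list[str]) -> float:
    """k_bar: mean number of pairwise differences over all C(n,2) pairs."""
    arr = _seq_array(seqs)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("k_bar requires n >= 2")
    total, _ = _site_pair_diffs(arr)
    return total / (n * (n - 1) / 2.0)


def nucleotide_diversity(seqs: list[str]) -> tuple[float, float, float]:
    """Nucleotide diversity per site with Nei's sampling standard error.

    Returns ``(pi, pi_se, k_bar)`` where ``pi = k_bar / L`` and the
    variance is Nei's (1987) total variance for the unknown-phylogeny case:

        V(pi) = (n+1) pi / (3 (n-1) L)  +  2 (n^2+n+3) pi^2 / (9 n (n-1))
    """
    arr = _seq_array(seqs)
    n, L = arr.shape
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2")
    total, _ = _site_pair_diffs(arr)
    k_bar = total / (n * (n - 1) / 2.0)
    pi = k_bar / L
    var = (n + 1) * pi / (3.0 * (n - 1) * L) + (
        2.0 * (n**2 + n + 3) * pi**2 / (9.0 * n * (n - 1))
    )
    return pi, math.sqrt(max(var, 0.0)), k_bar


def haplotype_diversity(counts: np.ndarray | list[int]) -> tuple[float, float]:
    """Haplotype (gene) diversity with Nei's sampling standard error.

    ``hd = n (1 - sum p_i^2) / (n - 1)``; the variance follows Nei's (1987)
    formula for heterozygosity estimated from a single sample of n genes.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = c / n
    sp2 = float((p**2).sum())
    sp3 = float((p**3).sum())
    hd = n * (1.0 - sp2) / (n - 1.0)
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2)
    )
    return hd, math.sqrt(max(var, 0.0))


def tajima_d_bounds(n: int) -> tuple[float, float]:
    """Large-S lower/upper bounds of D (all-singleton vs balanced sites)."""
    const = TajimaConstants.from_n(n)
    dmin = (2.0 / n - 1.0 / const.a1) / math.sqrt(const.e2)
    if n % 2 == 0:
        dmax = (n / (2.0 * (n - 1.0)) - 1.0 / const.a1) / math.sqrt(const.e2)
    else:
        dmax = ((n + 1.0) / (2.0 * n) - 1.0 / const.a1) / math.sqrt(const.e2)
    return dmin, dmax


def _tajima_p_beta(d: float, n: int) -> float:
    """Two-sided p-value from Tajima's beta approximation.

    D is assumed to have mean 0 and variance 1 on the support
    [Dmin, Dmax]; the matching beta distribution gives the tail areas.
    """
    dmin, dmax = tajima_d_bounds(n)
    rng = dmax - dmin
    alpha = -(1.0 + dmin * dmax) * dmax / rng
    beta = (1.0 + dmin * dmax) * dmin / rng
    if alpha <= 0 or beta <= 0:
        return float("nan")
    x = (d - dmin) / rng
    x = min(max(x, 0.0), 1.0)
    cdf = sps.beta.cdf(x, alpha, beta)
    return float(2.0 * min(cdf, 1.0 - cdf))


def tajimas_d(seqs: list[str]) -> tuple[float, float]:
    """Tajima's D and its beta-approximation two-sided p-value.

    Returns ``(nan, nan)`` when the statistic is undefined (n < 3, no
    segregating sites, or a zero variance term); report writers render
    such cells as "-".
    """
    arr = _seq_array(seqs)
    n = arr.shape[0]
    if n < 3:
        return float("nan"), float("nan")
    total, S = _site_pair_diffs(arr)
    if S == 0:
        return float("nan"), float("nan")
    k_bar = total / (n * (n - 1) / 2.0)
    const = TajimaConstants.from_n(n)
    var = const.e1 * S + const.e2 * S * (S - 1)
    if var <= 0:
        return float("nan"), float("nan")
    d = (k_bar - S / const.a1) / math.sqrt(var)
    return d, _tajima_p_beta(d, n)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _unit_members(
    table: HaplotypeTable, popmap: PopulationMap, scope: str
) -> list[tuple[str, list[str]]]:
    if scope == "population":
        return [(p, [p]) for p in table.populations]
    if scope == "group":
        out = []
        for g in popmap.groups:
            members = [p for p in table.populations if popmap.group_of(p) == g]
            if members:
                out.append((g, members))
        return out
    if scope == "all":
        return [("all", list(table.populations))]
    raise ValueError(f"unknown scope {scope!r}")


def summarize_population(
    table: HaplotypeTable, popmap: PopulationMap, scope: str = "population"
) -> list[DiversityStats]:
    """Diversity statistics per population, per group, or pooled.

    Units with a single sequence yield NaN statistics throughout
    (rendered "-" in reports).
    """
    results = []
    for unit, members in _unit_members(table, popmap, scope):
        freqs = table.frequencies(members)
        n = int(freqs.sum())
        if n < 2:
            results.append(
                DiversityStats(
                    unit, n, None, None, *([float("nan")] * 7)
                )
            )
            continue
        seqs = table.expand(members)
        pi, pi_se, k_bar = nucleotide_diversity(seqs)
        hd, hd_se = haplotype_diversity(freqs)
        d, p = tajimas_d(seqs)
        arr = _seq_array(seqs)
        _, S = _site_pair_diffs(arr)
        H = int((freqs > 0).sum())
        results.append(
            DiversityStats(unit, n, H, S, k_bar, pi, pi_se, hd, hd_se, d, p)
        )
    return results


def stats_frame(rows: list[DiversityStats]) -> pd.DataFrame:
    """Render diversity rows as the standard report table."""
    records = []
    for r in rows:
        records.append(
            {
                "unit": r.unit,
                "n": r.n,
                "H": r.H if r.H is not None else "-",
                "S": r.S if r.S is not None else "-",
                "pi": r.pi,
                "pi_se": r.pi_se,
                "hd": r.hd,
                "hd_se": r.hd_se,
                "tajima_d": r.tajima_d,
                "significance": significance_stars(r.tajima_p),
            }
        )
    return pd.DataFrame.from_records(records)
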