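"""Mismatch distributions and the sudden-expansion model.

The mismatch distribution is the histogram of pairwise sequence
differences among sampled sequences. Under a sudden demographic
expansion (scaled size theta0 jumping to theta1 at tau = 2ut mutational
time units before present) it is expected to be smooth and unimodal; the
Rogers–Harpending expected distribution is

    F_i(tau, theta0, theta1) = Fhat_i(theta1)
        + exp(-tau (theta1 + 1) / theta1)
          * sum_{j=0..i} tau^j / j! * (Fhat_{i-j}(theta0) - Fhat_{i-j}(theta1))

with the equilibrium distribution Fhat_i(theta) = theta^i / (theta+1)^(i+1).
Parameters are fitted by least squares on the observed vector via a
deterministic coarse grid followed by Nelder–Mead refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .structure import hamming_matrix

__all__ = [
    "MismatchResult",
    "mismatch_observed",
    "equilibrium_mismatch",
    "expected_mismatch",
    "sudden_expansion_fit",
    "raggedness",
]


@dataclass
class MismatchResult:
    observed: np.ndarray
    expected: np.ndarray
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    boundary: bool = False  # degenerate observed (single class)


def mismatch_observed(seqs: list[str]) -> np.ndarray:
    """Normalized histogram of pairwise differences over all C(n,2) pairs."""
    if len(seqs) < 2:
        raise ValueError("mismatch distribution requires n >= 2")
    d = hamming_matrix(seqs)
    vals = d[np.triu_indices(len(seqs), k=1)].astype(int)
    hist = np.bincount(vals)
    return hist / hist.sum()


def equilibrium_mismatch(theta: float, support: int) -> np.ndarray:
    """Fhat_i(theta) = theta^i / (theta+1)^(i+1) for i = 0..support-1."""
    i = np.arange(support, dtype=float)
    if theta == 0.0:
        out = np.zeros(support)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log(theta + 1.0))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, support: int
) -> np.ndarray:
    """Rogers–Harpending sudden-expansion expected mismatch distribution."""
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise ValueError("invalid sudden-expansion parameters")
    f0 = equilibrium_mismatch(theta0, support)
    f1 = equilibrium_mismatch(theta1, support)
    if tau == 0.0:
        return f0.copy()
    j = np.arange(support, dtype=float)
    log_pois = j * math.log(tau) - np.cumsum(np.concatenate([[0.0], np.log(np.maximum(j[1:], 1.0))]))
    pois = np.exp(log_pois - tau * (theta1 + 1.0) / theta1)
    conv = np.convolve(pois, f0 - f1)[:support]
    # convolution round-off can leave ~1e-17 negatives in the far tail
    return np.maximum(f1 + conv, 0.0)


def raggedness(observed: np.ndarray) -> float:
    """Harpending's raggedness r = sum of squared successive differences,
    padding the observed vector with zero classes at both ends."""
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("raggedness requires >= 2 classes")
    padded = np.concatenate([[0.0], obs, [0.0]])
    return float((np.diff(padded) ** 2).sum())


def _ssd(params: np.ndarray, observed: np.ndarray) -> float:
    tau, theta0, theta1 = params
    if tau < 0 or theta0 < 0 or theta1 <= 0 or theta0 > theta1:
        return float("inf")
    exp = expected_mismatch(tau, theta0, theta1, len(observed))
    return float(((observed - exp) ** 2).sum())


def sudden_expansion_fit(
    observed: np.ndarray,
    n_tau: int = 200,
    n_theta: int = 12,
) -> MismatchResult:
    """Least-squares fit of the sudden-expansion model.

    Deterministic: a coarse grid over tau in [0, 2*max_class], theta0 in
    [0, k_bar] and theta1 log-spaced in [max(k_bar, 0.1), 100*k_bar] is
    scanned, and the best grid point is refined with bounded Nelder–Mead
    (iteration-capped). theta0 <= theta1 is enforced by the fit bounds.
    A single-class observed vector short-circuits to the degenerate
    solution tau = class index, theta0 = 0, flagged ``boundary``.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 1:
        raise ValueError("observed must be a non-empty vector")
    support = obs.size
    k_bar = float((np.arange(support) * obs).sum())

    nonzero = np.nonzero(obs > 0)[0]
    if len(nonzero) == 1:
        cls = int(nonzero[0])
        theta1 = max(k_bar, 1e-3)
        exp = expected_mismatch(float(cls), 0.0, theta1, support)
        r = raggedness(obs) if support >= 2 else float("nan")
        return MismatchResult(obs, exp, float(cls), 0.0, theta1,
                              float(((obs - exp) ** 2).sum()), r, boundary=True)

    max_class = support - 1
    taus = np.linspace(0.0, 2.0 * max_class, n_tau)
    theta0s = np.linspace(0.0, max(k_bar, 1e-3), n_theta)
    hi = max(100.0 * k_bar, 1.0)
    lo = max(k_bar, 0.1)
    theta1s = np.geomspace(lo, hi, n_theta)

    best = (float("inf"), 0.0, 0.0, theta1s[0])
    for tau in taus:
        for th0 in theta0s:
            for th1 in theta1s:
                if th0 > th1:
                    continue
                ssd = _ssd(np.array([tau, th0, th1]), obs)
                if ssd < best[0]:
                    best = (ssd, float(tau), float(th0), float(th1))

    res = optimize.minimize(
        _ssd,
        x0=np.array(best[1:]),
        args=(obs,),
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-12},
    )
    if np.isfinite(res.fun) and res.fun <= best[0]:
        tau, th0, th1 = (float(v) for v in res.x)
        ssd = float(res.fun)
    else:
        ssd, tau, th0, th1 = best
    exp = expected_mismatch(tau, th0, th1, support)
    return MismatchResult(obs, exp, tau, th0, th1, ssd, raggedness(obs))
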