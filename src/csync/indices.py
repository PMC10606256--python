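"""Algebra of the complexity indices delta, mu, beta and D.

The scaling index delta of the homogeneous relation X(lambda*t) =
lambda**delta * X(t), the waiting-time index mu of psi(t) ~ t**(-mu), the
spectral index beta of S(f) ~ f**(-beta) and the fractal dimension D are
interchangeable measures of temporal complexity, linked by:

    D    = 2 - delta                         (always)
    beta = 3 - mu                            (1 <= mu <= 3)
    mu   = 1 + delta        non-ergodic      (1 <= mu <= 2)
    mu   = 1 + 1/delta      ergodic          (2 <= mu <= 3)
    delta = 1/2             Gaussian         (mu >= 3)

The delta <-> mu map is two-valued, so the regime must always be stated.
A further pair of indices describes the diffusion trajectory generated
from the events: the first-passage (recrossing) index muD = 2 - delta, and
the crucial-event index muS recovered from muD through the super-diffusive
relation muS = 1 + 1/(2 - muD) or the sub-diffusive relation
muS = 5 - 2*muD.  The sub-diffusive relation is derived under
1 < muS < 2; applying it outside that band (as is done for the
self-organized-criticality first-passage value muD = 1.3, which yields
muS = 2.4) triggers a warning rather than an error.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "REGIMES",
    "ComplexityIndexSet",
    "IndexRangeWarning",
    "delta_to_mu",
    "mu_to_delta",
    "mu_to_beta",
    "beta_to_mu",
    "fractal_dimension",
    "delta_to_muD",
    "muD_to_muS",
    "muS_to_muD",
    "index_set",
]

REGIMES = ("non_ergodic", "ergodic", "gaussian")


class IndexRangeWarning(UserWarning):
    """A conversion was applied outside the band its derivation assumes."""


def _check_delta(delta: float) -> None:
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"scaling index delta must lie in (0, 1], got {delta}")


def delta_to_mu(delta: float, regime: str) -> float:
    """Waiting-time index from the scaling index on a stated branch."""
    _check_delta(delta)
    if regime == "ergodic":
        return 1.0 + 1.0 / delta
    if regime == "non_ergodic":
        return 1.0 + delta
    if regime == "gaussian":
        return 3.0
    raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")


def mu_to_delta(mu: float) -> float:
    """Scaling index from the waiting-time index (single-valued)."""
    if mu >= 3.0:
        return 0.5
    if not (1.0 < mu):
        raise ValueError(f"mu must exceed 1, got {mu}")
    if mu <= 2.0:
        return mu - 1.0
    return 1.0 / (mu - 1.0)


def mu_to_beta(mu: float) -> float:
    """Spectral index beta = 3 - mu; beta = 1 at mu = 2 is true 1/f noise."""
    if not (1.0 <= mu <= 3.0):
        raise ValueError(f"mu must lie in [1, 3], got {mu}")
    return 3.0 - mu


def beta_to_mu(beta: float) -> float:
    if not (0.0 <= beta <= 2.0):
        raise ValueError(f"beta must lie in [0, 2], got {beta}")
    return 3.0 - beta


def fractal_dimension(delta: float) -> float:
    """Fractal dimension of the trajectory, D = 2 - delta."""
    _check_delta(delta)
    return 2.0 - delta


def delta_to_muD(delta: float) -> float:
    """First-passage (recrossing) waiting-time index muD = 2 - delta."""
    _check_delta(delta)
    return 2.0 - delta


def muD_to_muS(muD: float, diffusion_regime: str) -> float:
    """Crucial-event index from the first-passage index.

    super : muS = 1 + 1/(2 - muD), valid for muD < 2 (delta > 0.5 walks
        driven by a +/-1 velocity between events); singular at muD = 2.
    sub : muS = 5 - 2*muD, derived for an impulse walker under
        1 < muS < 2; outside that band an IndexRangeWarning is issued and
        the value returned unchanged.
    """
    if diffusion_regime == "super":
        if muD >= 2.0:
            raise ValueError("super-diffusive conversion requires muD < 2")
        return 1.0 + 1.0 / (2.0 - muD)
    if diffusion_regime == "sub":
        muS = 5.0 - 2.0 * muD
        if not (1.0 < muS < 2.0):
            warnings.warn(
                f"sub-diffusive relation applied outside its derivation band: muS={muS:g}",
                IndexRangeWarning,
                stacklevel=2,
            )
        return muS
    raise ValueError("diffusion_regime must be 'super' or 'sub'")


def muS_to_muD(muS: float, diffusion_regime: str) -> float:
    """Inverse of :func:`muD_to_muS` on the corresponding branch."""
    if diffusion_regime == "super":
        if muS <= 1.0:
            raise ValueError("super-diffusive inverse requires muS > 1")
        return 2.0 - 1.0 / (muS - 1.0)
    if diffusion_regime == "sub":
        return 2.5 - muS / 2.0
    raise ValueError("diffusion_regime must be 'super' or 'sub'")


@dataclass
class ComplexityIndexSet:
    """A mutually consistent tuple of complexity indices."""

    delta: float
    mu: float
    beta: float
    D: float
    regime: str

    def as_dict(self) -> dict:
        return {
            "delta": self.delta,
            "mu": self.mu,
            "beta": self.beta,
            "D": self.D,
            "regime": self.regime,
        }


def index_set(delta: float, regime: str) -> ComplexityIndexSet:
    """Complete the full index tuple from delta on a stated branch."""
    mu = delta_to_mu(delta, regime)
    return ComplexityIndexSet(
        delta=delta,
        mu=mu,
        beta=mu_to_beta(min(mu, 3.0)),
        D=fractal_dimension(delta),
        regime=regime,
    )
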