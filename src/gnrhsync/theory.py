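"""Analytic results about the network model.

Three exact statements are implemented and checked against simulation
elsewhere in the test suite:

* the synchronization period formula
  ``Tsyn = ln(sigma_on/sigma0) / (tau*eps*delta)``, valid in the limit of a
  Heaviside reset activation with a strong reset (gamma large relative to
  eps and delta): between episodes sigma grows linearly as
  sigma' = tau*delta*eps*sigma, so the inter-episode interval is the time
  to ride from sigma0 up to sigma_on;
* its inverse, which picks the growth rate delta to achieve a prescribed
  period;
* the rescaling invariance: the calcium outputs are unchanged under
  (sigma0, sigma_on, rho_syn) -> (alpha*sigma0, alpha*sigma_on,
  rho_syn/alpha) for any alpha > 0, because the substitution
  sigma -> alpha*sigma maps one system onto the other.  Only the ratio
  sigma_on/sigma0 is identifiable from calcium traces.

The boundaries in mu between the relaxation, MMO and steady regimes of the
single cell are not available in closed form; they are located by bisection
on the simulation-based classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_core import CellParams, NetworkParams, regime_of

__all__ = [
    "RescaleTransform",
    "tsyn_formula",
    "delta_for_period",
    "rescale_parameters",
    "find_mu_boundaries",
]


@dataclass(frozen=True)
class RescaleTransform:
    """Scaling factor alpha of the sigma-variable rescaling invariance."""

    alpha: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


def tsyn_formula(
    delta: float, tau: float, eps: float, sigma_on: float, sigma0: float
) -> float:
    """Predicted interval (minutes) between synchronization episodes:
    ln(sigma_on/sigma0) / (tau*eps*delta)."""
    _check_sigma_pair(sigma_on, sigma0)
    for name, v in dict(delta=delta, tau=tau, eps=eps).items():
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return math.log(sigma_on / sigma0) / (tau * eps * delta)


def delta_for_period(
    Tsyn: float, tau: float, eps: float, sigma_on: float, sigma0: float
) -> float:
    """Growth rate delta that yields a prescribed synchronization period;
    exact inverse of :func:`tsyn_formula`."""
    _check_sigma_pair(sigma_on, sigma0)
    if not Tsyn > 0:
        raise ValueError(f"Tsyn must be > 0, got {Tsyn}")
    return math.log(sigma_on / sigma0) / (tau * eps * Tsyn)


def _check_sigma_pair(sigma_on: float, sigma0: float) -> None:
    if not (sigma0 > 0 and sigma_on > sigma0):
        raise ValueError(
            f"need 0 < sigma0 < sigma_on, got sigma0={sigma0}, sigma_on={sigma_on}"
        )


def rescale_parameters(p: NetworkParams, t: RescaleTransform) -> NetworkParams:
    """Apply the invariance transform: sigma0 -> alpha*sigma0,
    sigma_on -> alpha*sigma_on, rho_syn -> rho_syn/alpha; calcium outputs
    of the rescaled system are identical (sigma itself is scaled by
    alpha)."""
    a = t.alpha
    return p.replace(
        sigma0=a * p.sigma0, sigma_on=a * p.sigma_on, rho_syn=p.rho_syn / a
    )


def find_mu_boundaries(
    p: CellParams,
    mu_lo: float = 2.0,
    mu_hi: float = 3.0,
    tol: float = 0.005,
    mu_mid: float | None = None,
) -> tuple[float, float]:
    """Locate the two regime boundaries in mu by bisection.

    Returns ``(mu_AB, mu_BC)``: the relaxation/MMO boundary and the
    MMO/steady boundary.  ``mu_mid`` must classify as MMO (defaults to the
    parameter set's own mu if it lies inside the bracket).  Bisection
    assumes the regime is monotone in mu over the bracket
    (relaxation below, MMO inside, steady above); a classification
    inconsistent with that ordering raises.
    """
    if not (mu_lo < mu_hi):
        raise ValueError("need mu_lo < mu_hi")
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if mu_mid is None:
        mu_mid = p.mu if mu_lo < p.mu < mu_hi else 0.5 * (mu_lo + mu_hi)

    def classify(mu: float) -> str:
        return regime_of(p.replace(mu=mu))

    r_lo, r_mid, r_hi = classify(mu_lo), classify(mu_mid), classify(mu_hi)
    if r_mid != "mmo":
        raise ValueError(f"mu_mid={mu_mid} classifies as {r_mid}, expected mmo")
    if r_lo != "relaxation" or r_hi != "steady":
        raise ValueError(
            "bracket endpoints must classify as relaxation (lo) and steady (hi), "
            f"got {r_lo} / {r_hi}"
        )

    def bisect(lo: float, hi: float, want_hi: str, lo_regime: str) -> float:
        # invariant: regime(lo) == lo_regime, regime(hi) == want_hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            r = classify(mid)
            if r == want_hi:
                hi = mid
            elif r == lo_regime:
                lo = mid
            else:
                raise ValueError(
                    f"regime {r} at mu={mid:.4f} breaks monotonicity between "
                    f"{lo_regime} and {want_hi}"
                )
        return 0.5 * (lo + hi)

    mu_ab = bisect(mu_lo, mu_mid, want_hi="mmo", lo_regime="relaxation")
    mu_bc = bisect(mu_mid, mu_hi, want_hi="steady", lo_regime="mmo")
    return mu_ab, mu_bc
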