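"""Core model definitions: parameters, state containers, right-hand sides,
and phase-plane geometry.

The single-cell model is a three-dimensional slow-fast system of
FitzHugh-Nagumo type,

    x'  = tau * (-y + 4x - x^3 - phi_fall(Ca))
    y'  = tau*eps*k * (a0*x + a1*y + a2 - drive)
    Ca' = tau*eps * (phi_rise(x) - (Ca - Cabas)/tauCa)

where ``x`` is the (dimensionless) average electrical activity of the cell,
``y`` the recovery variable and ``Ca`` the intracellular calcium
concentration in nM.  ``eps`` is the small time-scale separation parameter,
``k`` an order-one per-cell rate factor and ``tau`` rescales model time so
that the integration variable is experimental time in minutes.  Calcium
feeds back on the voltage dynamics through the saturating function
``phi_fall`` (bounded by the gain ``mu``); electrical activity drives
calcium entry through the sigmoid ``phi_rise``.

The network couples N such cells through a single super-slow global
variable ``sigma``: each cell receives the drive ``eta_j * phi_syn(sigma)``
in its y-equation, and

    sigma' = tau * (delta*eps*sigma
                    - gamma*(sigma - sigma0)*phi_sigma(mean(Ca) - Cadesyn))

so sigma grows quasi-exponentially while the population is asynchronous and
is reset toward ``sigma0`` once the population-mean calcium exceeds the
desynchronization threshold ``Cadesyn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "CellParams",
    "NetworkParams",
    "CellState",
    "NetworkState",
    "phi_fall",
    "phi_rise",
    "phi_syn",
    "phi_sigma",
    "cell_rhs",
    "network_rhs",
    "critical_manifold_y",
    "fold_x",
    "equilibrium",
    "regime_of",
    "cell_preset",
    "network_preset",
    "PRESET_NAMES",
]

# Exponent clamp for overflow-safe sigmoids; Heaviside-limit checks use
# slopes up to 1e6 where a naive exp() overflows.
_EXP_CLAMP = 700.0


def _safe_exp(z):
    return np.exp(np.clip(z, -_EXP_CLAMP, _EXP_CLAMP))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class CellParams:
    """Constants of the single-cell model.  Defaults are the reference
    parameter set of the model (MMO regime, 10-min inter-peak interval).

    Attributes
    ----------
    a0, a1, a2 : float
        Coefficients of the linear recovery dynamics.  ``a1`` must be
        negative and small so the y-nullcline is steep and meets the cubic
        exactly once.
    k : float
        Order-one time-scale factor of the recovery variable.
    eps : float
        Slow/fast separation parameter (> 0, small).
    tau : float
        Global rate that rescales model time to minutes.
    mu : float
        Gain of the calcium feedback ``phi_fall`` (controls the dynamical
        regime: relaxation / MMO / steady).
    Ca0 : float
        Half-saturation (nM) of ``phi_fall``.
    Cabas : float
        Baseline calcium level (nM).
    tauCa : float
        Calcium decay-rate divisor (exponential decay rate tau*eps/tauCa).
    lam : float
        Amplitude (nM scale) of the calcium influx sigmoid ``phi_rise``.
    rhoCa : float
        Slope of ``phi_rise``.
    xon : float
        Activation centre of ``phi_rise``.
    """

    a0: float = 1.0
    a1: float = -0.1
    a2: float = 0.8
    k: float = 1.0
    eps: float = 0.06
    tau: float = 37.0
    mu: float = 2.4
    Ca0: float = 500.0
    Cabas: float = 100.0
    tauCa: float = 2.0
    lam: float = 175.0
    rhoCa: float = 4.5
    xon: float = -0.45

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "eps": self.eps, "tau": self.tau, "k": self.k, "Ca0": self.Ca0,
            "tauCa": self.tauCa, "lam": self.lam, "rhoCa": self.rhoCa,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.Cabas < 0:
            raise ValueError(f"Cabas must be >= 0, got {self.Cabas}")
        if not self.a1 < 0:
            raise ValueError(f"a1 must be < 0, got {self.a1}")
        # |a1| small enough that the y-nullcline crosses the cubic once:
        # the depressed cubic x^3 + (a0/|a1| - 4)x + c has a unique real
        # root for every c when its linear coefficient is positive.
        if not self.a0 / abs(self.a1) > 4:
            raise ValueError(
                "a0/|a1| must exceed 4 for a unique cell equilibrium "
                f"(got {self.a0 / abs(self.a1):g})"
            )

    def replace(self, **changes) -> "CellParams":
        return replace(self, **changes)


@dataclass
class NetworkParams:
    """Constants of the N-cell network plus per-cell heterogeneity vectors.

    ``kj`` and ``etaj`` hold the per-cell rate factors and coupling
    sensitivities; the remaining scalars shape the global variable sigma.
    ``sigma0`` (reset value) must lie below ``sigma_on`` (activation
    threshold of ``phi_syn``).
    """

    cell: CellParams
    N: int
    kj: np.ndarray
    etaj: np.ndarray
    delta: float = 0.05
    gamma: float = 20.0
    sigma0: float = 0.1
    sigma_on: float = 60.0
    rho_syn: float = 5.0
    rho_sigma: float = 30.0
    Cadesyn: float = 350.0

    def __post_init__(self) -> None:
        self.kj = np.atleast_1d(np.asarray(self.kj, dtype=float))
        self.etaj = np.atleast_1d(np.asarray(self.etaj, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.kj.shape != (self.N,):
            raise ValueError(f"kj must have shape ({self.N},), got {self.kj.shape}")
        if self.etaj.shape != (self.N,):
            raise ValueError(f"etaj must have shape ({self.N},), got {self.etaj.shape}")
        if not np.all(self.kj > 0):
            raise ValueError("all kj must be > 0")
        if not np.all(self.etaj >= 0):
            raise ValueError("all etaj must be >= 0")
        for name in ("delta", "gamma", "rho_syn", "rho_sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.sigma0 < self.sigma_on:
            raise ValueError(
                f"sigma0 ({self.sigma0}) must be smaller than sigma_on ({self.sigma_on})"
            )

    def replace(self, **changes) -> "NetworkParams":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class CellState:
    """State (x, y, Ca) of one cell; Ca in nM."""

    x: float
    y: float
    Ca: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.Ca)):
            raise ValueError(f"non-finite cell state {(self.x, self.y, self.Ca)}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.Ca], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CellState":
        x, y, ca = np.asarray(arr, dtype=float)
        return cls(float(x), float(y), float(ca))


@dataclass
class NetworkState:
    """States of all N cells plus the global variable sigma.

    The flat-vector layout used by the integrator is
    ``[x_1..x_N, y_1..y_N, Ca_1..Ca_N, sigma]``.
    """

    cells: list[CellState]
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.sigma):
            raise ValueError("sigma must be finite")

    @property
    def N(self) -> int:
        return len(self.cells)

    def to_array(self) -> np.ndarray:
        n = self.N
        out = np.empty(3 * n + 1)
        for j, c in enumerate(self.cells):
            out[j], out[n + j], out[2 * n + j] = c.x, c.y, c.Ca
        out[3 * n] = self.sigma
        return out

    @classmethod
    def from_array(cls, arr, N: int) -> "NetworkState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (3 * N + 1,):
            raise ValueError(f"state vector must have length {3 * N + 1}, got {arr.shape}")
        cells = [
            CellState(arr[j], arr[N + j], arr[2 * N + j]) for j in range(N)
        ]
        return cls(cells, float(arr[3 * N]))


# ---------------------------------------------------------------------------
# coupling / feedback functions
# ---------------------------------------------------------------------------


def phi_fall(Ca, mu, Ca0):
    """Calcium feedback on the voltage dynamics: mu*Ca/(Ca + Ca0).

    Saturating Michaelis-Menten form, bounded by ``mu``, increasing in Ca.
    """
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("phi_fall requires Ca >= 0")
    if not Ca0 > 0:
        raise ValueError("phi_fall requires Ca0 > 0")
    return mu * Ca / (Ca + Ca0)


def phi_rise(x, lam, rhoCa, xon):
    """Activity-driven calcium influx: lam / (1 + exp(-rhoCa*(x - xon)))."""
    if not lam > 0:
        raise ValueError("phi_rise requires lam > 0")
    return lam / (1.0 + _safe_exp(-rhoCa * (np.asarray(x, dtype=float) - xon)))


def phi_syn(sigma, rho_syn, sigma_on):
    """Coupling activation sigmoid, 1/2 at sigma_on, bounded by 1."""
    return 1.0 / (1.0 + _safe_exp(-rho_syn * (np.asarray(sigma, dtype=float) - sigma_on)))


def phi_sigma(u, rho_sigma):
    """Reset activation sigmoid, 1/2 at u = 0, bounded by 1."""
    return 1.0 / (1.0 + _safe_exp(-rho_sigma * np.asarray(u, dtype=float)))


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def _cell_rhs_arrays(x, y, Ca, p: CellParams, drive, k=None):
    """Vectorized cell RHS on plain arrays (no validation); used by the
    integrators."""
    k = p.k if k is None else k
    dx = p.tau * (-y + 4.0 * x - x**3 - p.mu * Ca / (Ca + p.Ca0))
    dy = p.tau * p.eps * k * (p.a0 * x + p.a1 * y + p.a2 - drive)
    dca = p.tau * p.eps * (
        phi_rise(x, p.lam, p.rhoCa, p.xon) - (Ca - p.Cabas) / p.tauCa
    )
    return dx, dy, dca


def cell_rhs(state: CellState, p: CellParams, drive: float = 0.0) -> CellState:
    """Time derivative (per minute) of a single cell.

    ``drive`` is the coupling input eta_j * phi_syn(sigma); zero recovers
    the isolated cell.
    """
    if drive < 0:
        raise ValueError("drive must be >= 0")
    dx, dy, dca = _cell_rhs_arrays(state.x, state.y, state.Ca, p, drive)
    return CellState(float(dx), float(dy), float(dca))


def _network_rhs_flat(s: np.ndarray, p: NetworkParams, heaviside: bool = False) -> np.ndarray:
    """Network RHS on the flat state vector; the integration workhorse.

    With ``heaviside=True`` the two activation sigmoids are replaced by
    their infinite-slope (Heaviside) limits.
    """
    n = p.N
    c = p.cell
    x = s[0:n]
    y = s[n:2 * n]
    Ca = s[2 * n:3 * n]
    sigma = s[3 * n]
    if heaviside:
        psyn = 1.0 if sigma >= p.sigma_on else 0.0
        u = Ca.mean() - p.Cadesyn
        psig = 1.0 if u >= 0 else 0.0
    else:
        psyn = float(phi_syn(sigma, p.rho_syn, p.sigma_on))
        psig = float(phi_sigma(Ca.mean() - p.Cadesyn, p.rho_sigma))
    out = np.empty(3 * n + 1)
    dx, dy, dca = _cell_rhs_arrays(x, y, Ca, c, p.etaj * psyn, k=p.kj)
    out[0:n] = dx
    out[n:2 * n] = dy
    out[2 * n:3 * n] = dca
    out[3 * n] = c.tau * (p.delta * c.eps * sigma - p.gamma * (sigma - p.sigma0) * psig)
    return out


def network_rhs(state: NetworkState, p: NetworkParams, heaviside: bool = False) -> NetworkState:
    """Time derivative (per minute) of the full network state."""
    if state.N != p.N:
        raise ValueError(f"state has {state.N} cells but params expect {p.N}")
    ds = _network_rhs_flat(state.to_array(), p, heaviside=heaviside)
    return NetworkState.from_array(ds, p.N)


# ---------------------------------------------------------------------------
# phase-plane geometry
# ---------------------------------------------------------------------------


def critical_manifold_y(x, Ca, p: CellParams):
    """y-coordinate of the critical manifold (x-nullcline surface)
    y = 4x - x^3 - phi_fall(Ca)."""
    return 4.0 * np.asarray(x, dtype=float) - np.asarray(x, dtype=float) ** 3 - phi_fall(
        Ca, p.mu, p.Ca0
    )


def fold_x() -> tuple[float, float]:
    """x-coordinates of the two fold lines of the cubic, the roots of
    4 - 3x^2 = 0: (-2/sqrt(3), +2/sqrt(3))."""
    xf = 2.0 / math.sqrt(3.0)
    return (-xf, xf)


def _equilibrium_x_residual(x: float, p: CellParams, drive: float) -> float:
    """Scalar residual whose root gives the equilibrium x: substitute the
    Ca-nullcline Ca(x) and the critical manifold into the y-nullcline."""
    ca = p.tauCa * float(phi_rise(x, p.lam, p.rhoCa, p.xon)) + p.Cabas
    y = float(critical_manifold_y(x, ca, p))
    return p.a0 * x + p.a1 * y + p.a2 - drive


def equilibrium(p: CellParams, drive: float = 0.0, bracket=(-3.0, 3.0)) -> CellState:
    """Unique rest point of the single cell under a constant drive.

    Solves simultaneously the y-nullcline, the critical manifold and the
    Ca-nullcline by one-dimensional root finding in x.  Raises if the
    residual does not change sign over the bracket (which signals a
    parameter set violating the uniqueness invariant on a1).
    """
    from scipy.optimize import brentq

    lo, hi = bracket
    flo = _equilibrium_x_residual(lo, p, drive)
    fhi = _equilibrium_x_residual(hi, p, drive)
    if flo * fhi > 0:
        raise ValueError(
            "no sign change of the equilibrium residual on "
            f"[{lo}, {hi}]; check the a1 invariant"
        )
    x = brentq(_equilibrium_x_residual, lo, hi, args=(p, drive), xtol=1e-13, rtol=8.9e-16)
    ca = p.tauCa * float(phi_rise(x, p.lam, p.rhoCa, p.xon)) + p.Cabas
    y = float(critical_manifold_y(x, ca, p))
    return CellState(float(x), y, ca)


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

Regime = Literal["relaxation", "mmo", "steady"]

#: Ca excursions above baseline + this threshold (nM) count as large peaks.
PEAK_THRESHOLD_NM = 100.0
#: Final-window Ca amplitude below this (nM) counts as a steady state.
STEADY_AMPLITUDE_NM = 1.0


def regime_of(
    p: CellParams,
    burn_in: float = 50.0,
    T: float = 150.0,
    window_frac: float = 0.5,
) -> Regime:
    """Classify the attractor of the single cell by simulation.

    * ``relaxation`` -- periodic large calcium peaks with no sub-threshold
      oscillation interval between them (low mu).
    * ``mmo`` -- large peaks separated by small oscillations of x near the
      lower fold (intermediate mu); the small oscillations produce the
      quiescent phase of the calcium pattern.
    * ``steady`` -- after a transient excursion the trajectory settles at
      the stable equilibrium (high mu).

    The trace is integrated for ``burn_in + T`` minutes starting just off
    the drive-free equilibrium and the final ``window_frac`` of the
    post-burn-in trace is analysed.  Large peak: Ca exceeding
    baseline + 100 nM.  Steady: window Ca amplitude < 1 nM.  MMO: large
    peaks present and at least one sub-threshold local maximum of x
    (x < 0, i.e. short of a full excursion to the right sheet) between
    consecutive peaks.  The window must be long enough to hold at least
    two peaks at the slow periods reached near the regime boundaries
    (IPIs beyond 20 min); the defaults leave a 75-min window.
    """
    from scipy.signal import find_peaks

    from .simulate import simulate_cell

    traj = simulate_cell(p, T=T, burn_in=burn_in)
    t, x, ca = traj.t, traj.x[:, 0], traj.ca[:, 0]
    n = t.size
    w = slice(int((1.0 - window_frac) * n), n)
    xx, cc = x[w], ca[w]
    if cc.max() - cc.min() < STEADY_AMPLITUDE_NM:
        return "steady"
    big = cc > p.Cabas + PEAK_THRESHOLD_NM
    flips = np.diff(big.astype(np.int8))
    up = np.flatnonzero(flips == 1)
    down = np.flatnonzero(flips == -1)
    if up.size < 2:
        # at most one excursion left in the window: converging transient
        return "steady"
    peak_idx = []
    for i0 in up:
        after = down[down > i0]
        if after.size == 0:
            break
        peak_idx.append(i0 + int(np.argmax(cc[i0:after[0] + 1])))
    local_max, _ = find_peaks(xx, prominence=1e-3)
    sub = local_max[xx[local_max] < 0.0]
    for i1, i2 in zip(peak_idx[:-1], peak_idx[1:]):
        if np.any((sub > i1) & (sub < i2)):
            return "mmo"
    return "relaxation"


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: network-level constants of the two reference network regimes
_NETWORK_PRESETS = {
    # full synchronization every ~60 min, all cells recruited
    "table2-full-sync": dict(
        delta=0.05, gamma=20.0, eta=3.0, Cadesyn=350.0,
        rho_syn=5.0, rho_sigma=30.0, sigma_on=60.0, sigma0=0.1,
    ),
    # weak coupling + slow reset: synchronization episodes come as doublets
    "table3-doublets": dict(
        delta=0.05, gamma=0.3, eta=1.12, Cadesyn=380.0,
        rho_syn=5.0, rho_sigma=30.0, sigma_on=60.0, sigma0=0.1,
    ),
}

PRESET_NAMES = ("table1",) + tuple(_NETWORK_PRESETS)


def cell_preset(name: str = "table1") -> CellParams:
    """Reference single-cell parameter set."""
    if name != "table1":
        raise KeyError(f"unknown cell preset {name!r}")
    return CellParams()


def network_preset(
    name: str,
    N: int = 50,
    kj: np.ndarray | None = None,
    etaj: np.ndarray | None = None,
    cell: CellParams | None = None,
) -> NetworkParams:
    """Reference network parameter sets.

    ``kj`` defaults to all ones and ``etaj`` to the preset's uniform
    coupling sensitivity; pass vectors from
    :func:`gnrhsync.simulate.sample_heterogeneity` for heterogeneous runs.
    """
    if name not in _NETWORK_PRESETS:
        raise KeyError(
            f"unknown network preset {name!r}; known: {sorted(_NETWORK_PRESETS)}"
        )
    spec = _NETWORK_PRESETS[name]
    kj = np.ones(N) if kj is None else np.asarray(kj, dtype=float)
    etaj = np.full(N, spec["eta"]) if etaj is None else np.asarray(etaj, dtype=float)
    return NetworkParams(
        cell=cell if cell is not None else cell_preset(),
        N=N,
        kj=kj,
        etaj=etaj,
        delta=spec["delta"],
        gamma=spec["gamma"],
        sigma0=spec["sigma0"],
        sigma_on=spec["sigma_on"],
        rho_syn=spec["rho_syn"],
        rho_sigma=spec["rho_sigma"],
        Cadesyn=spec["Cadesyn"],
    )
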