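"""Numerical integration of the cell and network systems.

The dynamics is stiff (time-scale separation eps = 0.06 combined with steep
activation sigmoids), so trajectories are integrated with a stiff-capable
multistep method (LSODA) at tight local-error tolerances; the
canard-sensitive small oscillations between calcium peaks are lost at loose
tolerances.  Output is resampled onto a uniform grid fine enough (0.01 min)
to resolve peak times to better than a second, and upward crossings of the
synchronization threshold sigma_on are located by the integrator's event
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    CellParams,
    CellState,
    NetworkParams,
    NetworkState,
    _network_rhs_flat,
    _cell_rhs_arrays,
    equilibrium,
)

__all__ = [
    "Trajectory",
    "HeterogeneitySpec",
    "SolverSettings",
    "sample_heterogeneity",
    "default_initial_condition",
    "simulate_cell",
    "simulate_network",
]

#: default output grid spacing, minutes
GRID_DT = 0.01


class SolverError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_t: float):
        super().__init__(f"{message} (last valid time {last_t:.4f} min)")
        self.last_t = last_t


@dataclass
class SolverSettings:
    """Integration accuracy contract.

    atol is per-variable: the dimensionless x and y are resolved to 1e-10,
    calcium (hundreds of nM) to 1e-6 nM, sigma to 1e-8.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol_xy: float = 1e-10
    atol_ca: float = 1e-6
    atol_sigma: float = 1e-8
    max_step: float = 1.0
    grid_dt: float = GRID_DT

    def atol_cell(self) -> np.ndarray:
        return np.array([self.atol_xy, self.atol_xy, self.atol_ca])

    def atol_network(self, N: int) -> np.ndarray:
        atol = np.empty(3 * N + 1)
        atol[: 2 * N] = self.atol_xy
        atol[2 * N: 3 * N] = self.atol_ca
        atol[3 * N] = self.atol_sigma
        return atol

    def to_dict(self) -> dict:
        return {
            "method": self.method, "rtol": self.rtol, "atol_xy": self.atol_xy,
            "atol_ca": self.atol_ca, "atol_sigma": self.atol_sigma,
            "max_step": self.max_step, "grid_dt": self.grid_dt,
        }


@dataclass
class Trajectory:
    """Time-stamped state series on a uniform grid (time in minutes).

    ``x``, ``y``, ``ca`` have shape (n_times, n_cells); single-cell runs
    are stored as one-cell networks.  ``sigma`` and ``mean_ca`` are present
    for network runs, ``sigma_crossings`` holds the event-located times at
    which sigma crossed sigma_on upward.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ca: np.ndarray
    sigma: np.ndarray | None = None
    sigma_crossings: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.x.shape != (self.t.size, self.n_cells):
            raise ValueError("state arrays must have shape (n_times, n_cells)")

    @property
    def n_cells(self) -> int:
        return self.ca.shape[1]

    @property
    def mean_ca(self) -> np.ndarray:
        return self.ca.mean(axis=1)

    def cell(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(t, Ca) series of cell j."""
        return self.t, self.ca[:, j]

    # -- tidy CSV round trip ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        n, m = self.t.size, self.n_cells
        return pd.DataFrame(
            {
                "t": np.tile(self.t, m),
                "cell_id": np.repeat(np.arange(m), n),
                "x": self.x.T.ravel(),
                "y": self.y.T.ravel(),
                "Ca": self.ca.T.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        """Tidy per-cell series as CSV (gzip if the suffix says so); the
        global sigma / mean-Ca series go to a companion ``*_global`` file."""
        path = str(path)
        self.to_frame().to_csv(path, index=False)
        if self.sigma is not None:
            gpath = _global_path(path)
            pd.DataFrame(
                {"t": self.t, "sigma": self.sigma, "mean_Ca": self.mean_ca}
            ).to_csv(gpath, index=False)

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        path = str(path)
        df = pd.read_csv(path)
        cells = np.unique(df["cell_id"].to_numpy())
        t = df.loc[df["cell_id"] == cells[0], "t"].to_numpy()
        n, m = t.size, cells.size
        x = np.empty((n, m))
        y = np.empty((n, m))
        ca = np.empty((n, m))
        for i, cid in enumerate(cells):
            sub = df[df["cell_id"] == cid]
            x[:, i] = sub["x"].to_numpy()
            y[:, i] = sub["y"].to_numpy()
            ca[:, i] = sub["Ca"].to_numpy()
        sigma = None
        import os

        gpath = _global_path(path)
        if os.path.exists(gpath):
            g = pd.read_csv(gpath)
            sigma = g["sigma"].to_numpy()
        return cls(t=t, x=x, y=y, ca=ca, sigma=sigma)


def _global_path(path: str) -> str:
    for suffix in (".csv.gz", ".csv"):
        if path.endswith(suffix):
            return path[: -len(suffix)] + "_global" + suffix
    return path + "_global"


# ---------------------------------------------------------------------------
# heterogeneity and initial conditions
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneitySpec:
    """Random per-cell parameter law: kj ~ U[k_low, k_high] and etaj either
    constant, uniform on eta_bounds, or user-supplied."""

    k_low: float = 0.8
    k_high: float = 1.2
    eta_mode: Literal["constant", "uniform", "explicit"] = "constant"
    eta_value: float = 3.0
    eta_bounds: tuple[float, float] = (0.0, 3.0)
    eta_vector: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.k_low <= self.k_high:
            raise ValueError("need 0 <= k_low <= k_high")
        if self.eta_mode == "uniform" and not (
            0 <= self.eta_bounds[0] <= self.eta_bounds[1]
        ):
            raise ValueError("eta_bounds must be ordered and non-negative")


def sample_heterogeneity(
    spec: HeterogeneitySpec, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (kj, etaj) for N cells; deterministic given ``spec.seed``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(spec.seed)
    kj = rng.uniform(spec.k_low, spec.k_high, N)
    if spec.eta_mode == "constant":
        etaj = np.full(N, float(spec.eta_value))
    elif spec.eta_mode == "uniform":
        etaj = rng.uniform(spec.eta_bounds[0], spec.eta_bounds[1], N)
    elif spec.eta_mode == "explicit":
        etaj = np.asarray(spec.eta_vector, dtype=float)
        if etaj.shape != (N,):
            raise ValueError(f"eta_vector must have shape ({N},), got {etaj.shape}")
    else:
        raise ValueError(f"unknown eta_mode {spec.eta_mode!r}")
    return kj, etaj


def default_initial_condition(
    p: NetworkParams,
    seed: int | None = 0,
    phase_spread: float = 30.0,
    sigma_factor: float = 1.01,
) -> NetworkState:
    """Desynchronized starting state.

    sigma starts just above its reset value (sigma_factor * sigma0).  Each
    cell is placed at the drive-free rest point with calcium forced to the
    baseline (just below the lower fold, which launches one excursion) and
    is then integrated alone for a random burn-in time ~ U[0, phase_spread]
    minutes so that the population starts spread over its oscillation
    phases.  ``phase_spread=0`` (or ``seed=None``) puts every cell at the
    same state.
    """
    eq = equilibrium(p.cell, drive=0.0)
    base = CellState(eq.x, eq.y, p.cell.Cabas)
    cells = []
    if seed is None or phase_spread == 0.0:
        cells = [CellState(base.x, base.y, base.Ca) for _ in range(p.N)]
    else:
        rng = np.random.default_rng(seed)
        burns = rng.uniform(0.0, phase_spread, p.N)
        settings = SolverSettings()
        for j in range(p.N):
            cp = p.cell.replace(k=float(p.kj[j]))
            if burns[j] <= 0:
                cells.append(CellState(base.x, base.y, base.Ca))
                continue
            sol = solve_ivp(
                lambda t, s: np.array(
                    _cell_rhs_arrays(s[0], s[1], s[2], cp, 0.0)
                ),
                (0.0, burns[j]),
                base.to_array(),
                method=settings.method,
                rtol=settings.rtol,
                atol=settings.atol_cell(),
            )
            if sol.status != 0:
                raise SolverError("cell burn-in failed", float(sol.t[-1]))
            cells.append(CellState.from_array(sol.y[:, -1]))
    return NetworkState(cells=cells, sigma=sigma_factor * p.sigma0)


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------


def simulate_cell(
    p: CellParams,
    T: float,
    ic: CellState | None = None,
    settings: SolverSettings | None = None,
    burn_in: float = 0.0,
    drive: float = 0.0,
) -> Trajectory:
    """Integrate one cell for ``burn_in + T`` minutes and return the final
    ``T`` minutes with time restarted at zero.

    The default initial condition is the drive-free rest point with calcium
    set to the baseline, i.e. a state just below the lower fold.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    settings = settings or SolverSettings()
    if ic is None:
        eq = equilibrium(p, drive=drive)
        ic = CellState(eq.x, eq.y, p.Cabas)
    t_end = burn_in + T
    t_eval = np.arange(0.0, t_end + settings.grid_dt / 2, settings.grid_dt)
    sol = solve_ivp(
        lambda t, s: np.array(_cell_rhs_arrays(s[0], s[1], s[2], p, drive)),
        (0.0, t_end),
        ic.to_array(),
        method=settings.method,
        rtol=settings.rtol,
        atol=settings.atol_cell(),
        t_eval=t_eval,
        max_step=settings.max_step,
    )
    if sol.status != 0:
        raise SolverError("single-cell integration failed", float(sol.t[-1]))
    keep = sol.t >= burn_in
    t = sol.t[keep] - burn_in
    return Trajectory(
        t=t,
        x=sol.y[0, keep][:, None],
        y=sol.y[1, keep][:, None],
        ca=sol.y[2, keep][:, None],
        meta={
            "kind": "cell",
            "T": T,
            "burn_in": burn_in,
            "drive": drive,
            "solver": settings.to_dict(),
        },
    )


def simulate_network(
    p: NetworkParams,
    T: float,
    ic: NetworkState | None = None,
    settings: SolverSettings | None = None,
    seed: int | None = 0,
    dense: bool = True,
    heaviside: bool = False,
) -> Trajectory:
    """Integrate the 3N+1 dimensional network system for ``T`` minutes.

    Records per-cell series plus sigma, and locates every upward crossing
    of sigma through sigma_on with the solver's event detection (the
    crossing times are exact to solver tolerance, far better than the
    output grid).  ``ic`` defaults to
    :func:`default_initial_condition` with the given seed.  With
    ``dense=False`` only the event times and the final state are kept,
    which is considerably faster for long scans.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    settings = settings or SolverSettings()
    if ic is None:
        ic = default_initial_condition(p, seed=seed)
    if ic.N != p.N:
        raise ValueError(f"initial condition has {ic.N} cells, params expect {p.N}")

    n = p.N

    def rhs(t, s):
        return _network_rhs_flat(s, p, heaviside=heaviside)

    def crossing(t, s):
        return s[3 * n] - p.sigma_on

    crossing.direction = 1

    t_eval = (
        np.arange(0.0, T + settings.grid_dt / 2, settings.grid_dt) if dense else None
    )
    sol = solve_ivp(
        rhs,
        (0.0, T),
        ic.to_array(),
        method=settings.method,
        rtol=settings.rtol,
        atol=settings.atol_network(n),
        t_eval=t_eval,
        events=crossing,
        max_step=settings.max_step,
    )
    if sol.status == -1:
        raise SolverError("network integration failed", float(sol.t[-1]))
    t = sol.t
    y = sol.y
    return Trajectory(
        t=t,
        x=y[0:n].T.copy(),
        y=y[n:2 * n].T.copy(),
        ca=y[2 * n:3 * n].T.copy(),
        sigma=y[3 * n].copy(),
        sigma_crossings=sol.t_events[0].copy(),
        meta={
            "kind": "network",
            "N": n,
            "T": T,
            "seed": seed,
            "heaviside": heaviside,
            "solver": settings.to_dict(),
        },
    )
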