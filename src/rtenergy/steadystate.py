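"""Steady-state location, linear stability, and uniqueness probing.

The model spans ~7 orders of magnitude across its variables and is
stiff, so cold-start root finding is unreliable.  Steady states are
therefore located in two phases: integrate from the guess until the
state stops changing over a doubling of the time horizon, then polish
with a damped Newton iteration on the analytic Jacobian.  Residuals
are reported relative to the gross flux through each balance equation,
which makes the convergence criterion meaningful across the disparate
variable scales.

In the Alu-free reduced variant the frozen variables (``mS``, ``bS``,
``S``) are excluded from the Newton system and from the spectrum, so
stability statements refer to the 9 active degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._symjac import jacobian_array
from .dynamics import IntegrationError, simulate
from .model_core import (CellState, ParameterSet, REDUCED_FROZEN, STATE_NAMES,
                         equation_terms, rhs)

__all__ = [
    "SteadyStateResult",
    "find_steady_state",
    "jacobian",
    "assess_stability",
    "uniqueness_sweep",
    "residual_norm",
]

CONVERGENCE_RESIDUAL = 1e-9


@dataclass
class SteadyStateResult:
    """A located stationary solution and its linearisation.

    ``eigenvalues`` are those of the Jacobian restricted to the active
    variables (12 for the full model, 9 for the Alu-free variant).
    ``residual_norm`` is the largest |d/dt| relative to the gross flux
    of its equation.
    """

    state: CellState
    residual_norm: float
    eigenvalues: np.ndarray
    stable: bool
    converged: bool
    reduced: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "state": {n: getattr(self.state, n) for n in STATE_NAMES},
            "residual_norm": self.residual_norm,
            "eigenvalues": [[float(ev.real), float(ev.imag)] for ev in self.eigenvalues],
            "stable": bool(self.stable),
            "converged": bool(self.converged),
            "reduced": bool(self.reduced),
        }


def _active_indices(reduced: bool) -> list[int]:
    return [i for i in range(12) if not (reduced and i in REDUCED_FROZEN)]


def residual_norm(y: np.ndarray, p: ParameterSet, reduced: bool = False) -> float:
    """Max over equations of |sum of terms| / sum of |terms|."""
    terms = equation_terms(y, p, reduced=reduced)
    worst = 0.0
    for i in _active_indices(reduced):
        gross = sum(abs(t) for t in terms[i])
        if gross > 0:
            worst = max(worst, abs(sum(terms[i])) / gross)
    return float(worst)


def _newton_polish(y0: np.ndarray, p: ParameterSet, reduced: bool,
                   max_iter: int = 60) -> tuple[np.ndarray, float, bool]:
    """Damped Newton iteration on the active subsystem."""
    idx = _active_indices(reduced)
    y = np.maximum(np.array(y0, dtype=float), 0.0)
    res = residual_norm(y, p, reduced)
    for _ in range(max_iter):
        if res <= 1e-13:
            break
        f = rhs(y, p, reduced=reduced)[idx]
        J = jacobian_array(y, p, reduced=reduced)[np.ix_(idx, idx)]
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return y, res, False
        if not np.all(np.isfinite(step)):
            return y, res, False
        # Backtrack until the scaled residual decreases and the state
        # stays (essentially) nonnegative.
        lam, improved = 1.0, False
        scale = np.maximum(np.abs(y[idx]), 1.0)
        for _ in range(40):
            y_try = y.copy()
            y_try[idx] = y[idx] + lam * step
            if np.all(y_try[idx] >= -1e-9 * scale):
                y_try = np.maximum(y_try, 0.0)
                res_try = residual_norm(y_try, p, reduced)
                if res_try < res:
                    y, res, improved = y_try, res_try, True
                    break
            lam *= 0.5
        if not improved:
            break
    return y, res, res <= CONVERGENCE_RESIDUAL


def _integrate_to_rest(y0: np.ndarray, p: ParameterSet, reduced: bool,
                       t_first: float = 200.0, rel_tol: float = 1e-10,
                       max_doublings: int = 32) -> np.ndarray:
    """Integrate until the relative state change over a doubling of the
    total time falls below ``rel_tol``."""
    y = np.maximum(np.array(y0, dtype=float), 0.0)
    span = t_first
    for _ in range(max_doublings):
        # atol well below the nonnegativity floor so integration noise
        # near zero never trips the post-hoc validation
        traj = simulate(p, CellState.from_array(y), span, reduced=reduced,
                        dense=False, atol_fraction=1e-9)
        y_new = np.maximum(traj.states[-1], 0.0)
        if np.any(y_new > 1e30):
            raise IntegrationError("state diverged during steady-state search",
                                   last_time=float(traj.times[-1]))
        denom = np.maximum(np.abs(y_new), 1e-12 * np.max(np.abs(y_new)) + 1e-300)
        rel = float(np.max(np.abs(y_new - y) / denom))
        y = y_new
        if rel < rel_tol:
            break
        span *= 2.0
    return y


def find_steady_state(p: ParameterSet, guess: CellState,
                      reduced: bool = False, warm: bool = False) -> SteadyStateResult:
    """Locate a stationary solution starting from ``guess``.

    The default path integrates the model from the guess until it
    settles, then polishes by damped Newton.  With ``warm=True`` the
    Newton polish is attempted directly first (useful inside parameter
    scans where the previous solution is an excellent guess), falling
    back to the full two-phase search if it fails.
    """
    y0 = guess.to_array()
    message = ""
    if warm:
        y, res, ok = _newton_polish(y0, p, reduced)
        if not ok:
            y_rest = _integrate_to_rest(y0, p, reduced)
            y, res, ok = _newton_polish(y_rest, p, reduced)
            message = "warm polish failed; fell back to integration"
    else:
        y_rest = _integrate_to_rest(y0, p, reduced)
        y, res, ok = _newton_polish(y_rest, p, reduced)

    idx = _active_indices(reduced)
    J = jacobian_array(y, p, reduced=reduced)[np.ix_(idx, idx)]
    eig = np.linalg.eigvals(J)
    stable = bool(np.all(eig.real < 0))
    return SteadyStateResult(
        state=CellState.from_array(np.maximum(y, 0.0)),
        residual_norm=res, eigenvalues=eig, stable=stable,
        converged=ok, reduced=reduced, message=message,
    )


def jacobian(state: CellState, p: ParameterSet, reduced: bool = False) -> np.ndarray:
    """Analytic 12x12 Jacobian of the right-hand side at a state.

    Frozen rows of the reduced variant are identically zero.
    """
    return jacobian_array(state.to_array(), p, reduced=reduced)


def assess_stability(ss: SteadyStateResult) -> tuple[bool, dict]:
    """Linear stability verdict for a converged steady state.

    Returns the stability flag and a report containing the leading
    (largest real part) eigenvalue and the full spectrum.
    """
    if not ss.converged:
        raise ValueError("stability assessment requires a converged steady state")
    eig = np.asarray(ss.eigenvalues)
    leading = eig[np.argmax(eig.real)]
    report = {
        "stable": bool(np.all(eig.real < 0)),
        "leading_eigenvalue": complex(leading),
        "eigenvalues": eig,
        "n_active": eig.size,
    }
    return report["stable"], report


def _states_match(x: np.ndarray, y: np.ndarray, rel: float = 1e-3) -> bool:
    # Relative comparison for entries above 1 m.p.c., absolute below.
    for xi, yi in zip(x, y):
        big = max(abs(xi), abs(yi))
        if big > 1.0:
            if abs(xi - yi) / big > rel:
                return False
        elif abs(xi - yi) > rel:
            return False
    return True


def uniqueness_sweep(p: ParameterSet, n_starts: int, seed: int,
                     reduced: bool = False,
                     ref: CellState | None = None,
                     decades: float = 2.0) -> list[SteadyStateResult]:
    """Probe uniqueness by solving from randomized nonnegative starts.

    Starts are drawn log-uniformly within ``±decades`` decades of the
    reference state, per variable, with a fixed seed.  Converged
    results are clustered at 0.1% relative tolerance; one
    representative per cluster is returned.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    from .model_core import reference_state
    base = (ref or reference_state()).to_array()
    rng = np.random.default_rng(seed)
    distinct: list[SteadyStateResult] = []
    for _ in range(n_starts):
        factors = 10.0 ** rng.uniform(-decades, decades, size=12)
        start = base * factors
        if reduced:
            start[list(REDUCED_FROZEN)] = 0.0
        result = find_steady_state(p, CellState.from_array(start), reduced=reduced)
        if not result.converged:
            continue
        y = result.state.to_array()
        if not any(_states_match(y, d.state.to_array()) for d in distinct):
            distinct.append(result)
    return distinct
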