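"""Response of the stationary ATP level to parameter changes.

Local sensitivity is quantified by response coefficients — partial
derivatives of the stationary ATP count with respect to each model
parameter at the reference steady state — computed by central finite
differences with steady-state re-solves on each side.  Because the
parameters span ~12 orders of magnitude, ranking claims are made on
elasticities (derivatives normalised by ``p_ref/a_ref``), which are
dimensionless; the raw derivatives are reported alongside.

Nonlinear behaviour is probed by 1D and 2D fold-change scans of the
stationary ATP level, and by the inverse query: the fold change of one
parameter needed to bring stationary ATP down to a target fraction of
its reference value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import CellState, ParameterSet
from .steadystate import SteadyStateResult, find_steady_state

__all__ = [
    "ResponseEntry",
    "ResponseReport",
    "ScanResult",
    "SCANNABLE_PARAMETERS",
    "RTE_PARAMETERS",
    "response_coefficients",
    "scan_parameter",
    "scan_parameter_pair",
    "fold_to_reach_fraction",
]

#: Parameters probed by the sensitivity analysis: every model constant
#: except the calibration targets (a_wt, L_wt, S_wt), which are inputs
#: to parameter fitting, not model constants.  V_cell is metadata and
#: is kept to demonstrate a vanishing response.
SCANNABLE_PARAMETERS = tuple(
    n for n in ParameterSet.field_names() if n not in ("a_wt", "L_wt", "S_wt")
)

#: Parameters tied to the retrotransposon life cycle (element lengths,
#: transcription/translation/insertion kinetics of L1 and Alu, complex
#: formation and turnover, and deactivation).
RTE_PARAMETERS = (
    "NL", "NS", "chi_maxL", "chi_maxS", "K_chiL", "K_chiS", "K_L",
    "w_L", "w_S", "theta_L", "theta_S", "gamma_maxL", "K_gammaL",
    "k_bL", "k_uL", "k_subS", "k_subL",
    "d_mL", "d_mS", "d_cL", "d_O1", "d_bL", "d_bS",
    "lambda_L", "lambda_S",
)


@dataclass(frozen=True)
class ResponseEntry:
    name: str
    raw_derivative: float    # d a*/d p, mixed units
    elasticity: float        # (d a*/d p) * p_ref / a_ref, dimensionless
    sign: int                # sign of the response
    ok: bool = True          # False if a probe solve failed


@dataclass
class ResponseReport:
    entries: dict[str, ResponseEntry]
    a_ref: float

    def ranked(self, subset: tuple[str, ...] | None = None) -> list[ResponseEntry]:
        """Entries sorted by decreasing |elasticity|."""
        pool = self.entries.values() if subset is None else (
            self.entries[n] for n in subset if n in self.entries)
        return sorted((e for e in pool if e.ok),
                      key=lambda e: abs(e.elasticity), reverse=True)


@dataclass
class ScanResult:
    """Stationary ATP over a grid of parameter fold changes."""

    names: tuple[str, ...]
    folds: tuple[np.ndarray, ...]
    a_star: np.ndarray          # shape matches the fold grid(s)
    converged: np.ndarray
    a_ref: float

    def fraction(self) -> np.ndarray:
        return self.a_star / self.a_ref


def _solve_at(p: ParameterSet, guess: CellState, reduced: bool = False) -> SteadyStateResult:
    return find_steady_state(p, guess, reduced=reduced, warm=True)


def response_coefficients(p: ParameterSet, ref: SteadyStateResult,
                          rel_step: float = 1e-3,
                          names: tuple[str, ...] = SCANNABLE_PARAMETERS) -> ResponseReport:
    """Central-difference response coefficients at a converged reference.

    Each parameter is displaced by ``±rel_step`` relative and the
    steady state re-solved (warm-started from the reference).  A probe
    failure flags the entry instead of dropping it.
    """
    if not ref.converged:
        raise ValueError("reference steady state must be converged")
    a_ref = ref.state.a
    entries: dict[str, ResponseEntry] = {}
    for name in names:
        p0 = getattr(p, name)
        try:
            hi = _solve_at(p.with_updates(**{name: p0 * (1 + rel_step)}), ref.state)
            lo = _solve_at(p.with_updates(**{name: p0 * (1 - rel_step)}), ref.state)
            ok = hi.converged and lo.converged
            raw = (hi.state.a - lo.state.a) / (2 * rel_step * p0)
        except Exception:
            ok, raw = False, float("nan")
        elasticity = raw * p0 / a_ref if np.isfinite(raw) else float("nan")
        sign = 0 if not np.isfinite(raw) or raw == 0 else (1 if raw > 0 else -1)
        entries[name] = ResponseEntry(name=name, raw_derivative=raw,
                                      elasticity=elasticity, sign=sign, ok=ok)
    return ResponseReport(entries=entries, a_ref=a_ref)


def scan_parameter(p: ParameterSet, name: str, folds: np.ndarray,
                   ref: SteadyStateResult | None = None) -> ScanResult:
    """Stationary ATP at ``p[name] <- fold * reference`` over a grid.

    Grid points are solved warm-started from the previous point,
    ordered outward from fold = 1 for robustness.
    """
    folds = np.asarray(folds, dtype=float)
    if np.any(folds <= 0):
        raise ValueError("fold changes must be strictly positive")
    if ref is None:
        from .model_core import reference_state
        ref = find_steady_state(p, reference_state())
    p0 = getattr(p, name)
    a_star = np.full(folds.shape, np.nan)
    conv = np.zeros(folds.shape, dtype=bool)

    order = np.argsort(np.abs(np.log(folds)))  # outward from fold=1
    guess_below = guess_above = ref.state
    for i in order:
        fold = folds[i]
        guess = guess_below if fold < 1.0 else guess_above
        ss = _solve_at(p.with_updates(**{name: p0 * fold}), guess)
        a_star[i] = ss.state.a
        conv[i] = ss.converged
        if ss.converged:
            if fold < 1.0:
                guess_below = ss.state
            else:
                guess_above = ss.state
    return ScanResult(names=(name,), folds=(folds,), a_star=a_star,
                      converged=conv, a_ref=ref.state.a)


def scan_parameter_pair(p: ParameterSet, name1: str, name2: str,
                        folds1: np.ndarray, folds2: np.ndarray,
                        ref: SteadyStateResult | None = None) -> ScanResult:
    """Full factorial 2D fold-change scan, warm-started row-wise."""
    folds1 = np.asarray(folds1, dtype=float)
    folds2 = np.asarray(folds2, dtype=float)
    if np.any(folds1 <= 0) or np.any(folds2 <= 0):
        raise ValueError("fold changes must be strictly positive")
    if ref is None:
        from .model_core import reference_state
        ref = find_steady_state(p, reference_state())
    p1, p2 = getattr(p, name1), getattr(p, name2)
    shape = (folds1.size, folds2.size)
    a_star = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)

    row_guess = ref.state
    order1 = np.argsort(np.abs(np.log(folds1)))
    order2 = np.argsort(np.abs(np.log(folds2)))
    for i in order1:
        guess = row_guess
        row_start = None
        for j in order2:
            pij = p.with_updates(**{name1: p1 * folds1[i], name2: p2 * folds2[j]})
            ss = _solve_at(pij, guess)
            a_star[i, j] = ss.state.a
            conv[i, j] = ss.converged
            if ss.converged:
                guess = ss.state
                if row_start is None:
                    row_start = ss.state
        if row_start is not None:
            row_guess = row_start
    return ScanResult(names=(name1, name2), folds=(folds1, folds2),
                      a_star=a_star, converged=conv, a_ref=ref.state.a)


def fold_to_reach_fraction(p: ParameterSet, name: str, fraction: float,
                           direction: str, ref: SteadyStateResult | None = None,
                           tol: float = 1e-3, fold_limit: float = 1e3) -> float:
    """Fold change of ``name`` at which stationary ATP equals
    ``fraction`` of its reference value.

    ``direction`` is ``"increase"`` (bracket fold > 1) or
    ``"decrease"`` (fold < 1).  The bracket is expanded geometrically
    from 1 and then bisected on the log-fold until
    ``|a*/a_ref - fraction| < tol``.
    """
    if fraction == 1.0:
        return 1.0
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    if ref is None:
        from .model_core import reference_state
        ref = find_steady_state(p, reference_state())
    a_ref = ref.state.a
    p0 = getattr(p, name)
    step = 2.0 if direction == "increase" else 0.5

    def frac_at(fold: float, guess: CellState) -> tuple[float, CellState]:
        ss = _solve_at(p.with_updates(**{name: p0 * fold}), guess)
        return ss.state.a / a_ref, ss.state

    # Expand the bracket until the target fraction is straddled.
    lo_fold, lo_frac = 1.0, 1.0
    guess = ref.state
    fold = step
    while True:
        frc, guess = frac_at(fold, guess)
        if frc <= fraction:
            hi_fold, hi_frac = fold, frc
            break
        lo_fold, lo_frac = fold, frc
        fold *= step
        if not (1 / fold_limit <= fold <= fold_limit):
            raise RuntimeError(
                f"fraction {fraction} not reachable by scanning {name} "
                f"({direction}) within fold limits")

    # Bisect on log-fold.
    for _ in range(200):
        mid = float(np.sqrt(lo_fold * hi_fold))
        frc, guess = frac_at(mid, guess)
        if abs(frc - fraction) < tol:
            return mid
        if frc > fraction:
            lo_fold = mid
        else:
            hi_fold = mid
        if abs(np.log(hi_fold / lo_fold)) < 1e-12:
            return mid
    return float(np.sqrt(lo_fold * hi_fold))
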