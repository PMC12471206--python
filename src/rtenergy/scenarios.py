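"""Copy-number perturbation experiments and the Alu-free reduced model.

These are the model's in-silico analogues of genome-editing
interventions: multiply the initial number of genomic L1 or Alu copies
(all other variables at the reference steady state), follow the
transient, and measure how long and how deeply the ATP level falls
below the 30%-of-reference viability threshold.  The sweep over folds
maps the dose--response of the transient energy crisis; the threshold
fold is the smallest intervention that reaches the critical level at
all.

The Alu-free experiment removes the predator from the predator--prey
pair: without Alu competing for the ORF2p machinery, L1 settles at an
elevated stationary abundance and the stationary energy drops roughly
2.3-fold, illustrating that Alu activity implicitly protects the
energy balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import DropMetrics, Trajectory, drop_metrics, perturb_initial_state, simulate
from .model_core import CellState, ParameterSet, reference_state
from .steadystate import SteadyStateResult, find_steady_state

__all__ = [
    "CopyNumberSweep",
    "ReducedModelResult",
    "copy_number_sweep",
    "threshold_fold",
    "reduced_model_experiment",
    "scenario_trajectory",
]

#: Default integration horizon for scenario runs (min); extended x10
#: as needed until ATP has returned above threshold, up to 1e7 min.
SCENARIO_T_END = 1e4
SCENARIO_T_MAX = 1e7


@dataclass
class CopyNumberSweep:
    which_rte: str                  # "L1" or "Alu"
    folds: np.ndarray
    metrics: list[DropMetrics]
    a_ref: float
    threshold_fraction: float

    @property
    def T_drop(self) -> np.ndarray:
        return np.array([m.T_drop for m in self.metrics])

    @property
    def a_min(self) -> np.ndarray:
        return np.array([m.a_min for m in self.metrics])

    @property
    def crossed(self) -> np.ndarray:
        return np.array([m.crossed for m in self.metrics])


def _folds_for(which_rte: str, fold: float) -> tuple[float, float]:
    if which_rte == "L1":
        return fold, 1.0
    if which_rte == "Alu":
        return 1.0, fold
    raise ValueError("which_rte must be 'L1' or 'Alu'")


def scenario_trajectory(p: ParameterSet, which_rte: str, fold: float,
                        ref: CellState, threshold: float,
                        t_end: float = SCENARIO_T_END) -> Trajectory:
    """Simulate a copy-number scenario, extending the horizon tenfold
    (up to the cap) while ATP is still below threshold at the end."""
    fold_L1, fold_Alu = _folds_for(which_rte, fold)
    init = perturb_initial_state(ref, fold_L1=fold_L1, fold_Alu=fold_Alu)
    while True:
        traj = simulate(p, init, t_end, dense=True)
        if traj.values("a")[-1] >= threshold or t_end >= SCENARIO_T_MAX:
            return traj
        t_end *= 10.0


def _reference(p: ParameterSet,
               ref_ss: SteadyStateResult | None) -> SteadyStateResult:
    if ref_ss is None:
        ref_ss = find_steady_state(p, reference_state())
    if not ref_ss.converged:
        raise RuntimeError("reference steady state did not converge")
    return ref_ss


def copy_number_sweep(p: ParameterSet, which_rte: str, folds: np.ndarray,
                      threshold_fraction: float = 0.30,
                      ref_ss: SteadyStateResult | None = None) -> CopyNumberSweep:
    """Drop metrics for a grid of initial copy-number folds (each >= 1)."""
    folds = np.asarray(folds, dtype=float)
    if np.any(folds < 1):
        raise ValueError("sweep folds must be >= 1")
    ref_ss = _reference(p, ref_ss)
    a_ref = ref_ss.state.a
    thr = threshold_fraction * a_ref
    metrics = []
    for fold in folds:
        traj = scenario_trajectory(p, which_rte, float(fold), ref_ss.state, thr)
        metrics.append(drop_metrics(traj, threshold_fraction, a_ref))
    return CopyNumberSweep(which_rte=which_rte, folds=folds, metrics=metrics,
                           a_ref=a_ref, threshold_fraction=threshold_fraction)


def threshold_fold(p: ParameterSet, which_rte: str,
                   threshold_fraction: float = 0.30,
                   ref_ss: SteadyStateResult | None = None,
                   fold_tol: float = 0.05, fold_max: float = 1e5) -> float:
    """Smallest initial fold whose trajectory dips below the threshold.

    Log-fold bisection to a relative tolerance of ``fold_tol``; raises
    if even ``fold_max`` never crosses.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    ref_ss = _reference(p, ref_ss)
    a_ref = ref_ss.state.a
    thr = threshold_fraction * a_ref

    def crosses(fold: float) -> bool:
        traj = scenario_trajectory(p, which_rte, fold, ref_ss.state, thr)
        return drop_metrics(traj, threshold_fraction, a_ref).a_min < thr

    lo = 1.0  # the unperturbed reference never crosses
    hi = 10.0
    while not crosses(hi):
        lo = hi
        hi *= 10.0
        if hi > fold_max:
            raise RuntimeError(
                f"no crossing below {threshold_fraction:.0%} up to fold {fold_max:g}")
    while hi / lo > 1.0 + fold_tol:
        mid = float(np.sqrt(lo * hi))
        if crosses(mid):
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


@dataclass
class ReducedModelResult:
    full_ss: SteadyStateResult
    reduced_ss: SteadyStateResult
    trajectory: Trajectory
    energy_ratio: float     # a_ref / a_reduced
    L_reduced: float        # stationary L1 count in the Alu-free model


def reduced_model_experiment(p: ParameterSet,
                             ref_ss: SteadyStateResult | None = None,
                             t_end: float = 1e5) -> ReducedModelResult:
    """Run the Alu-free model from the full-model reference state.

    Alu and its products are removed (``mS = bS = S = 0``) and the
    dynamics followed to the reduced model's own steady state.
    """
    ref_ss = _reference(p, ref_ss)
    init = ref_ss.state.with_updates(mS=0.0, bS=0.0, S=0.0)
    traj = simulate(p, init, t_end, reduced=True, dense=False)
    reduced_ss = find_steady_state(p, traj.final_state(), reduced=True)
    if not reduced_ss.converged:
        raise RuntimeError("reduced-model steady state did not converge")
    return ReducedModelResult(
        full_ss=ref_ss, reduced_ss=reduced_ss, trajectory=traj,
        energy_ratio=ref_ss.state.a / reduced_ss.state.a,
        L_reduced=reduced_ss.state.L,
    )
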