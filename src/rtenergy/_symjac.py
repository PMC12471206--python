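"""Analytic Jacobian of the model right-hand side, derived symbolically.

The 12x12 Jacobian is built once per model variant (full / Alu-free)
with sympy and lambdified to a plain numpy function.  The symbolic
right-hand side mirrors :func:`rtenergy.model_core.rhs` without the
nonnegativity clamps, which is exact at admissible interior states
(``cq + cL < r_tot``, all variables > 0) — the regime in which the
Jacobian is consumed by the stiff integrator and the stability
analysis.  Agreement with central finite differences is enforced by
the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .model_core import ParameterSet, STATE_NAMES

_PARAM_NAMES = ParameterSet.field_names()


def _symbolic_rhs(reduced: bool):
    y = sp.symbols(" ".join(STATE_NAMES), positive=True)
    p = {name: sp.Symbol(name, positive=True) for name in _PARAM_NAMES}
    a, mq, cq, q, mL, mS, cL, O1, bL, bS, L, S = y

    omega_q = p["Q"] * p["w_q"] * a / (p["theta_q"] + a)
    omega_L = L * p["w_L"] * a / (p["theta_L"] + a)
    omega_S = S * p["w_S"] * a / (p["theta_S"] + a)

    frib = p["r_tot"] - cq - cL
    bind_q = p["k_bq"] * frib * mq
    bind_L = p["k_bL"] * frib * mL
    unbind_q = p["k_uq"] * cq
    unbind_L = p["k_uL"] * cL

    v_q = (p["gamma_maxq"] / p["Nq"]) * cq * a / (p["K_gammaq"] + a)
    v_L = (p["gamma_maxL"] / (p["NL"] / 3)) * cL * a / (p["K_gammaL"] + a)

    occ = p["K_L"] * O1 / (1 + p["K_L"] * O1)
    v_intL = (p["chi_maxL"] / p["NL"]) * bL * a / (p["K_chiL"] + a) * occ
    v_intS = (p["chi_maxS"] / p["NS"]) * bS * a / (p["K_chiS"] + a)

    sub_fwd = p["k_subS"] * mS * bL
    sub_rev = p["k_subL"] * mL * bS

    if reduced:
        omega_S = sp.Integer(0)
        v_intS = sp.Integer(0)
        sub_fwd = sp.Integer(0)
        sub_rev = sp.Integer(0)

    v_repl = p["Nnt"] * (p["Ng"] / p["tau"] + p["NL"] * v_intL + p["NS"] * v_intS)

    eqs = [
        p["A0"] - p["lambda_a"] * a - v_repl
        - p["Nnt"] * (p["NQ"] * omega_q + p["NL"] * omega_L + p["NS"] * omega_S)
        - p["Naa"] * (p["Nq"] * v_q + (p["NL"] / 3) * v_L)
        - p["Nnt"] * (p["NL"] * v_intL + p["NS"] * v_intS),
        omega_q - bind_q + unbind_q + v_q - p["d_mq"] * mq,
        bind_q - unbind_q - v_q - p["d_cq"] * cq,
        v_q - p["d_q"] * q,
        omega_L - bind_L + unbind_L + sub_fwd - sub_rev - p["d_mL"] * mL,
        omega_S - sub_fwd + sub_rev - p["d_mS"] * mS,
        bind_L - unbind_L - v_L - p["d_cL"] * cL,
        v_L - v_intL - p["d_O1"] * O1,
        v_L - v_intL - sub_fwd + sub_rev - p["d_bL"] * bL,
        sub_fwd - sub_rev - v_intS - p["d_bS"] * bS,
        v_intL - p["lambda_L"] * L,
        v_intS - p["lambda_S"] * S,
    ]
    if reduced:
        for i in (5, 9, 11):
            eqs[i] = sp.Integer(0)
    return y, [p[name] for name in _PARAM_NAMES], eqs


@lru_cache(maxsize=2)
def _jacobian_func(reduced: bool):
    y, psyms, eqs = _symbolic_rhs(reduced)
    jac = sp.Matrix(eqs).jacobian(sp.Matrix(y))
    return sp.lambdify(tuple(y) + tuple(psyms), jac, modules="numpy")


def _param_values(p: ParameterSet) -> tuple[float, ...]:
    return tuple(getattr(p, name) for name in _PARAM_NAMES)


def jacobian_array(y: np.ndarray, p: ParameterSet, reduced: bool = False) -> np.ndarray:
    """Analytic Jacobian d(rhs)/d(state) at a state vector, 12x12."""
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    func = _jacobian_func(bool(reduced))
    return np.asarray(func(*y, *_param_values(p)), dtype=float)
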