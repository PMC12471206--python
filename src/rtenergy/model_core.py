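"""Core kinetics of the retrotransposon bioenergetic model.

The model tracks the energy balance of a single "average" eukaryotic
cell through the number of free ATP molecules, coupled to the life
cycle of the two active human retrotransposon families: the autonomous
LINE-1 (L1) and the nonautonomous Alu (SINE).  Twelve concentrations,
all expressed in molecules per cell (m.p.c.), evolve under a constant
ATP influx ``A0`` and consumption by transcription, translation, new
retrotransposon insertions, basal DNA replication, and first-order
degradation.

Every ATP-consuming step follows Michaelis--Menten kinetics in the ATP
concentration ``a``; mRNA--ribosome binding and the exchange of L1/Alu
mRNA on the ORF2p reverse-transcriptase complex follow mass action.
Alu carries no coding capacity and hijacks the L1-encoded machinery:
the ``bS`` complex is formed only by substituting the Alu mRNA for the
L1 mRNA on the ``bL`` complex, which is what couples the two element
families into a predator--prey-like system.

An Alu-free reduced variant of the model (``reduced=True``) freezes
``mS``, ``bS`` and ``S`` and removes every Alu-related flux, while
sharing the same code path as the full system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ParameterSet",
    "CellState",
    "FluxVector",
    "STATE_NAMES",
    "REDUCED_FROZEN",
    "reference_state",
    "transcription_rate",
    "free_ribosomes",
    "translation_rate",
    "insertion_rate_L1",
    "insertion_rate_Alu",
    "replication_energy_rate",
    "fluxes",
    "rhs",
    "equation_terms",
]

#: Canonical ordering of the dynamical variables.
STATE_NAMES = ("a", "mq", "cq", "q", "mL", "mS", "cL", "O1", "bL", "bS", "L", "S")

#: Indices of the variables frozen in the Alu-free reduced model (mS, bS, S).
REDUCED_FROZEN = (5, 9, 11)

_STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class ParameterSet:
    """All model constants, defaulting to the published calibration.

    Units: lengths in bp or aa, counts in m.p.c., first-order rate
    constants in 1/min, bimolecular rate constants in 1/(m.p.c. min),
    ``K_L`` in 1/m.p.c.  ``V_cell`` is metadata (cell volume, um^3) and
    does not enter the dynamics; ``a_wt``, ``L_wt`` and ``S_wt`` are
    the wild-type calibration targets for stationary ATP, L1 and Alu
    counts.
    """

    Ng: float = 3.08e9          # human genome size, bp
    Q: float = 3804.0           # housekeeping gene count, m.p.c.
    A0: float = 1.31e10         # ATP influx, m.p.c./min
    tau: float = 1320.0         # cell-cycle duration, min
    Nq: float = 431.0           # median protein length, aa
    NQ: float = 1300.0          # median gene length, bp
    NL: float = 6000.0          # L1 length, bp
    NS: float = 300.0           # Alu length, bp
    Naa: float = 5.0            # ATP per amino acid
    Nnt: float = 15.0           # ATP per nucleotide
    chi_maxL: float = 840.0     # max nucleotide incorporation, L1 insertion, 1/min
    chi_maxS: float = 840.0     # max nucleotide incorporation, Alu insertion, 1/min
    K_chiL: float = 1.1e7       # Michaelis constant, L1 insertion, m.p.c.
    K_chiS: float = 1.1e7       # Michaelis constant, Alu insertion, m.p.c.
    K_L: float = 2.24e-3        # L1 mRNA--ORF1p association constant, 1/m.p.c.
    w_q: float = 4.64           # max transcription rate per housekeeping gene, 1/min
    w_L: float = 1.0            # max transcription rate per L1, 1/min
    w_S: float = 20.0           # max transcription rate per Alu, 1/min
    theta_q: float = 3.8e9      # transcription Michaelis constant (hk), m.p.c.
    theta_L: float = 3.8e9      # transcription Michaelis constant (L1), m.p.c.
    theta_S: float = 3.8e9      # transcription Michaelis constant (Alu), m.p.c.
    gamma_maxq: float = 300.0   # max translation rate (hk), aa/min
    gamma_maxL: float = 300.0   # max translation rate (L1), aa/min
    K_gammaq: float = 25900.0   # translation Michaelis constant (hk), m.p.c.
    K_gammaL: float = 25900.0   # translation Michaelis constant (L1), m.p.c.
    k_bq: float = 5e-8          # mRNA--ribosome binding (hk), 1/(m.p.c. min)
    k_bL: float = 5e-8          # mRNA--ribosome binding (L1), 1/(m.p.c. min)
    k_uq: float = 0.01          # mRNA--ribosome unbinding (hk), 1/min
    k_uL: float = 0.01          # mRNA--ribosome unbinding (L1), 1/min
    k_subS: float = 5e-8        # mL->mS substitution on ORF2p complex, 1/(m.p.c. min)
    k_subL: float = 5e-6        # mS->mL substitution on ORF2p complex, 1/(m.p.c. min)
    r_tot: float = 9.5e6        # total ribosomes, m.p.c.
    lambda_a: float = 1.47      # ATP degradation, 1/min
    d_mq: float = 1.15e-3       # degradation of hk mRNA, 1/min
    d_mL: float = 1.15e-3       # degradation of L1 mRNA, 1/min
    d_mS: float = 1.15e-3       # degradation of Alu mRNA, 1/min
    d_cq: float = 1.55e-3       # degradation of cq complex, 1/min
    d_cL: float = 1.55e-3       # degradation of cL complex, 1/min
    d_q: float = 5.67e-4        # degradation of hk protein, 1/min
    d_O1: float = 5.67e-4       # degradation of ORF1p, 1/min
    d_bL: float = 5.67e-4       # degradation of bL complex, 1/min
    d_bS: float = 5.67e-4       # degradation of bS complex, 1/min
    lambda_L: float = 0.37      # L1 deactivation, 1/min
    lambda_S: float = 1.18      # Alu deactivation, 1/min
    V_cell: float = 3700.0      # cell volume, um^3 (metadata)
    a_wt: float = 5.33e9        # wild-type ATP count, m.p.c. (calibration target)
    L_wt: float = 1064.0        # wild-type active L1 count, m.p.c. (calibration target)
    S_wt: float = 13243.0       # wild-type active Alu count, m.p.c. (calibration target)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} is not finite: {v}")
            if v <= 0:
                raise ValueError(f"parameter {f.name!r} must be strictly positive, got {v}")

    def with_updates(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


#: Names of the free parameters re-estimated by numerical optimisation.
FREE_PARAMETER_NAMES = (
    "k_bq", "k_bL", "k_uq", "k_uL", "k_subS", "k_subL",
    "lambda_a", "d_cq", "d_cL", "lambda_L", "lambda_S",
)


@dataclass(frozen=True)
class CellState:
    """The 12 dynamical concentrations, in molecules per cell."""

    a: float    # free ATP
    mq: float   # housekeeping mRNA
    cq: float   # housekeeping mRNA--ribosome complex
    q: float    # housekeeping protein
    mL: float   # L1 mRNA
    mS: float   # Alu mRNA
    cL: float   # L1 mRNA--ribosome complex
    O1: float   # ORF1p protein
    bL: float   # L1 mRNA--ORF2p complex (reverse transcriptase)
    bS: float   # Alu mRNA--ORF2p complex
    L: float    # active L1 copies in the genome
    S: float    # active Alu copies in the genome

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state variable {name!r} is not finite: {v}")
            if v < 0:
                raise ValueError(f"state variable {name!r} must be nonnegative, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        y = np.asarray(y, dtype=float)
        if y.shape != (12,):
            raise ValueError(f"expected a length-12 state vector, got shape {y.shape}")
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def with_updates(self, **kwargs: float) -> "CellState":
        return replace(self, **kwargs)


def reference_state() -> CellState:
    """Reference stationary solution: homeostatic energy balance with
    low retrotransposon activity, used as the starting point of every
    perturbation experiment."""
    return CellState(
        a=5.32e9, mq=5.44e6, cq=2.61e6, q=3.20e9,
        mL=5.13e4, mS=1.22e8, cL=1.8e5, O1=2.78e7,
        bL=2.83e3, bS=5.64e3, L=1.07e3, S=1.34e4,
    )


@dataclass(frozen=True)
class FluxVector:
    """Every elementary process rate evaluated at one state.

    Production/conversion rates are in m.p.c./min; ``v_repl`` is an ATP
    expenditure rate (ATP m.p.c./min).
    """

    omega_q: float
    omega_L: float
    omega_S: float
    v_q: float
    v_L: float
    v_intL: float
    v_intS: float
    v_repl: float
    bind_q: float
    bind_L: float
    unbind_q: float
    unbind_L: float
    sub_fwd: float
    sub_rev: float
    deg_a: float
    deg_mq: float
    deg_cq: float
    deg_q: float
    deg_mL: float
    deg_mS: float
    deg_cL: float
    deg_O1: float
    deg_bL: float
    deg_bS: float
    deg_L: float
    deg_S: float


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------

def transcription_rate(copies: float, w: float, theta: float, a: float) -> float:
    """Transcription rate ``copies * w * a / (theta + a)`` in m.p.c./min.

    ``copies`` is the number of active templates (fixed ``Q`` for
    housekeeping genes, the dynamic ``L`` or ``S`` for the elements),
    ``w`` the maximum per-copy initiation rate and ``theta`` the
    Michaelis constant of the ATP dependence.
    """
    if copies < 0 or w < 0 or theta < 0 or a < 0:
        raise ValueError("transcription_rate arguments must be nonnegative")
    return copies * w * a / (theta + a) if a > 0 else 0.0


def free_ribosomes(cq: float, cL: float, r_tot: float) -> float:
    """Concentration of ribosomes not sequestered in mRNA complexes,
    clamped at zero so binding fluxes stay nonnegative during extreme
    transients."""
    if cq < 0 or cL < 0:
        raise ValueError("complex concentrations must be nonnegative")
    return max(r_tot - cq - cL, 0.0)


def translation_rate(c: float, a: float, gamma_max: float,
                     protein_len: float, K_gamma: float) -> float:
    """Protein production rate from mRNA--ribosome complexes.

    The elongation rate ``gamma_max`` (aa/min) is scaled by the protein
    length to a per-complex completion rate: ``(gamma_max/protein_len)
    * c * a/(K_gamma + a)``.  Housekeeping proteins use the median
    length ``Nq``; the L1 protein length is ``NL/3`` (one amino acid
    per codon of the element sequence).
    """
    if protein_len <= 0:
        raise ValueError("protein_len must be strictly positive")
    if c < 0 or a < 0:
        raise ValueError("translation_rate arguments must be nonnegative")
    return (gamma_max / protein_len) * c * (a / (K_gamma + a) if a > 0 else 0.0)


def insertion_rate_L1(bL: float, O1: float, a: float, p: ParameterSet) -> float:
    """Rate of new genomic L1 insertions from the ``bL`` reverse-
    transcriptase complex.

    The single-nucleotide incorporation rate ``chi_maxL`` is scaled by
    the element length to a full-copy rate, with Michaelis--Menten ATP
    dependence and an ORF1p occupancy factor ``K_L*O1/(1 + K_L*O1)``
    (limited binding occupancy: insertion requires ORF1p but saturates
    in it).
    """
    if bL < 0 or O1 < 0 or a < 0:
        raise ValueError("insertion_rate_L1 arguments must be nonnegative")
    occ = p.K_L * O1 / (1.0 + p.K_L * O1)
    return (p.chi_maxL / p.NL) * bL * (a / (p.K_chiL + a) if a > 0 else 0.0) * occ


def insertion_rate_Alu(bS: float, a: float, p: ParameterSet) -> float:
    """Rate of new genomic Alu insertions from the ``bS`` complex;
    Alu needs no ORF1p, so there is no occupancy factor."""
    if bS < 0 or a < 0:
        raise ValueError("insertion_rate_Alu arguments must be nonnegative")
    return (p.chi_maxS / p.NS) * bS * (a / (p.K_chiS + a) if a > 0 else 0.0)


def replication_energy_rate(a: float, bL: float, O1: float, bS: float,
                            p: ParameterSet, reduced: bool = False) -> float:
    """ATP expenditure rate of DNA replication: the basal synthesis of
    a genome of ``Ng`` bp per cell cycle ``tau`` plus the extra
    nucleotides added by new retrotransposon insertions, at ``Nnt`` ATP
    per nucleotide."""
    v_iL = insertion_rate_L1(bL, O1, a, p)
    v_iS = 0.0 if reduced else insertion_rate_Alu(bS, a, p)
    return p.Nnt * (p.Ng / p.tau + p.NL * v_iL + p.NS * v_iS)


# ---------------------------------------------------------------------------
# Assembled fluxes and right-hand side
# ---------------------------------------------------------------------------

def _as_array(state: "CellState | np.ndarray") -> np.ndarray:
    if isinstance(state, CellState):
        return state.to_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (12,):
        raise ValueError(f"expected a length-12 state vector, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state vector contains non-finite entries")
    return y


def fluxes(state: "CellState | np.ndarray", p: ParameterSet,
           reduced: bool = False) -> FluxVector:
    """Evaluate every elementary rate of the model exactly once.

    The state is clipped at zero before evaluation, mirroring the
    integrator convention: tiny negative excursions of a stiff solver
    must not produce negative fluxes.
    """
    y = np.maximum(_as_array(state), 0.0)
    a, mq, cq, q, mL, mS, cL, O1, bL, bS, L, S = y

    omega_q = transcription_rate(p.Q, p.w_q, p.theta_q, a)
    omega_L = transcription_rate(L, p.w_L, p.theta_L, a)
    omega_S = 0.0 if reduced else transcription_rate(S, p.w_S, p.theta_S, a)

    frib = free_ribosomes(cq, cL, p.r_tot)
    bind_q = p.k_bq * frib * mq
    bind_L = p.k_bL * frib * mL
    unbind_q = p.k_uq * cq
    unbind_L = p.k_uL * cL

    v_q = translation_rate(cq, a, p.gamma_maxq, p.Nq, p.K_gammaq)
    v_L = translation_rate(cL, a, p.gamma_maxL, p.NL / 3.0, p.K_gammaL)

    v_intL = insertion_rate_L1(bL, O1, a, p)
    v_intS = 0.0 if reduced else insertion_rate_Alu(bS, a, p)
    v_repl = p.Nnt * (p.Ng / p.tau + p.NL * v_intL + p.NS * v_intS)

    sub_fwd = 0.0 if reduced else p.k_subS * mS * bL
    sub_rev = 0.0 if reduced else p.k_subL * mL * bS

    return FluxVector(
        omega_q=omega_q, omega_L=omega_L, omega_S=omega_S,
        v_q=v_q, v_L=v_L, v_intL=v_intL, v_intS=v_intS, v_repl=v_repl,
        bind_q=bind_q, bind_L=bind_L, unbind_q=unbind_q, unbind_L=unbind_L,
        sub_fwd=sub_fwd, sub_rev=sub_rev,
        deg_a=p.lambda_a * a, deg_mq=p.d_mq * mq, deg_cq=p.d_cq * cq,
        deg_q=p.d_q * q, deg_mL=p.d_mL * mL, deg_mS=p.d_mS * mS,
        deg_cL=p.d_cL * cL, deg_O1=p.d_O1 * O1, deg_bL=p.d_bL * bL,
        deg_bS=p.d_bS * bS, deg_L=p.lambda_L * L, deg_S=p.lambda_S * S,
    )


def equation_terms(state: "CellState | np.ndarray", p: ParameterSet,
                   reduced: bool = False) -> list[list[float]]:
    """Signed additive terms of each of the 12 balance equations.

    Summing each inner list gives the corresponding time derivative;
    the terms themselves are used to express steady-state residuals
    relative to the gross flux through each equation.
    """
    f = fluxes(state, p, reduced=reduced)
    terms = [
        # da/dt: influx minus degradation, replication, transcription,
        # translation and insertion (reverse-transcription) costs
        [p.A0, -f.deg_a, -f.v_repl,
         -p.Nnt * (p.NQ * f.omega_q + p.NL * f.omega_L + p.NS * f.omega_S),
         -p.Naa * (p.Nq * f.v_q + (p.NL / 3.0) * f.v_L),
         -p.Nnt * (p.NL * f.v_intL + p.NS * f.v_intS)],
        # dmq/dt
        [f.omega_q, -f.bind_q, f.unbind_q, f.v_q, -f.deg_mq],
        # dcq/dt
        [f.bind_q, -f.unbind_q, -f.v_q, -f.deg_cq],
        # dq/dt
        [f.v_q, -f.deg_q],
        # dmL/dt
        [f.omega_L, -f.bind_L, f.unbind_L, f.sub_fwd, -f.sub_rev, -f.deg_mL],
        # dmS/dt
        [f.omega_S, -f.sub_fwd, f.sub_rev, -f.deg_mS],
        # dcL/dt
        [f.bind_L, -f.unbind_L, -f.v_L, -f.deg_cL],
        # dO1/dt
        [f.v_L, -f.v_intL, -f.deg_O1],
        # dbL/dt
        [f.v_L, -f.v_intL, -f.sub_fwd, f.sub_rev, -f.deg_bL],
        # dbS/dt
        [f.sub_fwd, -f.sub_rev, -f.v_intS, -f.deg_bS],
        # dL/dt
        [f.v_intL, -f.deg_L],
        # dS/dt
        [f.v_intS, -f.deg_S],
    ]
    if reduced:
        for i in REDUCED_FROZEN:
            terms[i] = [0.0]
    return terms


def rhs(state: "CellState | np.ndarray", p: ParameterSet,
        reduced: bool = False) -> np.ndarray:
    """Time derivatives of the 12 state variables, in m.p.c./min.

    With ``reduced=True`` the Alu-free variant is evaluated: Alu
    transcription, the mRNA substitution reaction and Alu insertion are
    switched off and the derivatives of ``mS``, ``bS`` and ``S`` are
    identically zero.
    """
    return np.array([math.fsum(t) for t in equation_terms(state, p, reduced=reduced)])
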