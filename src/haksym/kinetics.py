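"""Closed-form steady state of the four-state K+/H+ symport cycle.

The cycle C1 -> C2 -> C3 -> C4 -> C1 (H+ binding, K+ binding, electroneutral
conformational step, charge-moving return step) is solved with the
King-Altman method: each state occupancy is a sum of four directed
spanning-tree rate products, sixteen terms in all, divided by their grand
total.  The net current follows from the charge-moving step,

    I = 2 e N (k14 C1 - k41 C4),

two elementary charges per cycle because the empty carrier moves two
negative charges across the membrane.  A matrix null-space solver is kept
alongside as an independent oracle for the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import ELEMENTARY_CHARGE, FARADAY, GAS_CONSTANT
from .exceptions import DegenerateSystemError, UndefinedReversalError
from .params import Conditions, KineticParams, ResolvedRates

__all__ = [
    "resolve_rates", "king_altman_terms", "king_altman_occupancies",
    "steady_state_current", "numeric_occupancy_oracle", "reversal_potential",
    "SteadyStateSolution",
]

#: relative tolerance for the internal cross-check of the two current routes
_CURRENT_CONSISTENCY_RTOL = 1e-9


@dataclass(frozen=True)
class SteadyStateSolution:
    """Steady-state occupancies, spanning-tree terms and currents.

    ``occupancy`` holds the probabilities of C1..C4 (sums to one);
    ``terms`` is the 4x4 array of King-Altman directed-tree products;
    ``I`` is the total current in ampere, negative for net inward
    (K+ and H+ entering the cytosol); ``I_plus`` (>= 0) and ``I_minus``
    (<= 0) are the unidirectional efflux and influx components with
    ``I = I_plus + I_minus``.
    """

    occupancy: np.ndarray
    terms: np.ndarray
    I: float = float("nan")
    I_plus: float = float("nan")
    I_minus: float = float("nan")


def resolve_rates(params: KineticParams, cond: Conditions) -> ResolvedRates:
    """Turn binding constants and voltage factors into first-order rates.

    Binding steps are multiplied by the relevant concentrations
    (``k43`` is bilinear in the two internal concentrations) and the
    charge-moving pair picks up symmetric Eyring factors ``exp(+-FV/RT)``.
    """
    u = FARADAY * (cond.V_mV * 1e-3) / (GAS_CONSTANT * cond.T_K)
    return ResolvedRates(
        k12=params.k12_0 * cond.H_out_M,
        k21=params.k21,
        k23=params.k23_0 * cond.K_out_M,
        k32=params.k32,
        k34=params.k34,
        k43=params.k43_0 * cond.H_in_M * cond.K_in_M,
        k14=params.k14_0 * math.exp(u),
        k41=params.k41_0 * math.exp(-u),
    )


def king_altman_terms(rates: ResolvedRates) -> np.ndarray:
    """The sixteen directed spanning-tree products, one row per state."""
    k12, k21, k23, k32, k34, k43, k14, k41 = rates.as_tuple()
    return np.array([
        [k23 * k34 * k41, k34 * k41 * k21, k41 * k21 * k32, k21 * k32 * k43],
        [k34 * k41 * k12, k41 * k12 * k32, k12 * k32 * k43, k32 * k43 * k14],
        [k41 * k12 * k23, k12 * k23 * k43, k23 * k43 * k14, k43 * k14 * k21],
        [k12 * k23 * k34, k23 * k34 * k14, k34 * k14 * k21, k14 * k21 * k32],
    ])


def king_altman_occupancies(rates: ResolvedRates) -> SteadyStateSolution:
    """Closed-form steady-state occupancies of the four states.

    Each occupancy is the row sum of the spanning-tree terms divided by the
    grand total; no currents are attached (see
    :func:`steady_state_current`).
    """
    terms = king_altman_terms(rates)
    denom = float(terms.sum())
    if denom <= 0.0 or not math.isfinite(denom):
        raise DegenerateSystemError(
            "King-Altman denominator is zero: the rate configuration admits "
            "no unique steady state")
    occ = terms.sum(axis=1) / denom
    return SteadyStateSolution(occupancy=occ, terms=terms)


def steady_state_current(params: KineticParams,
                         cond: Conditions) -> SteadyStateSolution:
    """Steady-state occupancies and transport current.

    The total current is computed in closed form from the factorised
    numerator

        I = 2 e N k41_0 k12_0 k23_0 k34
            ([H+]i [K+]i e^{FV/RT} - [H+]o [K+]o e^{-FV/RT}) / sum(terms)

    and verified internally against the flux form
    ``2 e N (k14 C1 - k41 C4)``; the two are algebraically identical through
    the detailed-balance identity, so disagreement indicates a corrupted
    parameter set.  ``I_plus``/``I_minus`` split the numerator into its
    efflux (cytosol to bath) and influx parts.
    """
    rates = resolve_rates(params, cond)
    sol = king_altman_occupancies(rates)
    denom = float(sol.terms.sum())

    u = FARADAY * (cond.V_mV * 1e-3) / (GAS_CONSTANT * cond.T_K)
    pref = (2.0 * ELEMENTARY_CHARGE * params.N
            * params.k41_0 * params.k12_0 * params.k23_0 * params.k34)
    I_plus = pref * cond.H_in_M * cond.K_in_M * math.exp(u) / denom
    I_minus = -pref * cond.H_out_M * cond.K_out_M * math.exp(-u) / denom
    I = I_plus + I_minus

    C1, C4 = sol.occupancy[0], sol.occupancy[3]
    I_flux = 2.0 * ELEMENTARY_CHARGE * params.N * (rates.k14 * C1 - rates.k41 * C4)
    # near equilibrium the flux form subtracts two nearly equal unidirectional
    # fluxes, so roundoff must be judged against their magnitude
    two_eN = 2.0 * ELEMENTARY_CHARGE * params.N
    scale = max(abs(I_plus), abs(I_minus),
                two_eN * rates.k14 * C1, two_eN * rates.k41 * C4)
    if scale > 0 and abs(I - I_flux) > _CURRENT_CONSISTENCY_RTOL * scale:
        raise DegenerateSystemError(
            f"internal inconsistency: closed-form current {I:.12g} A differs "
            f"from flux form {I_flux:.12g} A")
    return SteadyStateSolution(occupancy=sol.occupancy, terms=sol.terms,
                               I=I, I_plus=I_plus, I_minus=I_minus)


def numeric_occupancy_oracle(rates: ResolvedRates) -> np.ndarray:
    """Stationary distribution from the master equation, no closed form.

    Builds the 4x4 generator of the continuous-time Markov chain and solves
    the singular system ``A c = 0`` with normalisation by Gaussian
    elimination in the cancellation-free GTH (Grassmann-Taksar-Heyman)
    form: diagonals are recomputed as sums of off-diagonal rates, so the
    elimination involves only nonnegative additions and multiplications and
    the result is componentwise accurate even when occupancies span many
    orders of magnitude.  Serves as an independent check of
    :func:`king_altman_occupancies`.
    """
    k12, k21, k23, k32, k34, k43, k14, k41 = rates.as_tuple()
    # q[i, j] = transition rate from state i+1 to state j+1
    q = np.array([
        [0.0, k12, 0.0, k14],
        [k21, 0.0, k23, 0.0],
        [0.0, k32, 0.0, k34],
        [k41, 0.0, k43, 0.0],
    ])
    if not q.any():
        raise DegenerateSystemError("all rates are zero")
    for k in (3, 2, 1):  # eliminate states 4, 3, 2
        s = q[k, :k].sum()
        if s <= 0.0:
            raise DegenerateSystemError(
                "stationary distribution not unique: state "
                f"C{k + 1} cannot reach the remaining states")
        q[:k, k] /= s
        for i in range(k):
            for j in range(k):
                if i != j:
                    q[i, j] += q[i, k] * q[k, j]
    occ = np.empty(4)
    occ[0] = 1.0
    for k in (1, 2, 3):  # back substitution, only positive terms
        occ[k] = np.dot(occ[:k], q[:k, k])
    return occ / occ.sum()


def reversal_potential(cond: Conditions) -> float:
    """Zero-current voltage of the coupled cycle, in mV.

    The current numerator vanishes when
    ``[H+]i [K+]i e^{FV/RT} = [H+]o [K+]o e^{-FV/RT}``, giving

        V_rev = (RT / 2F) ln([H+]o [K+]o / ([H+]i [K+]i)).

    Two charges cross per cycle, hence the factor 2.  The result does not
    depend on the rate constants.
    """
    for name in ("K_out_M", "H_out_M", "K_in_M", "H_in_M"):
        if getattr(cond, name) <= 0:
            raise UndefinedReversalError(
                f"reversal potential undefined: {name} is zero")
    ratio = (cond.H_out_M * cond.K_out_M) / (cond.H_in_M * cond.K_in_M)
    return 0.5 * cond.VT_mV * math.log(ratio)
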