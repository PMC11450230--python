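"""Equilibrium uptake limits: K+ channel versus H+-coupled symport.

A K+ channel can only accumulate potassium down to the Nernst limit set by
membrane voltage; an n:1 H+:K+ symporter adds the proton motive force of
each coupled proton.  With the decadic slope s (mV per tenfold), the lowest
external K+ still permitting net influx is

    channel:   [K+]o,min = [K+]i * 10^(V/s)
    symport:   [K+]o,min = [K+]i * 10^(n*dpH) * 10^((1+n)*V/s)

with dpH = pH_out - pH_in (negative when the outside is more acidic).  The
default slope of 60 mV/decade reproduces the textbook round numbers; an
exact temperature-derived slope is available via
:func:`haksym.constants.nernst_slope_mV`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import InvalidInputError

__all__ = ["ThermoScenario", "channel_uptake_limit", "symport_uptake_limit",
           "accumulation_advantage"]


@dataclass(frozen=True)
class ThermoScenario:
    """Cytosolic K+, voltage, pH gradient and coupling stoichiometry.

    ``delta_pH`` is external minus internal pH; ``n_H`` the number of
    protons co-transported per K+ (0 for a channel); ``slope_mV`` the
    decadic Nernst slope.
    """

    K_in_M: float
    V_mV: float
    delta_pH: float = 0.0
    n_H: int = 0
    slope_mV: float = 60.0

    def __post_init__(self):
        if not (self.K_in_M > 0 and math.isfinite(self.K_in_M)):
            raise InvalidInputError(f"K_in_M must be positive, got {self.K_in_M!r}")
        if not (self.slope_mV > 0):
            raise InvalidInputError(f"slope_mV must be positive, got {self.slope_mV!r}")
        if not (isinstance(self.n_H, int) and self.n_H >= 0):
            raise InvalidInputError(f"n_H must be a nonnegative integer, got {self.n_H!r}")


def channel_uptake_limit(s: ThermoScenario) -> float:
    """Minimal external [K+] (mol/L) permitting net influx through a channel.

    Requires ``n_H == 0``; the limit is the Nernst equilibrium
    ``K_in * 10^(V/slope)``.
    """
    if s.n_H != 0:
        raise InvalidInputError("channel_uptake_limit requires n_H == 0; "
                                "use symport_uptake_limit for coupled transport")
    return s.K_in_M * 10.0 ** (s.V_mV / s.slope_mV)


def symport_uptake_limit(s: ThermoScenario) -> float:
    """Minimal external [K+] (mol/L) for an n_H:1 H+:K+ symporter.

    Each coupled proton contributes its chemical gradient (``10^dpH``) and
    one extra charge moving through the membrane field; n_H = 0 reduces to
    the channel limit.
    """
    return (s.K_in_M
            * 10.0 ** (s.n_H * s.delta_pH)
            * 10.0 ** ((1 + s.n_H) * s.V_mV / s.slope_mV))


def accumulation_advantage(s_channel: ThermoScenario,
                           s_symport: ThermoScenario) -> float:
    """Ratio of the channel limit to the symport limit (dimensionless).

    Both scenarios must share the cytosolic K+ and the voltage so the ratio
    isolates the contribution of proton coupling; it equals
    ``10^(-n_H*dpH) * 10^(-n_H*V/slope)`` algebraically.
    """
    if not (math.isclose(s_channel.K_in_M, s_symport.K_in_M)
            and math.isclose(s_channel.V_mV, s_symport.V_mV)):
        raise InvalidInputError(
            "accumulation_advantage requires scenarios sharing K_in and V")
    chan = channel_uptake_limit(replace(s_channel, n_H=0))
    return chan / symport_uptake_limit(s_symport)
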