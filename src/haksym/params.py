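"""Kinetic parameter sets and experimental conditions.

The transport cycle has four states: outward-open empty carrier (C1),
carrier with H+ bound (C2), carrier with H+ and K+ bound (C3), and the
inward-open carrier after the electroneutral conformational step (C4).
Eight elementary rate constants connect them:

==========  =====================================================  ==========
constant    step                                                   units
==========  =====================================================  ==========
k12_0       external H+ binding, C1 -> C2 (second order)           M^-1 s^-1
k21         H+ debinding to the outside, C2 -> C1                  s^-1
k23_0       external K+ binding, C2 -> C3 (second order)           M^-1 s^-1
k32         K+ debinding to the outside, C3 -> C2                  s^-1
k34         forward conformational change, C3 -> C4                s^-1
k43_0       re-binding of internal H+ and K+, C4 -> C3             M^-2 s^-1
k14_0       outward charge-moving step at 0 mV, C1 -> C4           s^-1
k41_0       inward charge-moving step at 0 mV, C4 -> C1            s^-1
==========  =====================================================  ==========

Microscopic reversibility ties the eight constants together::

    k41_0 * k12_0 * k23_0 * k34 == k14_0 * k21 * k32 * k43_0

so only seven are independent.  One constant, named by
``derived_constant``, is always recomputed from the other seven.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace

from .constants import (FARADAY, GAS_CONSTANT, H_IN_DEFAULT, K_IN_DEFAULT,
                        T_DEFAULT)
from .exceptions import InvalidInputError

#: constants appearing on the forward (clockwise) side of the cycle product
_FORWARD = ("k41_0", "k12_0", "k23_0", "k34")
#: constants on the reverse side
_REVERSE = ("k14_0", "k21", "k32", "k43_0")

RATE_NAMES = ("k12_0", "k21", "k23_0", "k32", "k34", "k43_0", "k14_0", "k41_0")

#: relative tolerance on the microscopic-reversibility identity
REVERSIBILITY_RTOL = 1e-10


@dataclass(frozen=True)
class KineticParams:
    """The eight elementary rate constants plus the transporter count N.

    The constant named by ``derived_constant`` (default ``k43_0``) is
    computed from the detailed-balance identity; any value supplied for it
    is ignored.  ``k43_0`` is the default because it multiplies the small
    internal concentration product and therefore perturbs simulated curves
    least.
    """

    k12_0: float
    k21: float
    k23_0: float
    k32: float
    k34: float
    k14_0: float
    k41_0: float
    k43_0: float | None = None
    N: float = 1.0
    derived_constant: str = "k43_0"

    def __post_init__(self):
        if self.derived_constant not in RATE_NAMES:
            raise InvalidInputError(
                f"derived_constant must be one of {RATE_NAMES}, "
                f"got {self.derived_constant!r}")
        object.__setattr__(self, self.derived_constant,
                           self._solve_derived(self.derived_constant))
        for name in RATE_NAMES:
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise InvalidInputError(f"rate constant {name} must be a "
                                        f"finite positive number, got {v!r}")
        if not (self.N >= 1 and math.isfinite(self.N)):
            raise InvalidInputError(f"transporter count N must be >= 1, got {self.N!r}")
        fwd = self.cycle_product_forward
        rev = self.cycle_product_reverse
        if abs(fwd - rev) > REVERSIBILITY_RTOL * max(abs(fwd), abs(rev)):
            raise InvalidInputError(
                "microscopic reversibility violated: "
                f"k41_0*k12_0*k23_0*k34 = {fwd:.15g} but "
                f"k14_0*k21*k32*k43_0 = {rev:.15g}")

    def _solve_derived(self, name: str) -> float:
        def prod(names, skip):
            p = 1.0
            for n in names:
                if n != skip:
                    v = getattr(self, n)
                    if v is None or v <= 0:
                        raise InvalidInputError(
                            f"cannot derive {skip}: constant {n} missing or nonpositive")
                    p *= v
            return p

        if name in _FORWARD:
            return prod(_REVERSE, None) / prod(_FORWARD, name)
        return prod(_FORWARD, None) / prod(_REVERSE, name)

    @property
    def cycle_product_forward(self) -> float:
        return self.k41_0 * self.k12_0 * self.k23_0 * self.k34

    @property
    def cycle_product_reverse(self) -> float:
        return self.k14_0 * self.k21 * self.k32 * self.k43_0

    def with_updates(self, **changes) -> "KineticParams":
        """Return a copy with ``changes`` applied and the derived constant
        recomputed so detailed balance still holds."""
        return replace(self, **changes)

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in RATE_NAMES}
        d["N"] = self.N
        d["derived_constant"] = self.derived_constant
        return d

    def to_json(self, path=None, **json_kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, **json_kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown kinetic parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "KineticParams":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        s = str(source)
        if s.lstrip().startswith("{"):
            return cls.from_dict(json.loads(s))
        with open(s) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Conditions:
    """Membrane voltage, temperature and the four ion concentrations.

    Voltage is cytosol relative to bath, in mV; concentrations in mol/L.
    Internal defaults are the oocyte values: pH_in 7.1, 100 mM K+.
    """

    V_mV: float
    K_out_M: float
    H_out_M: float
    K_in_M: float = K_IN_DEFAULT
    H_in_M: float = H_IN_DEFAULT
    T_K: float = T_DEFAULT

    def __post_init__(self):
        if not (self.T_K > 0 and math.isfinite(self.T_K)):
            raise InvalidInputError(f"temperature must be positive, got {self.T_K!r}")
        if not math.isfinite(self.V_mV):
            raise InvalidInputError(f"voltage must be finite, got {self.V_mV!r}")
        for name in ("K_out_M", "H_out_M", "K_in_M", "H_in_M"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise InvalidInputError(f"concentration {name} must be >= 0, got {v!r}")

    @property
    def VT_mV(self) -> float:
        """Thermal voltage RT/F in mV."""
        return GAS_CONSTANT * self.T_K / FARADAY * 1e3

    @property
    def pH_out(self) -> float:
        return -math.log10(self.H_out_M)

    @property
    def pH_in(self) -> float:
        return -math.log10(self.H_in_M)

    def to_dict(self) -> dict:
        return {"V_mV": self.V_mV, "T_K": self.T_K,
                "K_out_M": self.K_out_M, "H_out_M": self.H_out_M,
                "K_in_M": self.K_in_M, "H_in_M": self.H_in_M}

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "Conditions":
        d = dict(d)
        # pH convenience keys: H = 10^-pH mol/L
        if "pH_out" in d:
            d["H_out_M"] = 10.0 ** -float(d.pop("pH_out"))
        if "pH_in" in d:
            d["H_in_M"] = 10.0 ** -float(d.pop("pH_in"))
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown condition keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "Conditions":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        s = str(source)
        if s.lstrip().startswith("{"):
            return cls.from_dict(json.loads(s))
        with open(s) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ResolvedRates:
    """Effective first-order rates after applying concentrations and voltage.

    ``k12 = k12_0*[H+]o``, ``k23 = k23_0*[K+]o``, ``k43 = k43_0*[H+]i*[K+]i``;
    the charge-moving pair carries symmetric Eyring voltage factors
    ``k14 = k14_0*exp(FV/RT)`` and ``k41 = k41_0*exp(-FV/RT)`` so that the
    product k14*k41 is voltage independent.
    """

    k12: float
    k21: float
    k23: float
    k32: float
    k34: float
    k43: float
    k14: float
    k41: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0 and math.isfinite(v)):
                raise InvalidInputError(f"resolved rate {f.name} must be >= 0 "
                                        f"and finite, got {v!r}")

    def as_tuple(self):
        return (self.k12, self.k21, self.k23, self.k32,
                self.k34, self.k43, self.k14, self.k41)
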