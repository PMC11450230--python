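"""Dose-response fitting and TEVC trace feature extraction.

Peak currents evoked by concentration steps saturate hyperbolically and are
fitted with a Michaelis-Menten law; proton dose-responses with a Hill law.
The current remaining after inactivation follows a bell-shaped curve in
[K+]: a Michaelis-Menten activation term multiplied by a hyperbolic
inactivation term sharing the same K_m,

    I_ss([K]) = ([K]/([K]+K_m)) * I_max/([K]/K_m + 1) + I_s
              = I_max * K_m [K] / ([K]+K_m)^2 + I_s,

whose maximum sits exactly at [K] = K_m.  All responses are treated as
magnitudes |dI| (the physiological inward currents are negative; the
fitting layer works on their absolute size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

from .exceptions import (FeatureExtractionError, FitFailureError,
                         InsufficientDataError, InvalidInputError,
                         UndefinedMetricError)

__all__ = [
    "DoseResponseDataset", "MMFit", "HillFit", "SSFit", "TraceFeatures",
    "michaelis_menten", "hill", "steady_state_bell",
    "fit_michaelis_menten", "fit_hill", "fit_steady_state_bell",
    "bell_argmax", "percent_inactivation", "extract_trace_features",
]


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------

def michaelis_menten(conc, I_max, K_m):
    """Saturating response ``I_max * c / (c + K_m)``."""
    conc = np.asarray(conc, dtype=float)
    return I_max * conc / (conc + K_m)


def hill(conc, I_max, K_m, h):
    """Cooperative saturating response ``I_max * c^h / (c^h + K_m^h)``."""
    conc = np.asarray(conc, dtype=float)
    return I_max * conc ** h / (conc ** h + K_m ** h)


def steady_state_bell(conc, I_max, K_m, I_s):
    """Bell-shaped steady-state current ``I_max*K_m*c/(c+K_m)^2 + I_s``."""
    conc = np.asarray(conc, dtype=float)
    return (conc / (conc + K_m)) * (I_max / (conc / K_m + 1.0)) + I_s


def bell_argmax(K_m: float) -> float:
    """Concentration maximising the bell-shaped steady-state current.

    The concentration-dependent part of the curve is ``K_m*c/(c+K_m)^2``
    whose derivative vanishes at ``c = K_m``; the offset ``I_s`` and scale
    ``I_max`` do not move the argmax, so it equals the peak-fit K_m.
    """
    if not (K_m > 0 and math.isfinite(K_m)):
        raise InvalidInputError(f"K_m must be positive, got {K_m!r}")
    return float(K_m)


def percent_inactivation(dI_peak: float, dI_ss: float) -> float:
    """Percentage of peak current lost at steady state,
    ``100 * (dI_peak - dI_ss) / dI_peak``."""
    if not (dI_peak > 0):
        raise UndefinedMetricError(
            f"percent inactivation undefined for dI_peak = {dI_peak!r}")
    if dI_ss < 0:
        raise UndefinedMetricError(f"dI_ss must be >= 0, got {dI_ss!r}")
    return 100.0 * (dI_peak - dI_ss) / dI_peak


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseDataset:
    """(concentration, response magnitude) points, optionally replicated.

    Concentrations in mol/L; responses are magnitudes (ampere or
    normalised) and must be nonnegative.  Within each replicate the
    concentrations must be strictly increasing.
    """

    conc_M: np.ndarray
    response: np.ndarray
    replicate: np.ndarray = None
    substrate: str = "K+"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        conc = np.asarray(self.conc_M, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        rep = (np.zeros(conc.size, dtype=int) if self.replicate is None
               else np.asarray(self.replicate, dtype=int))
        if not (conc.shape == resp.shape == rep.shape) or conc.ndim != 1:
            raise InvalidInputError("conc_M, response and replicate must be "
                                    "1-d arrays of equal length")
        if conc.size and (conc <= 0).any():
            raise InvalidInputError("concentrations must be strictly positive")
        if resp.size and (resp < 0).any():
            raise InvalidInputError("responses must be nonnegative magnitudes")
        for r in np.unique(rep):
            c = conc[rep == r]
            if (np.diff(c) <= 0).any():
                raise InvalidInputError(
                    f"concentrations must be strictly increasing and distinct "
                    f"within replicate {r}")
        object.__setattr__(self, "conc_M", conc)
        object.__setattr__(self, "response", resp)
        object.__setattr__(self, "replicate", rep)

    def __len__(self):
        return self.conc_M.size

    @property
    def n_replicates(self) -> int:
        return int(np.unique(self.replicate).size)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _FitResultBase:
    stderr: dict
    residual_norm: float
    n_points: int
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["model"] = type(self).__name__
        return d


@dataclass(frozen=True)
class MMFit(_FitResultBase):
    I_max: float = float("nan")
    K_m: float = float("nan")


@dataclass(frozen=True)
class HillFit(_FitResultBase):
    I_max: float = float("nan")
    K_m: float = float("nan")
    h: float = float("nan")


@dataclass(frozen=True)
class SSFit(_FitResultBase):
    I_max: float = float("nan")
    I_s: float = float("nan")
    K_m_fixed: float = float("nan")


_KM_MIN, _KM_MAX = 1e-15, 1e3


def _km_init(conc: np.ndarray, resp: np.ndarray) -> float:
    """Concentration nearest half of the largest response, log-interpolated."""
    order = np.argsort(conc)
    c, r = conc[order], resp[order]
    # average duplicate concentrations (replicates)
    cu, inv = np.unique(c, return_inverse=True)
    ru = np.bincount(inv, weights=r) / np.bincount(inv)
    half = ru.max() / 2.0
    above = ru >= half
    if above.all() or not above.any():
        return float(np.exp(np.mean(np.log(cu))))
    i = int(np.argmax(above))  # first point at/above half-max
    if i == 0:
        return float(cu[0])
    x0, x1 = math.log(cu[i - 1]), math.log(cu[i])
    y0, y1 = ru[i - 1], ru[i]
    if y1 == y0:
        return float(cu[i])
    return float(math.exp(x0 + (half - y0) * (x1 - x0) / (y1 - y0)))


def _run_fit(model: lmfit.Model, params: lmfit.Parameters,
             conc: np.ndarray, resp: np.ndarray,
             weights: np.ndarray | None):
    result = model.fit(resp, params, conc=conc, weights=weights,
                       fit_kws={"xtol": 1e-13, "ftol": 1e-13})
    if not result.success:
        raise FitFailureError("fit did not converge",
                              diagnostics={"message": result.message,
                                           "nfev": result.nfev})
    for name, par in result.params.items():
        if not par.vary:
            continue
        if par.min > -np.inf and par.value <= par.min * (1 + 1e-6) + 1e-300:
            raise FitFailureError(f"parameter {name} stuck at lower bound",
                                  diagnostics={"value": par.value, "min": par.min})
        if par.max < np.inf and par.value >= par.max * (1 - 1e-6):
            raise FitFailureError(f"parameter {name} stuck at upper bound",
                                  diagnostics={"value": par.value, "max": par.max})
    return result


def _se(result, name) -> float:
    err = result.params[name].stderr
    return float(err) if err is not None else float("nan")


def fit_michaelis_menten(data: DoseResponseDataset,
                         weights: Sequence[float] | None = None) -> MMFit:
    """Least-squares Michaelis-Menten fit of peak-current magnitudes.

    Needs at least three points spanning a tenfold concentration range.
    ``weights`` (optional) are per-point weights, e.g. 1/SE.
    """
    conc, resp = data.conc_M, data.response
    if len(data) < 3:
        raise InsufficientDataError("Michaelis-Menten fit needs >= 3 points")
    if conc.max() / conc.min() < 10.0:
        raise InsufficientDataError(
            "concentrations must span at least a factor 10")
    model = lmfit.Model(michaelis_menten, independent_vars=["conc"])
    p = model.make_params()
    p["I_max"].set(value=float(resp.max()) or 1.0, min=0.0)
    p["K_m"].set(value=_km_init(conc, resp), min=_KM_MIN, max=_KM_MAX)
    w = None if weights is None else np.asarray(weights, dtype=float)
    result = _run_fit(model, p, conc, resp, w)
    return MMFit(I_max=result.params["I_max"].value,
                 K_m=result.params["K_m"].value,
                 stderr={"I_max": _se(result, "I_max"), "K_m": _se(result, "K_m")},
                 residual_norm=float(np.linalg.norm(result.residual)),
                 n_points=len(data), converged=True, message=result.message)


def fit_hill(data: DoseResponseDataset,
             weights: Sequence[float] | None = None) -> HillFit:
    """Least-squares Hill fit with a free Hill coefficient (initialised at 1)."""
    conc, resp = data.conc_M, data.response
    if len(data) < 4:
        raise InsufficientDataError("Hill fit needs >= 4 points")
    model = lmfit.Model(hill, independent_vars=["conc"])
    p = model.make_params()
    p["I_max"].set(value=float(resp.max()) or 1.0, min=0.0)
    p["K_m"].set(value=_km_init(conc, resp), min=_KM_MIN, max=_KM_MAX)
    p["h"].set(value=1.0, min=0.05, max=20.0)
    w = None if weights is None else np.asarray(weights, dtype=float)
    result = _run_fit(model, p, conc, resp, w)
    return HillFit(I_max=result.params["I_max"].value,
                   K_m=result.params["K_m"].value,
                   h=result.params["h"].value,
                   stderr={n: _se(result, n) for n in ("I_max", "K_m", "h")},
                   residual_norm=float(np.linalg.norm(result.residual)),
                   n_points=len(data), converged=True, message=result.message)


def fit_steady_state_bell(data: DoseResponseDataset, K_m_fixed: float,
                          weights: Sequence[float] | None = None) -> SSFit:
    """Fit the bell-shaped steady-state curve with K_m held at the peak-fit
    value; only the scale ``I_max`` and offset ``I_s`` are free."""
    if not (K_m_fixed > 0 and math.isfinite(K_m_fixed)):
        raise InvalidInputError(f"K_m_fixed must be positive, got {K_m_fixed!r}")
    conc, resp = data.conc_M, data.response
    if len(data) < 3:
        raise InsufficientDataError("steady-state fit needs >= 3 points")
    model = lmfit.Model(steady_state_bell, independent_vars=["conc"])
    p = model.make_params()
    p["I_max"].set(value=4.0 * float(resp.max()) or 1.0, min=0.0)
    p["K_m"].set(value=K_m_fixed, vary=False)
    p["I_s"].set(value=float(resp.min()))
    w = None if weights is None else np.asarray(weights, dtype=float)
    result = _run_fit(model, p, conc, resp, w)
    return SSFit(I_max=result.params["I_max"].value,
                 I_s=result.params["I_s"].value,
                 K_m_fixed=K_m_fixed,
                 stderr={"I_max": _se(result, "I_max"), "I_s": _se(result, "I_s")},
                 residual_norm=float(np.linalg.norm(result.residual)),
                 n_points=len(data), converged=True, message=result.message)


# ---------------------------------------------------------------------------
# trace features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceFeatures:
    """Peak and steady-state current changes of one concentration step.

    ``dI_peak_A``/``dI_ss_A`` are baseline-subtracted magnitudes;
    ``t_peak_s`` is measured from the step onset; ``pct_inactivation`` is
    NaN when the step evoked no current at all.
    """

    dI_peak_A: float
    dI_ss_A: float
    t_peak_s: float
    pct_inactivation: float


def extract_trace_features(trace, protocol, step_index: int = 1,
                           ss_window_frac: float = 0.05) -> TraceFeatures:
    """Extract dI_peak and dI_ss from a current trace.

    ``trace`` needs ``time_s``/``current_A`` arrays and ``protocol`` a
    ``segments`` sequence with ``duration_s`` attributes (any step
    protocol, simulated or loaded, qualifies).  The baseline is the median
    current before the chosen step segment; the steady-state level is the
    mean magnitude over the final ``ss_window_frac`` of the step window.
    """
    t = np.asarray(trace.time_s, dtype=float)
    i = np.asarray(trace.current_A, dtype=float)
    durations = [seg.duration_s for seg in protocol.segments]
    if not 1 <= step_index < len(durations):
        raise FeatureExtractionError(
            f"step_index {step_index} leaves no pre-step baseline segment")
    start = float(sum(durations[:step_index]))
    end = start + durations[step_index]
    base_mask = t < start
    step_mask = (t >= start) & (t < end)
    if not base_mask.any():
        raise FeatureExtractionError("no samples in the baseline window")
    if not step_mask.any():
        raise FeatureExtractionError("no samples in the step window")
    baseline = float(np.median(i[base_mask]))
    dI = np.abs(i[step_mask] - baseline)
    t_step = t[step_mask] - start
    k = int(np.argmax(dI))
    dI_peak = float(dI[k])
    ss_mask = t_step >= (1.0 - ss_window_frac) * durations[step_index]
    if not ss_mask.any():
        ss_mask = np.zeros_like(t_step, dtype=bool)
        ss_mask[-1] = True
    dI_ss = float(dI[ss_mask].mean())
    pct = (percent_inactivation(dI_peak, dI_ss) if dI_peak > 0
           else float("nan"))
    return TraceFeatures(dI_peak_A=dI_peak, dI_ss_A=dI_ss,
                         t_peak_s=float(t_step[k]), pct_inactivation=pct)
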