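"""Synthetic TEVC recordings and noisy dose-response datasets.

The generator emulates the statistical structure of whole-oocyte
voltage-clamp data: concentration steps at a holding voltage, peak currents
saturating with substrate, relaxation toward a bell-shaped steady-state
level (concentration- and pH-graded inactivation), cation leak currents of
the magnitudes measured in water-injected control oocytes, and
multiplicative measurement noise across replicate "oocytes".  Everything is
driven by a single seeded random stream so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .doseresponse import DoseResponseDataset
from .exceptions import InvalidInputError
from .kinetics import steady_state_current
from .params import Conditions, KineticParams

__all__ = [
    "Segment", "StepProtocol", "step_protocol", "NoiseModel", "OocytePreset",
    "WT_PRESET", "Y450A_PRESET", "TEVCTrace",
    "generate_dose_response", "simulate_tevc_trace",
]


@dataclass(frozen=True)
class Segment:
    """One bath condition held for ``duration_s`` seconds."""

    duration_s: float
    conc_M: float
    pH: float = 4.5
    substrate: str = "K+"

    def __post_init__(self):
        if not (self.duration_s > 0):
            raise InvalidInputError(f"segment duration must be > 0, got {self.duration_s!r}")
        if self.conc_M < 0:
            raise InvalidInputError(f"concentration must be >= 0, got {self.conc_M!r}")


@dataclass(frozen=True)
class StepProtocol:
    """Holding voltage, ordered bath segments and sampling rate."""

    holding_mV: float
    segments: tuple
    sampling_hz: float = 10.0

    def __post_init__(self):
        if not self.segments:
            raise InvalidInputError("protocol needs at least one segment")
        if not (self.sampling_hz > 0):
            raise InvalidInputError(f"sampling rate must be > 0, got {self.sampling_hz!r}")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))


def step_protocol(conc_M: float, pH: float = 4.5, baseline_s: float = 10.0,
                  step_s: float = 120.0, washout_s: float = 10.0,
                  holding_mV: float = -120.0, sampling_hz: float = 10.0,
                  substrate: str = "K+") -> StepProtocol:
    """Standard three-segment protocol: substrate-free bath, concentration
    step, washout — the 120 s step used for inactivation experiments."""
    segs = [Segment(baseline_s, 0.0, pH, substrate),
            Segment(step_s, conc_M, pH, substrate)]
    if washout_s > 0:
        segs.append(Segment(washout_s, 0.0, pH, substrate))
    return StepProtocol(holding_mV=holding_mV, segments=tuple(segs),
                        sampling_hz=sampling_hz)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative CV, additive SD and a leak current.

    Leak defaults match the mean +- SD current response of water-injected
    control oocytes to 2 mM K+.  The seed is mandatory; all randomness of a
    generator call flows from one stream.
    """

    seed: int
    cv: float = 0.0
    additive_sd_A: float = 0.0
    leak_mean_A: float = -84.55e-9
    leak_sd_A: float = 7.2e-9

    def __post_init__(self):
        if self.cv < 0 or self.additive_sd_A < 0 or self.leak_sd_A < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class OocytePreset:
    """Phenomenological whole-oocyte response surface.

    Peak currents follow a Michaelis-Menten law in the cation and a Hill
    law in external H+; the post-inactivation steady-state level follows
    the bell-shaped law ``gain*K_ss*c/(c+K_ss)^2 + offset`` (relative to
    the maximal peak), clamped to never exceed the peak.  ``K_ss`` scales
    with [H+]o so that alkaline media inactivate at lower K+, reproducing
    the observed ladder: no inactivation at 10 uM K+/pH 4.5, near-complete
    at 2 mM K+/pH 4.5 and at moderate K+ under alkaline external pH.
    """

    I_peak_max_A: float = 1.01e-6
    K_m_K_M: float = 23.56e-6
    K_m_H_M: float = 4.81e-6
    hill_h: float = 1.67
    K_m_ss_M: float = 28.3e-6
    ss_gain: float = 2.0
    ss_offset_frac: float = 0.04
    pH_ref: float = 4.5

    def _h_activation(self, pH: float) -> float:
        H = 10.0 ** -pH
        return H ** self.hill_h / (H ** self.hill_h + self.K_m_H_M ** self.hill_h)

    def peak_response(self, conc_M: float, pH: float | None = None) -> float:
        """Magnitude of the peak current change at ``conc_M`` and ``pH``."""
        pH = self.pH_ref if pH is None else pH
        return (self.I_peak_max_A * conc_M / (conc_M + self.K_m_K_M)
                * self._h_activation(pH))

    def ss_response(self, conc_M: float, pH: float | None = None) -> float:
        """Magnitude of the steady-state current change after inactivation."""
        pH = self.pH_ref if pH is None else pH
        if conc_M <= 0:
            return 0.0
        K_ss = self.K_m_ss_M * 10.0 ** (self.pH_ref - pH)
        rel = (self.ss_gain * K_ss * conc_M / (conc_M + K_ss) ** 2
               + self.ss_offset_frac)
        ss = self.I_peak_max_A * self._h_activation(pH) * rel
        return min(ss, self.peak_response(conc_M, pH))


#: Wild-type response surface (published fit values).
WT_PRESET = OocytePreset()

#: K+-binding-site mutant: ~500-fold weaker K+ affinity, one pH unit higher
#: H+ affinity, steeper H+ cooperativity, no residual steady-state offset.
Y450A_PRESET = OocytePreset(I_peak_max_A=1.12e-6, K_m_K_M=12.92e-3,
                            K_m_H_M=0.36e-6, hill_h=2.17,
                            K_m_ss_M=12.92e-3, ss_offset_frac=0.0)


@dataclass(frozen=True)
class TEVCTrace:
    """A simulated whole-cell current trace with its generating truth."""

    time_s: np.ndarray
    current_A: np.ndarray
    protocol: StepProtocol
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        i = np.asarray(self.current_A, dtype=float)
        if t.shape != i.shape or t.ndim != 1:
            raise InvalidInputError("time and current must be 1-d arrays of equal length")
        if t.size > 1 and (np.diff(t) <= 0).any():
            raise InvalidInputError("time samples must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "current_A", i)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _truth_curve(truth, pH: float) -> tuple[Callable[[float], float], dict]:
    if isinstance(truth, OocytePreset):
        return (lambda c: truth.peak_response(c, pH),
                {"model": "preset", **{k: getattr(truth, k)
                                       for k in ("I_peak_max_A", "K_m_K_M",
                                                 "K_m_H_M", "hill_h")}})
    if callable(truth):
        return truth, {"model": "callable"}
    truth = tuple(truth)
    if len(truth) == 2:
        I_max, K_m = truth
        return (lambda c: I_max * c / (c + K_m),
                {"model": "mm", "I_max": I_max, "K_m": K_m})
    if len(truth) == 3:
        I_max, K_m, h = truth
        return (lambda c: I_max * c ** h / (c ** h + K_m ** h),
                {"model": "hill", "I_max": I_max, "K_m": K_m, "h": h})
    raise InvalidInputError("truth must be a preset, a callable, "
                            "(I_max, K_m) or (I_max, K_m, h)")


def generate_dose_response(truth, concs: Sequence[float], noise: NoiseModel,
                           n_replicates: int = 1, pH: float = 4.5,
                           substrate: str = "K+") -> DoseResponseDataset:
    """Noisy replicate dose-response measurements around a known truth.

    Each response is ``model(c) * (1 + cv*z) + additive_sd*z'`` with
    independent standard normal draws, clipped at zero (responses are
    magnitudes).  The generating parameters, noise model and seed are
    recorded in the dataset's ``meta`` for round-trip tests.
    """
    concs = np.sort(np.unique(np.asarray(list(concs), dtype=float)))
    if concs.size == 0:
        raise InvalidInputError("concs must be nonempty")
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    curve, truth_rec = _truth_curve(truth, pH)
    model_vals = np.array([curve(c) for c in concs])

    rng = noise.rng()
    conc_all, resp_all, rep_all = [], [], []
    for r in range(n_replicates):
        z = rng.standard_normal(concs.size)
        z2 = rng.standard_normal(concs.size)
        resp = model_vals * (1.0 + noise.cv * z) + noise.additive_sd_A * z2
        conc_all.append(concs)
        resp_all.append(np.clip(resp, 0.0, None))
        rep_all.append(np.full(concs.size, r, dtype=int))
    meta = {"truth": truth_rec, "pH": pH, "seed": noise.seed,
            "cv": noise.cv, "additive_sd_A": noise.additive_sd_A,
            "model_values": model_vals.tolist()}
    return DoseResponseDataset(conc_M=np.concatenate(conc_all),
                               response=np.concatenate(resp_all),
                               replicate=np.concatenate(rep_all),
                               substrate=substrate, meta=meta)


def simulate_tevc_trace(source, protocol: StepProtocol,
                        noise: NoiseModel,
                        tau_act_s: float = 0.7,
                        tau_inact_s: float = 20.0) -> TEVCTrace:
    """Simulate a whole-cell current trace for a concentration-step protocol.

    Per segment the current change rises mono-exponentially (``tau_act_s``)
    toward the peak level and relaxes mono-exponentially (``tau_inact_s``)
    toward the steady-state level:

        dI(t) = (ss + (peak - ss) e^{-t/tau_inact}) (1 - e^{-t/tau_act}).

    ``source`` is an :class:`OocytePreset` (peak and steady state from the
    phenomenological surface) or a :class:`KineticParams` set (peak from the
    steady-state cycle current; the pure cycle model has no inactivation,
    so the steady state equals the peak).  The default time constants put
    the peak near 2 s and let high-K+ currents vanish within the 120 s
    pulse.  Inward currents are negative; a leak current drawn once per
    trace is added, then multiplicative and additive noise.

    The returned trace's ``truth`` records, per segment, both the target
    levels and the achieved (sampled, noiseless) peak and late-window mean
    for round-trip tests.
    """
    if tau_act_s <= 0 or tau_inact_s <= 0:
        raise InvalidInputError("time constants must be positive")
    if isinstance(source, OocytePreset):
        def levels(seg: Segment):
            return (source.peak_response(seg.conc_M, seg.pH),
                    source.ss_response(seg.conc_M, seg.pH))
    elif isinstance(source, KineticParams):
        def levels(seg: Segment):
            cond = Conditions(V_mV=protocol.holding_mV, K_out_M=seg.conc_M,
                              H_out_M=10.0 ** -seg.pH)
            peak = abs(steady_state_current(source, cond).I)
            return peak, peak
    else:
        raise InvalidInputError(
            "source must be an OocytePreset or KineticParams")

    dt = 1.0 / protocol.sampling_hz
    rng = noise.rng()
    leak = noise.leak_mean_A + noise.leak_sd_A * rng.standard_normal()

    t_parts, sig_parts, truth_segments = [], [], []
    t0 = 0.0
    for seg in protocol.segments:
        n = max(1, int(round(seg.duration_s * protocol.sampling_hz)))
        tl = (np.arange(n) + 0.5) * dt  # sample mid-intervals, local time
        peak, ss = levels(seg)
        dI = ((ss + (peak - ss) * np.exp(-tl / tau_inact_s))
              * (1.0 - np.exp(-tl / tau_act_s)))
        t_parts.append(t0 + tl)
        sig_parts.append(-dI)  # inward negative
        n_tail = max(1, int(math.ceil(0.05 * n)))
        truth_segments.append({
            "conc_M": seg.conc_M, "pH": seg.pH, "substrate": seg.substrate,
            "dI_peak_target_A": peak, "dI_ss_target_A": ss,
            "dI_peak_achieved_A": float(dI.max()),
            "dI_ss_achieved_A": float(dI[-n_tail:].mean()),
        })
        t0 += seg.duration_s

    t = np.concatenate(t_parts)
    signal = np.concatenate(sig_parts)
    z = rng.standard_normal(t.size)
    z2 = rng.standard_normal(t.size)
    current = leak + signal * (1.0 + noise.cv * z) + noise.additive_sd_A * z2
    truth = {"leak_A": float(leak), "tau_act_s": tau_act_s,
             "tau_inact_s": tau_inact_s, "seed": noise.seed,
             "segments": truth_segments}
    return TEVCTrace(time_s=t, current_A=current, protocol=protocol,
                     truth=truth)
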