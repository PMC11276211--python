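"""Forward models of the oxygen-evolving complex S-state cycle under flash trains.

The oxygen-evolving complex (OEC) of photosystem II steps through the Kok
cycle S0 -> S1 -> S2 -> S3 -> (S4) -> S0 under saturating flashes, releasing
one O2 per turn of the cycle.  This module implements two families of forward
models for the flash-number dependence of the detected O2 amplitude:

* classic Kok variants: a single miss probability ``alpha`` per flash,
  optionally with a double-hit fraction ``gamma`` acting from S0 and S1;
* a heterogeneous five-state model: per-transition misses ``alpha_i`` and a
  bifurcation of the S3 -> S0 step, where a fraction ``d`` of advancing
  centers releases O2 promptly (short-lived S4) and the remaining ``1 - d``
  enters a metastable pool S4' that relaxes to S0 with first-order kinetics
  (time constant ``tau_s4p``), releasing O2 slowly.

Detected amplitudes are damped flash-by-flash by a geometric factor
``C**(n-1)`` (1-based flash index ``n``) attributed to depletion of the
plastoquinone acceptor pool; the damping acts on the measured amplitude, not
on the state vector, so center probability is conserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ModelMismatchError, NormalizationError, ParameterError, ProtocolError

__all__ = [
    "SStateVector",
    "FiveSParams",
    "KokParams",
    "FlashProtocol",
    "FlashPattern",
    "flash_transition",
    "interflash_relaxation",
    "detected_amplitude",
    "flash_transition_kok",
    "simulate_pattern",
    "simulate_pattern_detailed",
    "normalize_to_y3",
    "total_miss",
]

_SUM_ATOL = 1e-12


def _check_prob(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class SStateVector:
    """Occupancies of S0..S3 plus the metastable S4' pool.

    Components are ensemble fractions of active centers; they are
    non-negative and sum to one (centers recycle, they never leak).
    """

    s0: float
    s1: float
    s2: float
    s3: float
    s4p: float = 0.0

    def __post_init__(self) -> None:
        comps = self.as_array()
        if np.any(comps < -_SUM_ATOL):
            raise ParameterError(f"S-state occupancies must be >= 0, got {tuple(comps)}")
        if abs(float(comps.sum()) - 1.0) > 1e-9:
            raise ParameterError(
                f"S-state occupancies must sum to 1, got {float(comps.sum())!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3, self.s4p], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SStateVector":
        a = [float(x) for x in arr]
        if len(a) != 5:
            raise ParameterError("SStateVector requires 5 components")
        return cls(*a)


@dataclass(frozen=True)
class FiveSParams:
    """Parameters of the heterogeneous five-state model.

    Parameters
    ----------
    alpha : per-transition miss probabilities (alpha0..alpha3).
    d : fraction of the advancing S3 flux that releases O2 promptly.
    C : per-flash geometric damping of the detected amplitude, in (0, 1].
    init : initial occupancies (S0, S1, S2, S3); S4' starts empty in
        dark-adapted material.
    tau_s4p : first-order relaxation time constant of S4' -> S0, ms.
    window_ms : length of the amplitude-detection window after a flash, ms;
        the fraction ``1 - exp(-window_ms / tau_s4p)`` of freshly created
        slow release is captured in the flash's own amplitude.
    """

    alpha: tuple[float, float, float, float]
    d: float
    C: float
    init: tuple[float, float, float, float]
    tau_s4p: float = 150.0
    window_ms: float = 30.0

    def __post_init__(self) -> None:
        if len(self.alpha) != 4:
            raise ParameterError("alpha must have four components (alpha0..alpha3)")
        object.__setattr__(self, "alpha", tuple(_check_prob(f"alpha{i}", a)
                                                for i, a in enumerate(self.alpha)))
        _check_prob("d", self.d)
        if not (0.0 < self.C <= 1.0):
            raise ParameterError(f"C must be in (0, 1], got {self.C!r}")
        if len(self.init) != 4:
            raise ParameterError("init must give (S0, S1, S2, S3)")
        init = tuple(float(x) for x in self.init)
        if any(x < 0 for x in init):
            raise ParameterError(f"init occupancies must be >= 0, got {init}")
        if abs(sum(init) - 1.0) > 1e-9:
            raise ParameterError(f"init occupancies must sum to 1, got {sum(init)!r}")
        object.__setattr__(self, "init", init)
        if not self.tau_s4p > 0:
            raise ParameterError("tau_s4p must be > 0")
        if not self.window_ms > 0:
            raise ParameterError("window_ms must be > 0")

    @property
    def window_capture(self) -> float:
        """Fraction of freshly created slow release seen within the window."""
        return 1.0 - math.exp(-self.window_ms / self.tau_s4p)

    def initial_state(self) -> SStateVector:
        return SStateVector(*self.init, 0.0)


@dataclass(frozen=True)
class KokParams:
    """Classic Kok-model parameters: equal misses, optional double hits.

    ``gamma`` is the double-hit fraction; following the convention adopted
    here it acts only from S0 and S1.  ``alpha + gamma <= 1`` is required.
    """

    alpha: float
    gamma: float
    C: float
    init: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        _check_prob("alpha", self.alpha)
        _check_prob("gamma", self.gamma)
        if self.alpha + self.gamma > 1.0 + 1e-12:
            raise ParameterError(
                f"alpha + gamma must be <= 1, got {self.alpha + self.gamma!r}"
            )
        if not (0.0 < self.C <= 1.0):
            raise ParameterError(f"C must be in (0, 1], got {self.C!r}")
        init = tuple(float(x) for x in self.init)
        if len(init) != 4 or any(x < 0 for x in init) or abs(sum(init) - 1.0) > 1e-9:
            raise ParameterError(f"init must be a length-4 distribution, got {init}")
        object.__setattr__(self, "init", init)

    def initial_state(self) -> SStateVector:
        return SStateVector(*self.init, 0.0)


@dataclass(frozen=True)
class FlashProtocol:
    """Timing of a saturating-flash train (times in ms, strictly increasing)."""

    flash_times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.flash_times)
        if len(times) < 1:
            raise ProtocolError("a protocol needs at least one flash")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ProtocolError("flash times must be strictly increasing")
        object.__setattr__(self, "flash_times", times)

    @property
    def count(self) -> int:
        return len(self.flash_times)

    @classmethod
    def standard(cls, n_flashes: int = 16, interval_ms: float = 300.0) -> "FlashProtocol":
        """The standard train: ``n_flashes`` flashes, equally spaced."""
        return cls(tuple(i * interval_ms for i in range(n_flashes)))

    @classmethod
    def with_varied_interval(
        cls,
        varied_pair: str,
        interval_ms: float,
        n_flashes: int = 16,
        base_interval_ms: float = 300.0,
    ) -> "FlashProtocol":
        """A train where one early interval is varied and the rest are standard.

        ``varied_pair`` selects the varied gap: ``"1-2"`` (between flashes 1
        and 2) or ``"2-3"`` (between flashes 2 and 3).  The varied interval
        must lie in the instrument's 5-500 ms range.
        """
        if varied_pair not in ("1-2", "2-3"):
            raise ProtocolError(f"varied_pair must be '1-2' or '2-3', got {varied_pair!r}")
        if not (5.0 <= interval_ms <= 500.0):
            raise ProtocolError(
                f"varied interval must be in [5, 500] ms, got {interval_ms!r}"
            )
        gaps = [base_interval_ms] * (n_flashes - 1)
        gaps[0 if varied_pair == "1-2" else 1] = interval_ms
        times = [0.0]
        for g in gaps:
            times.append(times[-1] + g)
        return cls(tuple(times))


@dataclass(frozen=True)
class FlashPattern:
    """Per-flash detected O2 amplitudes (flash 1 first).

    ``normalization`` is ``"raw"`` for model/instrument units or ``"y3"``
    once amplitudes are expressed relative to the third flash.
    """

    amplitudes: np.ndarray
    errors: np.ndarray | None = None
    normalization: str = "raw"

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1 or amps.size < 1:
            raise ParameterError("amplitudes must be a 1-d array")
        if np.any(amps < 0) or np.any(~np.isfinite(amps)):
            raise ParameterError("amplitudes must be finite and >= 0")
        object.__setattr__(self, "amplitudes", amps)
        if self.errors is not None:
            errs = np.asarray(self.errors, dtype=float)
            if errs.shape != amps.shape or np.any(errs < 0):
                raise ParameterError("errors must match amplitudes and be >= 0")
            object.__setattr__(self, "errors", errs)
        if self.normalization not in ("raw", "y3"):
            raise ParameterError(f"unknown normalization tag {self.normalization!r}")
        if self.normalization == "y3":
            if amps.size < 3 or abs(amps[2] - 1.0) > 1e-9:
                raise ParameterError("y3-normalized patterns must have amplitude 1 at flash 3")

    @property
    def n_flashes(self) -> int:
        return int(self.amplitudes.size)


# ---------------------------------------------------------------------------
# elementary operations


def flash_transition(
    state: SStateVector, params: FiveSParams
) -> tuple[SStateVector, float, float]:
    """Apply one saturating flash under the five-state model.

    Each S_i (i = 0..2) retains ``alpha_i`` of its occupancy and passes the
    rest to S_{i+1}.  Of the advancing S3 flux, fraction ``d`` returns
    directly to S0 (prompt O2, returned as ``fast_yield``) and ``1 - d``
    enters the metastable S4' pool (returned as ``slow_pool_added``).
    Pre-existing S4' is inert to the flash.
    """
    a0, a1, a2, a3 = params.alpha
    adv3 = (1.0 - a3) * state.s3
    fast = params.d * adv3
    slow = (1.0 - params.d) * adv3
    new = SStateVector(
        s0=a0 * state.s0 + fast,
        s1=a1 * state.s1 + (1.0 - a0) * state.s0,
        s2=a2 * state.s2 + (1.0 - a1) * state.s1,
        s3=a3 * state.s3 + (1.0 - a2) * state.s2,
        s4p=state.s4p + slow,
    )
    return new, fast, slow


def interflash_relaxation(
    state: SStateVector, dt_ms: float, params: FiveSParams
) -> tuple[SStateVector, float]:
    """First-order decay of the S4' pool back to S0 over a dark interval.

    Returns the relaxed state and the fraction of the ensemble that released
    O2 slowly (the decayed part of S4').
    """
    if dt_ms < 0:
        raise ParameterError(f"dt_ms must be >= 0, got {dt_ms!r}")
    decayed = state.s4p * (1.0 - math.exp(-dt_ms / params.tau_s4p))
    new = replace(state, s0=state.s0 + decayed, s4p=state.s4p - decayed)
    return new, decayed


def detected_amplitude(
    fast_yield: float, slow_pool_added: float, flash_index: int, params: FiveSParams
) -> float:
    """Detected O2 amplitude for one flash (1-based ``flash_index``).

    The prompt release is counted fully; of the slow release created by this
    flash only the fraction decaying within the detection window,
    ``w = 1 - exp(-window_ms / tau_s4p)``, contributes to the peak.  The
    whole amplitude is damped by the geometric acceptor-pool factor
    ``C**(flash_index - 1)``.
    """
    if flash_index < 1:
        raise ParameterError("flash_index is 1-based and must be >= 1")
    w = params.window_capture
    return params.C ** (flash_index - 1) * (fast_yield + slow_pool_added * w)


def flash_transition_kok(
    state: SStateVector, params: KokParams
) -> tuple[SStateVector, float]:
    """Apply one flash under the classic Kok model (equal misses, double hits).

    Double hits (fraction ``gamma``) act from S0 and S1 only.  All O2
    release is prompt; the S4' pool must be empty.
    """
    if state.s4p != 0.0:
        raise ModelMismatchError("Kok variants have no S4' pool; s4p must be 0")
    a, g = params.alpha, params.gamma
    single = 1.0 - a - g
    y = (1.0 - a) * state.s3
    new = SStateVector(
        s0=a * state.s0 + y,
        s1=a * state.s1 + single * state.s0,
        s2=a * state.s2 + single * state.s1 + g * state.s0,
        s3=a * state.s3 + (1.0 - a) * state.s2 + g * state.s1,
        s4p=0.0,
    )
    return new, y


# ---------------------------------------------------------------------------
# pattern simulation


def simulate_pattern_detailed(
    params: FiveSParams | KokParams, protocol: FlashProtocol
) -> tuple[FlashPattern, np.ndarray, np.ndarray]:
    """Simulate a flash train, returning the raw pattern plus per-flash
    prompt yields and slow-pool additions (both before C damping).

    Flashes are instantaneous; between consecutive flashes the S4' pool
    relaxes for the full inter-flash interval.
    """
    n = protocol.count
    amps = np.empty(n)
    fast_arr = np.zeros(n)
    slow_arr = np.zeros(n)
    state = params.initial_state()
    if isinstance(params, FiveSParams):
        for i, t in enumerate(protocol.flash_times):
            if i > 0:
                dt = t - protocol.flash_times[i - 1]
                state, _ = interflash_relaxation(state, dt, params)
            state, fast, slow = flash_transition(state, params)
            fast_arr[i], slow_arr[i] = fast, slow
            amps[i] = detected_amplitude(fast, slow, i + 1, params)
    elif isinstance(params, KokParams):
        for i in range(n):
            state, y = flash_transition_kok(state, params)
            fast_arr[i] = y
            amps[i] = params.C**i * y
    else:
        raise ParameterError(f"unsupported parameter type {type(params).__name__}")
    return FlashPattern(amps, normalization="raw"), fast_arr, slow_arr


def simulate_pattern(
    params: FiveSParams | KokParams, protocol: FlashProtocol
) -> FlashPattern:
    """Deterministic raw O2 yield pattern for a flash protocol."""
    pattern, _, _ = simulate_pattern_detailed(params, protocol)
    return pattern


def normalize_to_y3(pattern: FlashPattern) -> FlashPattern:
    """Express amplitudes relative to the third-flash amplitude Y3.

    Idempotent; errors, if present, are scaled identically.
    """
    if pattern.n_flashes < 3:
        raise NormalizationError("need at least three flashes to normalize to Y3")
    y3 = pattern.amplitudes[2]
    scale_floor = max(pattern.amplitudes.max(), 1.0) * 1e-12
    if y3 <= scale_floor:
        raise NormalizationError(f"third-flash amplitude is zero or near zero ({y3!r})")
    errs = None if pattern.errors is None else pattern.errors / y3
    return FlashPattern(pattern.amplitudes / y3, errors=errs, normalization="y3")


def total_miss(params: FiveSParams) -> float:
    """Total miss alpha_t = alpha0 + alpha1 + alpha2 + alpha3."""
    return float(sum(params.alpha))
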