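"""Synthetic-data generators emulating fast-polarography measurements.

Every stage of the analysis pipeline can be exercised without external
data: a per-center Monte-Carlo sampler of the five-state scheme (the
brute-force oracle for the deterministic ensemble model), noisy flash
pattern replicates, Y3-versus-interval kinetics datasets, and raw
polarographic current traces (flash-locked peaks on a drifting, noisy
baseline) together with peak-amplitude extraction.

The trace model is phenomenological: real electrode signals depend on
sample contact and thickness and are not analyzed for shape here.  Each
flash injects a peak-normalized double-exponential pulse carrying the
flash's detected amplitude (prompt release plus the window-captured part of
the slow release), and the remaining slow release is spread as a low, broad
tail with the S4' relaxation constant.  Peak-minus-baseline extraction on a
clean trace therefore returns the detected amplitude to within the sampling
quadrature of the kernel peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ProtocolError
from .kinetics import BiexpParams, KineticsDataset, biexp_value
from .sstate import (
    FiveSParams,
    FlashPattern,
    FlashProtocol,
    normalize_to_y3,
    simulate_pattern_detailed,
)

__all__ = [
    "TraceConfig",
    "PolarographicTrace",
    "monte_carlo_pattern",
    "generate_pattern_dataset",
    "generate_kinetics_dataset",
    "simulate_trace",
    "trace_from_amplitudes",
    "extract_amplitudes",
    "generate_kinetics_traces",
]


@dataclass(frozen=True)
class TraceConfig:
    """Phenomenological polarographic trace parameters.

    ``rise_tau_ms`` shapes the O2 arrival at the electrode surface and
    ``electrode_tau_ms`` its consumption/diffusion decay; together they set
    the double-exponential pulse shape.  Drift and noise are in the same
    arbitrary current units as ``amplitude_scale``.
    """

    sampling_rate: float = 10_000.0
    rise_tau_ms: float = 2.0
    electrode_tau_ms: float = 6.0
    baseline_drift_per_s: float = 0.0
    noise_sd: float = 0.0
    amplitude_scale: float = 1.0
    lead_in_ms: float = 50.0
    tail_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.sampling_rate < 1000.0:
            raise ParameterError("sampling_rate must be >= 1000 Hz")
        if self.rise_tau_ms <= 0 or self.electrode_tau_ms <= 0:
            raise ParameterError("kernel time constants must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate


@dataclass(frozen=True)
class PolarographicTrace:
    """Uniformly sampled current trace with the flash times that produced it."""

    times: np.ndarray  # ms
    current: np.ndarray
    flash_times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        current = np.asarray(self.current, dtype=float)
        if times.shape != current.shape or times.ndim != 1:
            raise ParameterError("times and current must be matching 1-d arrays")
        steps = np.diff(times)
        if times.size > 1 and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ParameterError("trace must be uniformly sampled")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "current", current)
        object.__setattr__(self, "flash_times", tuple(float(t) for t in self.flash_times))


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def monte_carlo_pattern(
    params: FiveSParams,
    protocol: FlashProtocol,
    n_centers: int,
    seed: int | None,
) -> FlashPattern:
    """Per-center stochastic sampling of the five-state scheme.

    Each center holds a discrete state in {S0..S3, S4'}; flashes advance it
    with probability ``1 - alpha_i``, the advancing S3 fraction splits
    ``d : 1 - d`` between prompt release and the S4' pool, and S4' decays to
    S0 between flashes with probability ``1 - exp(-dt/tau)``.  The detected
    amplitude applies the same window capture and geometric damping as the
    deterministic model.  Serves as the independent brute-force oracle for
    ``simulate_pattern``; reproducible by seed.
    """
    if n_centers < 1:
        raise ParameterError("n_centers must be >= 1")
    rng = np.random.default_rng(seed)
    states = rng.choice(4, size=n_centers, p=np.asarray(params.init))
    alpha = np.asarray(params.alpha)
    w = params.window_capture
    amps = np.empty(protocol.count)
    for n, t in enumerate(protocol.flash_times):
        if n > 0:
            dt = t - protocol.flash_times[n - 1]
            p_decay = 1.0 - math.exp(-dt / params.tau_s4p)
            pool = states == 4
            decayed = pool & (rng.random(n_centers) < p_decay)
            states[decayed] = 0
        u = rng.random(n_centers)
        new = states.copy()
        for i in range(3):
            advancing = (states == i) & (u >= alpha[i])
            new[advancing] = i + 1
        adv3 = (states == 3) & (u >= alpha[3])
        go_fast = adv3 & (rng.random(n_centers) < params.d)
        go_slow = adv3 & ~go_fast
        new[go_fast] = 0
        new[go_slow] = 4
        states = new
        fast_frac = go_fast.sum() / n_centers
        slow_frac = go_slow.sum() / n_centers
        amps[n] = params.C**n * (fast_frac + slow_frac * w)
    return FlashPattern(amps, normalization="raw")


# ---------------------------------------------------------------------------
# dataset generators


def generate_pattern_dataset(
    params: FiveSParams,
    protocol: FlashProtocol,
    noise_sd: float,
    n_replicates: int,
    seed: int | None,
) -> list[FlashPattern]:
    """Noisy Y3-normalized flash-pattern replicates.

    ``noise_sd`` is expressed on the Y3-normalized scale (the scale of
    published flash-pattern error bars): Gaussian noise of that standard
    deviation, truncated at zero, is added to the normalized amplitudes and
    each replicate is then re-normalized to its own third flash, as in the
    measurement convention.  Truncation at zero slightly biases very small
    amplitudes.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base, _, _ = simulate_pattern_detailed(params, protocol)
    base_norm = normalize_to_y3(base)
    out = []
    for _ in range(n_replicates):
        noisy = base_norm.amplitudes + rng.normal(0.0, noise_sd, size=base.n_flashes) \
            if noise_sd > 0 else base_norm.amplitudes.copy()
        noisy = np.maximum(noisy, 0.0)
        out.append(normalize_to_y3(FlashPattern(noisy, normalization="raw")))
    return out


def generate_kinetics_dataset(
    p: BiexpParams,
    dt_grid=None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    varied_pair: str = "2-3",
    seed: int | None = None,
) -> KineticsDataset:
    """Y3(dt) dataset following the saturating biexponential law plus noise.

    Values are on the normalized scale (the law is the post-normalization
    quantity), so the dataset is tagged ``scaled`` and can be fitted
    directly.  Rows with dt == 300 ms are the standard-protocol entries and
    are flagged ``is_standard``.  The same law is used for both varied-pair
    protocols, reflecting the linear S-state sequence.
    """
    from .kinetics import DEFAULT_DT_GRID

    if dt_grid is None:
        dt_grid = DEFAULT_DT_GRID
    dt_grid = [float(dt) for dt in dt_grid]
    if any(dt < 5.0 or dt > 500.0 for dt in dt_grid):
        raise ParameterError("dt_grid must lie within [5, 500] ms")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for dt in dt_grid:
            y = biexp_value(dt, p)
            if noise_sd > 0:
                y = max(0.0, y + rng.normal(0.0, noise_sd))
            rows.append({
                "dt_ms": dt, "y3": y, "replicate": rep, "series": 1,
                "is_standard": dt == 300.0,
            })
    return KineticsDataset(
        pd.DataFrame(rows), varied_pair=varied_pair, normalization_state="scaled"
    )


# ---------------------------------------------------------------------------
# polarographic traces


def _prompt_kernel(cfg: TraceConfig, length_ms: float) -> np.ndarray:
    """Peak-normalized double-exponential pulse on the sampling grid."""
    t = np.arange(0.0, length_ms, cfg.dt_ms)
    k = (1.0 - np.exp(-t / cfg.rise_tau_ms)) * np.exp(-t / cfg.electrode_tau_ms)
    peak = k.max()
    if peak <= 0:
        raise ParameterError("degenerate kernel: check time constants")
    return k / peak


def _tail_kernel(cfg: TraceConfig, tau_s4p: float, length_ms: float) -> np.ndarray:
    """Slow-release tail, normalized to unit area (per ms)."""
    t = np.arange(0.0, length_ms, cfg.dt_ms)
    g = (1.0 - np.exp(-t / cfg.rise_tau_ms)) * np.exp(-t / tau_s4p)
    area = g.sum() * cfg.dt_ms
    return g / area


def trace_from_amplitudes(
    prompt_amplitudes,
    flash_times,
    cfg: TraceConfig,
    seed: int | None = None,
    tail_amplitudes=None,
    tau_s4p: float = 150.0,
) -> PolarographicTrace:
    """Synthesize a trace from per-flash peak amplitudes.

    ``prompt_amplitudes`` set the pulse peak heights (already in current
    units); ``tail_amplitudes``, if given, are O2 fractions released slowly
    after each flash, spread over the S4' relaxation with the same area
    scaling per unit amplitude as the prompt pulse.
    """
    prompt = np.asarray(prompt_amplitudes, dtype=float)
    flash_times = [float(t) for t in flash_times]
    if prompt.size != len(flash_times):
        raise ParameterError("one amplitude per flash required")
    rng = np.random.default_rng(seed)
    t_end = flash_times[-1] + cfg.tail_ms
    times = np.arange(0.0, cfg.lead_in_ms + t_end, cfg.dt_ms)
    current = np.zeros_like(times)

    kernel = _prompt_kernel(cfg, length_ms=min(200.0, times[-1]))
    kernel_area = kernel.sum() * cfg.dt_ms
    tail = None
    if tail_amplitudes is not None:
        tail_amps = np.asarray(tail_amplitudes, dtype=float)
        tail = _tail_kernel(cfg, tau_s4p, length_ms=min(6.0 * tau_s4p, times[-1]))

    shifted = [cfg.lead_in_ms + t for t in flash_times]
    for i, t0 in enumerate(shifted):
        start = int(round(t0 / cfg.dt_ms))
        stop = min(start + kernel.size, times.size)
        current[start:stop] += prompt[i] * kernel[: stop - start]
        if tail is not None and tail_amps[i] > 0:
            stop_t = min(start + tail.size, times.size)
            # tail area per unit amplitude matches the prompt pulse area
            current[start:stop_t] += tail_amps[i] * kernel_area * tail[: stop_t - start]
    current += cfg.baseline_drift_per_s * times / 1000.0
    if cfg.noise_sd > 0:
        current += rng.normal(0.0, cfg.noise_sd, size=times.size)
    return PolarographicTrace(times, current, tuple(shifted))


def simulate_trace(
    params: FiveSParams,
    protocol: FlashProtocol,
    cfg: TraceConfig,
    seed: int | None = None,
) -> PolarographicTrace:
    """Raw polarographic trace for a flash train under the five-state model.

    Pulse peaks carry the detected amplitudes (prompt plus window-captured
    slow release, geometrically damped); the uncaptured slow release forms
    a broad tail with the S4' relaxation constant.
    """
    _, fast, slow = simulate_pattern_detailed(params, protocol)
    n = np.arange(fast.size)
    damp = params.C**n
    w = params.window_capture
    prompt = cfg.amplitude_scale * damp * (fast + slow * w)
    tails = cfg.amplitude_scale * damp * slow * (1.0 - w)
    return trace_from_amplitudes(
        prompt, protocol.flash_times, cfg, seed=seed,
        tail_amplitudes=tails, tau_s4p=params.tau_s4p,
    )


def extract_amplitudes(
    trace: PolarographicTrace,
    protocol: FlashProtocol | None = None,
    window_ms: float = 30.0,
    baseline_ms: float = 20.0,
) -> FlashPattern:
    """Peak-minus-baseline amplitude readout per flash.

    Amplitude = max current within ``window_ms`` after the flash minus the
    mean current over ``baseline_ms`` just before it, clipped at zero.  The
    composite window ``[t - baseline_ms, t + window_ms]`` must not contain a
    neighboring flash.
    """
    if window_ms <= 0 or baseline_ms <= 0:
        raise ParameterError("window_ms and baseline_ms must be > 0")
    flash_times = list(trace.flash_times)
    for i, t0 in enumerate(flash_times):
        if i + 1 < len(flash_times) and flash_times[i + 1] < t0 + window_ms:
            raise ProtocolError(
                f"detection window after flash {i + 1} overlaps flash {i + 2}"
            )
        if i > 0 and flash_times[i - 1] > t0 - baseline_ms:
            raise ProtocolError(
                f"baseline window before flash {i + 1} overlaps flash {i}"
            )
    times, current = trace.times, trace.current
    amps = np.empty(len(flash_times))
    for i, t0 in enumerate(flash_times):
        win = (times >= t0) & (times <= t0 + window_ms)
        base = (times >= t0 - baseline_ms) & (times < t0)
        if not win.any() or not base.any():
            raise ProtocolError(f"flash {i + 1} windows fall outside the trace")
        amps[i] = max(0.0, float(current[win].max() - current[base].mean()))
    return FlashPattern(amps, normalization="raw")


# ---------------------------------------------------------------------------
# kinetics traces (end-to-end plumbing)


def generate_kinetics_traces(
    kin_params: BiexpParams,
    template_params: FiveSParams,
    dt_grid=None,
    varied_pair: str = "2-3",
    cfg: TraceConfig | None = None,
    n_replicates: int = 1,
    seed: int | None = None,
) -> list[dict]:
    """Traces for a variable-interval protocol series.

    For each interval dt the third-flash amplitude follows the relaxation
    law (relative to its 300 ms value); the yield deficit is carried over to
    flash 4, as centers that fail to fire under flash 3 fire later, so the
    total yield Ys is conserved.  The remaining flashes follow the template
    preparation's standard pattern.  Returns records with keys ``dt_ms``,
    ``replicate``, ``is_standard``, ``trace``, ``protocol``.
    """
    from .kinetics import DEFAULT_DT_GRID

    if dt_grid is None:
        dt_grid = DEFAULT_DT_GRID
    if cfg is None:
        cfg = TraceConfig()
    rng = np.random.default_rng(seed)
    std_protocol = FlashProtocol.standard()
    _, fast, slow = simulate_pattern_detailed(template_params, std_protocol)
    w = template_params.window_capture
    damp = template_params.C ** np.arange(fast.size)
    template = cfg.amplitude_scale * damp * (fast + slow * w)
    y3_std = template[2]
    f300 = biexp_value(300.0, kin_params)
    records = []
    for rep in range(1, n_replicates + 1):
        for dt in dt_grid:
            dt = float(dt)
            protocol = FlashProtocol.with_varied_interval(varied_pair, dt)
            amps = template.copy()
            y3 = y3_std * biexp_value(dt, kin_params) / f300
            amps[2] = y3
            amps[3] = max(0.0, amps[3] + (y3_std - y3))  # deficit fires one flash later
            trace = trace_from_amplitudes(
                amps, protocol.flash_times, cfg,
                seed=int(rng.integers(2**31)),
            )
            records.append({
                "dt_ms": dt, "replicate": rep, "is_standard": dt == 300.0,
                "trace": trace, "protocol": protocol,
            })
    return records
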