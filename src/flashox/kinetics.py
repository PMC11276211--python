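"""Biphasic O2-release kinetics: the Y3(dt) relaxation analysis.

The variable flash-interval protocol measures the third-flash O2 amplitude
Y3 as a function of the interval dt preceding it (dt between flashes 1-2 or
2-3, 5-500 ms, all other flashes 300 ms apart).  Y3(dt) follows a
saturating rise

    Y3(t) = A_fast * (1 - exp(-t / tau_fast)) + A_slow * (1 - exp(-t / tau_slow))

whose two phases report the fast (~ms) and slow (~tens of ms) modes of
oxygen release.  This module provides the model function, the raw-to-scaled
normalization chain, one- and two-component least-squares fitting, a
small-sample-corrected information-criterion component count selection, and
the fixed-time-constant counter-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DataSchemaError, FitError, NormalizationError, ParameterError
from .fitting import FitResult

__all__ = [
    "BiexpParams",
    "KineticsDataset",
    "biexp_value",
    "normalize_kinetics",
    "fit_relaxation",
    "select_n_components",
    "fixed_tau_check",
    "DEFAULT_DT_GRID",
]

#: interval grid (ms) used for synthetic recovery runs, spanning 5-500 ms
DEFAULT_DT_GRID: tuple[float, ...] = (5, 10, 20, 40, 80, 120, 200, 300, 400, 500)

_NORMALIZATION_STATES = ("raw", "per_sum", "standardized", "scaled")


@dataclass(frozen=True)
class BiexpParams:
    """Amplitudes and time constants of the two O2-release phases.

    ``tau_fast < tau_slow`` by convention.  A single-component model is
    encoded as ``a_fast = 0`` with ``tau_fast = None``.
    """

    a_fast: float
    tau_fast: float | None
    a_slow: float
    tau_slow: float

    def __post_init__(self) -> None:
        if self.a_fast < 0 or self.a_slow < 0:
            raise ParameterError("amplitudes must be >= 0")
        if self.a_fast + self.a_slow <= 0:
            raise ParameterError("at least one amplitude must be positive")
        if not self.tau_slow > 0:
            raise ParameterError("tau_slow must be > 0")
        if self.a_fast > 0:
            if self.tau_fast is None or not self.tau_fast > 0:
                raise ParameterError("tau_fast must be > 0 when a_fast > 0")
            if not self.tau_fast < self.tau_slow:
                raise ParameterError("convention requires tau_fast < tau_slow")

    @property
    def total_amplitude(self) -> float:
        return self.a_fast + self.a_slow


def biexp_value(t_ms, p: BiexpParams):
    """Evaluate the saturating biexponential rise at time(s) ``t_ms`` (ms)."""
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t_ms must be >= 0")
    y = p.a_slow * (1.0 - np.exp(-t / p.tau_slow))
    if p.a_fast > 0:
        y = y + p.a_fast * (1.0 - np.exp(-t / p.tau_fast))
    return float(y) if np.isscalar(t_ms) else y


@dataclass(frozen=True)
class KineticsDataset:
    """Y3 amplitudes versus inter-flash interval, with replicate structure.

    ``data`` columns: ``dt_ms``, ``y3``, ``replicate``, ``series``,
    ``is_standard`` (True for the all-300 ms stability checks).
    ``varied_pair`` records which gap was varied ('1-2' or '2-3');
    ``normalization_state`` tracks the normalization chain.
    """

    data: pd.DataFrame
    varied_pair: str = "2-3"
    normalization_state: str = "scaled"

    def __post_init__(self) -> None:
        required = {"dt_ms", "y3", "replicate", "series", "is_standard"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataSchemaError(f"kinetics data missing columns: {sorted(missing)}")
        if self.varied_pair not in ("1-2", "2-3"):
            raise ParameterError(f"varied_pair must be '1-2' or '2-3', got {self.varied_pair!r}")
        if self.normalization_state not in _NORMALIZATION_STATES:
            raise ParameterError(f"unknown normalization state {self.normalization_state!r}")
        dt = self.data["dt_ms"].to_numpy(dtype=float)
        if np.any(dt < 5.0) or np.any(dt > 500.0):
            # the instrument protocol covers 5-500 ms; out-of-range rows are
            # kept (they may be bookkeeping entries) but flagged loudly
            warnings.warn(
                "dt_ms values outside the 5-500 ms protocol range", stacklevel=2
            )
        object.__setattr__(self, "data", self.data.reset_index(drop=True))

    @property
    def n_distinct_dt(self) -> int:
        return int(self.data["dt_ms"].nunique())


def normalize_kinetics(
    raw: pd.DataFrame,
    varied_pair: str = "2-3",
    stop_after: str = "scaled",
    scaling_window_ms: tuple[float, float] = (200.0, 500.0),
) -> KineticsDataset:
    """Run the three-stage normalization chain on raw flash-train measurements.

    ``raw`` is a long table with one row per flash per measurement, columns
    ``series``, ``replicate``, ``dt_ms``, ``is_standard``, ``flash``,
    ``amplitude``; every measurement must provide all 16 flash amplitudes.

    Stages:

    1. ``per_sum`` - each measurement's Y3 is divided by the sum of all its
       flash amplitudes Ys (cancels sample loading);
    2. ``standardized`` - divided by the series' mean standard ratio
       Y3(300)/Ys(300) (each series must contain at least one standard
       all-300 ms measurement);
    3. ``scaled`` - each series is rescaled so that its mean over the
       200-500 ms window matches the pooled mean over all series (puts
       independent measurement series on one curve).
    """
    required = {"series", "replicate", "dt_ms", "is_standard", "flash", "amplitude"}
    missing = required - set(raw.columns)
    if missing:
        raise DataSchemaError(f"raw kinetics table missing columns: {sorted(missing)}")
    if stop_after not in ("per_sum", "standardized", "scaled"):
        raise ParameterError(f"stop_after must be a normalization stage, got {stop_after!r}")

    keys = ["series", "replicate", "dt_ms", "is_standard"]
    rows = []
    for key, grp in raw.groupby(keys, sort=True):
        flashes = np.sort(grp["flash"].to_numpy())
        if len(flashes) != 16 or not np.array_equal(flashes, np.arange(1, 17)):
            raise DataSchemaError(
                f"measurement {key} must provide flashes 1..16, got {len(flashes)} rows"
            )
        amps = grp.sort_values("flash")["amplitude"].to_numpy(dtype=float)
        ys = amps.sum()
        if ys <= 0:
            raise NormalizationError(f"measurement {key} has zero total amplitude")
        rows.append(dict(zip(keys, key)) | {"y3": amps[2] / ys})
    df = pd.DataFrame(rows)

    if stop_after == "per_sum":
        return KineticsDataset(df, varied_pair=varied_pair, normalization_state="per_sum")

    # stage 2: per-series standardization by the mean standard ratio
    out = []
    for series, grp in df.groupby("series", sort=True):
        std = grp.loc[grp["is_standard"], "y3"]
        if std.empty:
            raise NormalizationError(
                f"series {series!r} has no standard (all-300 ms) measurement"
            )
        g = grp.copy()
        g["y3"] = g["y3"] / std.mean()
        out.append(g)
    df = pd.concat(out, ignore_index=True)
    if stop_after == "standardized":
        return KineticsDataset(df, varied_pair=varied_pair, normalization_state="standardized")

    # stage 3: cross-series scaling over the slow-saturation window
    lo, hi = scaling_window_ms
    in_window = (df["dt_ms"] >= lo) & (df["dt_ms"] <= hi)
    if not in_window.any():
        raise NormalizationError(f"no measurements with dt in [{lo}, {hi}] ms for scaling")
    pooled = df.loc[in_window, "y3"].mean()
    out = []
    for series, grp in df.groupby("series", sort=True):
        win = grp.loc[in_window.reindex(grp.index, fill_value=False), "y3"]
        if win.empty:
            raise NormalizationError(
                f"series {series!r} has no dt in [{lo}, {hi}] ms; cannot scale"
            )
        g = grp.copy()
        g["y3"] = g["y3"] * (pooled / win.mean())
        out.append(g)
    df = pd.concat(out, ignore_index=True)
    return KineticsDataset(df, varied_pair=varied_pair, normalization_state="scaled")


# ---------------------------------------------------------------------------
# fitting


def _require_normalized(ds: KineticsDataset) -> None:
    if ds.normalization_state not in ("standardized", "scaled"):
        raise NormalizationError(
            "kinetics fits require a standardized or scaled dataset, "
            f"got state {ds.normalization_state!r}"
        )


def _residual_weights(ds: KineticsDataset, weighted: bool) -> np.ndarray | None:
    if not weighted:
        return None
    # weight each point by the replicate RMS spread at its dt (floor avoids
    # zero-variance degeneracies on noiseless synthetic data)
    sd = ds.data.groupby("dt_ms")["y3"].transform("std").to_numpy(dtype=float)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, np.nan)
    floor = np.nanmedian(sd) if np.isfinite(sd).any() else 1.0
    sd = np.where(np.isfinite(sd), sd, floor if floor > 0 else 1.0)
    return 1.0 / np.maximum(sd, 1e-6)

#: initial (tau_fast, tau_slow) guesses for the deterministic multistart
_TAU_STARTS = ((2.0, 20.0), (4.0, 40.0), (8.0, 80.0), (2.0, 200.0), (20.0, 200.0))

#: fitted tau_fast / tau_slow above this is flagged effectively one-component
TAU_DEGENERACY_RATIO = 0.8


def fit_relaxation(
    ds: KineticsDataset,
    n_components: int = 2,
    seed: int | None = None,
    weighted: bool = False,
) -> tuple[BiexpParams, FitResult]:
    """Least-squares fit of the saturating relaxation model to Y3(dt).

    ``n_components=1`` fixes ``a_fast = 0`` and fits a single phase;
    ``n_components=2`` fits both phases from a deterministic multistart over
    time-constant pairs.  The tau ordering convention is enforced by
    swapping after the fit; a fit with ``tau_fast/tau_slow`` above
    ``TAU_DEGENERACY_RATIO`` is flagged effectively single-component via
    ``FitResult.extra['degenerate']``.
    """
    _require_normalized(ds)
    if n_components not in (1, 2):
        raise ParameterError("n_components must be 1 or 2")
    n_dt = ds.n_distinct_dt
    if n_components == 2 and n_dt < 6:
        raise FitError(f"two-component fit needs >= 6 distinct dt values, got {n_dt}")
    if n_components == 1 and n_dt < 3:
        raise FitError(f"one-component fit needs >= 3 distinct dt values, got {n_dt}")

    t = ds.data["dt_ms"].to_numpy(dtype=float)
    y = ds.data["y3"].to_numpy(dtype=float)
    wts = _residual_weights(ds, weighted)
    a_tot = max(float(np.max(y)), 1e-6)

    def run(x0, lb, ub, model):
        def resid(x):
            r = model(x) - y
            return r if wts is None else r * wts

        return optimize.least_squares(
            resid, x0, bounds=(lb, ub), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
        )

    if n_components == 1:
        model = lambda x: x[0] * (1.0 - np.exp(-t / x[1]))
        best = None
        nfev = 0
        for tau0 in (5.0, 20.0, 80.0, 300.0):
            res = run([a_tot, tau0], [0.0, 1e-3], [np.inf, 1e4], model)
            nfev += res.nfev
            if best is None or res.cost < best.cost:
                best = res
        a_slow, tau_slow = best.x
        params = BiexpParams(a_fast=0.0, tau_fast=None, a_slow=a_slow, tau_slow=tau_slow)
        degenerate = False
    else:
        model = lambda x: (
            x[0] * (1.0 - np.exp(-t / x[2])) + x[1] * (1.0 - np.exp(-t / x[3]))
        )
        best = None
        nfev = 0
        for tf0, ts0 in _TAU_STARTS:
            res = run(
                [0.5 * a_tot, 0.5 * a_tot, tf0, ts0],
                [0.0, 0.0, 1e-3, 1e-3],
                [np.inf, np.inf, 1e4, 1e4],
                model,
            )
            nfev += res.nfev
            if best is None or res.cost < best.cost:
                best = res
        af, asl, tf, tsl = best.x
        if tf > tsl:  # enforce the ordering convention
            af, asl, tf, tsl = asl, af, tsl, tf
        degenerate = (tsl > 0 and (tf / tsl) > TAU_DEGENERACY_RATIO) or (
            min(af, asl) <= 0.01 * (af + asl)  # vanishing second component
        )
        if af <= 0:
            params = BiexpParams(a_fast=0.0, tau_fast=None, a_slow=asl, tau_slow=tsl)
            degenerate = True
        elif tf >= tsl:
            # exactly equal taus collapse to one component
            params = BiexpParams(a_fast=0.0, tau_fast=None, a_slow=af + asl, tau_slow=tsl)
            degenerate = True
        else:
            params = BiexpParams(a_fast=af, tau_fast=tf, a_slow=asl, tau_slow=tsl)

    residuals = biexp_value(t, params) - y
    n_free = 2 if n_components == 1 else 4
    stderr = _stderr_from_jacobian(best, residuals, n_free)
    result = FitResult(
        model_kind=f"biexp{n_components}",
        params={
            "a_fast": params.a_fast,
            "tau_fast": params.tau_fast,
            "a_slow": params.a_slow,
            "tau_slow": params.tau_slow,
        },
        pfq=float(np.mean(residuals**2)),
        residuals=residuals,
        n_free=n_free,
        converged=bool(best.status > 0),
        n_evaluations=int(nfev),
        observed=y,
        extra={"degenerate": bool(degenerate), "stderr": stderr},
    )
    return params, result


def _stderr_from_jacobian(res, residuals: np.ndarray, n_free: int) -> list[float] | None:
    """Parameter standard errors from the residual covariance at the optimum."""
    n = residuals.size
    if n <= n_free:
        return None
    s2 = float(residuals @ residuals) / (n - n_free)
    try:
        jtj = res.jac.T @ res.jac
        cov = s2 * np.linalg.pinv(jtj)
        return [float(x) for x in np.sqrt(np.maximum(np.diag(cov), 0.0))]
    except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
        return None


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC for Gaussian residuals (k counts sigma)."""
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def select_n_components(ds: KineticsDataset, seed: int | None = None) -> dict:
    """Choose between one and two relaxation components.

    Both models are fitted; the two-component model is selected only when
    its residual sum of squares improves on the one-component fit by more
    than the corrected-AIC penalty for its two extra parameters.  Returns a
    report with both fits and the criterion values.
    """
    p1, r1 = fit_relaxation(ds, n_components=1, seed=seed)
    p2, r2 = fit_relaxation(ds, n_components=2, seed=seed)
    n = r1.residuals.size
    rss1 = float(r1.residuals @ r1.residuals)
    rss2 = float(r2.residuals @ r2.residuals)
    aicc1 = _aicc(rss1, n, k=3)  # A_slow, tau_slow, sigma
    aicc2 = _aicc(rss2, n, k=5)  # + A_fast, tau_fast
    selected = 2 if (aicc2 < aicc1 and not r2.extra["degenerate"]) else 1
    return {
        "selected": selected,
        "aicc": {1: aicc1, 2: aicc2},
        "rss": {1: rss1, 2: rss2},
        "fits": {1: (p1, r1), 2: (p2, r2)},
    }


def fixed_tau_check(ds: KineticsDataset, taus: tuple[float, float]) -> dict:
    """Amplitude-only fit with both time constants held fixed.

    Used as a counter-check: can the dataset be reproduced by the two-phase
    model of another preparation's time constants?  The amplitudes are the
    only free parameters, so the problem is linear and solved by
    non-negative least squares.  Returns residual statistics for comparison
    with the free fit.
    """
    _require_normalized(ds)
    tau_fast, tau_slow = taus
    if not (tau_fast > 0 and tau_slow > 0):
        raise ParameterError("both time constants must be > 0")
    t = ds.data["dt_ms"].to_numpy(dtype=float)
    y = ds.data["y3"].to_numpy(dtype=float)
    design = np.column_stack([1.0 - np.exp(-t / tau_fast), 1.0 - np.exp(-t / tau_slow)])
    amps, _ = optimize.nnls(design, y)
    residuals = design @ amps - y
    rss = float(residuals @ residuals)
    return {
        "a_fast": float(amps[0]),
        "a_slow": float(amps[1]),
        "tau_fast": float(tau_fast),
        "tau_slow": float(tau_slow),
        "rss": rss,
        "rmse": math.sqrt(rss / y.size),
        "residuals": residuals,
    }
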