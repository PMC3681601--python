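"""FRAP recovery-curve correction, normalization, model fitting and selection.

The recovery of fluorescence after photobleaching a spindle region is
modelled as the sum of up to two exponentially recovering populations,

    F(t) = f * (1 - 2**(-t / tf_half)) + s * (1 - 2**(-t / ts_half)),

where ``f`` and ``s`` are the proportions of the fast and slow populations
and ``tf_half``/``ts_half`` their half-recovery times.  Half-times use a
base-2 decay (rate ``k = ln 2 / t_half``) so fitted values are directly the
times at which a population reaches half of its final recovered level.
``f + s`` may be less than 1; the remainder is an immobile (non-turnover)
population that never recovers within the observation window.

Three nested model kinds are supported:

``full_single``
    one recovering population with full recovery (plateau fixed at 1);
``single_plus_immobile``
    one recovering population with a free plateau ``f <= 1`` (the
    complement ``1 - f`` is immobile);
``two_population``
    two recovering populations with distinct half-times
    (reported with ``tf_half < ts_half``).

Raw traces are first corrected for acquisition-induced photobleaching
against a non-bleached control, then normalized between the pre-bleach
mean and the first post-bleach intensity so that 0 is the bleach floor and
1 is full recovery to the pre-bleach level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MODEL_KINDS",
    "FrapTrace",
    "NormalizedTrace",
    "RecoveryParams",
    "FitResult",
    "correct_photobleach",
    "normalize_trace",
    "model_recovery",
    "fit_recovery",
    "select_model",
    "pool_traces",
]

MODEL_KINDS = ("full_single", "single_plus_immobile", "two_population")

#: Minimum number of post-bleach samples required for any fit.
MIN_POST_BLEACH = 4


@dataclass(frozen=True)
class FrapTrace:
    """A raw fluorescence recovery time series.

    Pre-bleach frames carry negative times; ``t = 0`` is the first
    post-bleach frame.
    """

    times: np.ndarray
    intensities: np.ndarray
    n_pre: int
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        if times.ndim != 1 or times.shape != intens.shape:
            raise ValueError("times and intensities must be 1-D and congruent")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1")
        if self.n_pre >= times.size:
            raise ValueError("n_pre must leave at least one post-bleach frame")
        if np.any(intens < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def pre_times(self) -> np.ndarray:
        return self.times[: self.n_pre]

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_pre :]

    @property
    def pre_mean(self) -> float:
        """Mean intensity over the pre-bleach frames."""
        return float(np.mean(self.intensities[: self.n_pre]))


@dataclass(frozen=True)
class NormalizedTrace:
    """A corrected trace normalized to [bleach floor, pre-bleach level].

    ``values[0]`` is 0 by construction (the bleach instant) and full
    recovery to the pre-bleach level maps to 1.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D and congruent")
        if times[0] != 0:
            raise ValueError("normalized trace must start at t = 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("normalized values must be finite")


@dataclass(frozen=True)
class RecoveryParams:
    """Parameters of the recovery model family.

    ``f``/``tf_half`` describe the fast population and ``s``/``ts_half``
    the slow one; unused terms are zero for the single-population kinds.
    """

    model_kind: str
    f: float = 0.0
    s: float = 0.0
    tf_half: float = 1.0
    ts_half: float = 1.0

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(
                f"model_kind must be one of {MODEL_KINDS}, got {self.model_kind!r}"
            )
        if self.f < 0 or self.s < 0:
            raise ValueError("population fractions must be non-negative")
        if self.f + self.s > 1 + 1e-9:
            raise ValueError("f + s must not exceed 1")
        if self.model_kind == "full_single":
            if abs(self.f + self.s - 1.0) > 1e-9:
                raise ValueError("full_single requires f + s = 1")
            if self.s != 0:
                raise ValueError("full_single uses a single rate: set f=1, s=0")
        if self.model_kind == "single_plus_immobile" and self.s != 0:
            raise ValueError("single_plus_immobile uses a single rate: set s=0")
        if self.f > 0 and self.tf_half <= 0:
            raise ValueError("tf_half must be positive")
        if self.s > 0 and self.ts_half <= 0:
            raise ValueError("ts_half must be positive")
        if self.model_kind == "two_population" and self.tf_half >= self.ts_half:
            raise ValueError(
                "two_population requires tf_half < ts_half (relabel populations)"
            )

    @property
    def mobile_fraction(self) -> float:
        return self.f + self.s

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.f - self.s


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded multistart least-squares fit."""

    params: RecoveryParams
    rss: float
    n_obs: int
    aicc: float
    converged: bool
    n_starts_used: int
    n_free_params: int = 0
    se: dict | None = None


def _n_free(kind: str, free_total: bool) -> int:
    if kind == "full_single":
        return 1
    if kind == "single_plus_immobile":
        return 2
    return 4 if free_total else 3


# ---------------------------------------------------------------------------
# trace preparation


def correct_photobleach(sample: FrapTrace, control: FrapTrace) -> FrapTrace:
    """Correct a bleached trace for acquisition-induced photobleaching.

    The control is a non-bleached spindle imaged under the same protocol;
    its decay estimates the fluorescence loss caused by imaging itself.
    The corrected intensity is::

        F_corr(t) = F(t) * C_pre / F_control(t)

    where ``C_pre`` is the mean pre-bleach control intensity.  The control
    is linearly interpolated onto the sample's time grid if the grids
    differ; its range must cover the sample's.
    """
    if np.any(control.intensities <= 0):
        raise ValueError("control intensities must be strictly positive")
    if (
        control.times[0] > sample.times[0] + 1e-9
        or control.times[-1] < sample.times[-1] - 1e-9
    ):
        raise ValueError("control time range does not cover the sample's")
    ctrl_at = np.interp(sample.times, control.times, control.intensities)
    c_pre = control.pre_mean
    corrected = sample.intensities * (c_pre / ctrl_at)
    return replace(sample, intensities=corrected)


def normalize_trace(corrected: FrapTrace, atol: float = 1e-9) -> NormalizedTrace:
    """Normalize a corrected trace between pre-bleach mean and bleach floor.

    ``F_norm(t) = (F_corr(t) - F_corr(0)) / (F_pre_mean - F_corr(0))``,
    evaluated over the post-bleach frames only, so that the bleach instant
    maps to 0 and full recovery to the pre-bleach level maps to 1.
    """
    post_t = corrected.post_times
    if post_t.size < 1 or abs(post_t[0]) > atol:
        raise ValueError("corrected trace must contain a post-bleach frame at t = 0")
    post_i = corrected.intensities[corrected.n_pre :]
    f0 = post_i[0]
    denom = corrected.pre_mean - f0
    if abs(denom) <= atol * max(1.0, corrected.pre_mean):
        raise ValueError("no bleach detected: pre-bleach mean equals value at t = 0")
    values = (post_i - f0) / denom
    values[0] = 0.0
    return NormalizedTrace(times=post_t, values=values, label=corrected.label)


def pool_traces(traces: list[NormalizedTrace]) -> tuple[NormalizedTrace, np.ndarray]:
    """Pointwise mean of normalized traces on a common grid, with SEM.

    Returns the mean trace and the per-timepoint standard error of the
    mean (zero when only one trace is supplied).
    """
    if not traces:
        raise ValueError("no traces to pool")
    grid = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            raise ValueError("traces must share a common time grid")
    stack = np.vstack([tr.values for tr in traces])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    mean[0] = 0.0  # each member is exactly 0 at the bleach instant
    return NormalizedTrace(times=grid, values=mean, label="pooled"), sem


# ---------------------------------------------------------------------------
# model evaluation


def model_recovery(t, params: RecoveryParams):
    """Evaluate the recovery model at times ``t >= 0`` (scalar or array)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("recovery model is defined for t >= 0 only")
    out = np.zeros_like(t_arr)
    if params.f > 0:
        out = out + params.f * (1.0 - np.exp2(-t_arr / params.tf_half))
    if params.s > 0:
        out = out + params.s * (1.0 - np.exp2(-t_arr / params.ts_half))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting


def _unpack_params(kind: str, x: np.ndarray, free_total: bool) -> RecoveryParams:
    if kind == "full_single":
        return RecoveryParams(kind, f=1.0, tf_half=10.0 ** x[0])
    if kind == "single_plus_immobile":
        return RecoveryParams(kind, f=min(float(x[0]), 1.0), tf_half=10.0 ** x[1])
    if free_total:
        m, phi = float(x[0]), float(x[1])
        tf, ts = 10.0 ** x[2], 10.0 ** x[3]
    else:
        m, phi = 1.0, float(x[0])
        tf, ts = 10.0 ** x[1], 10.0 ** x[2]
    f, s = m * phi, m * (1.0 - phi)
    if tf > ts:  # relabel so the fast population is first
        tf, ts = ts, tf
        f, s = s, f
    if ts <= tf:  # coincident rates: split is unidentifiable, merge labels
        ts = tf * (1.0 + 1e-12)
    return RecoveryParams(kind, f=f, s=s, tf_half=tf, ts_half=ts)


def _model_from_x(kind, x, t, free_total) -> np.ndarray:
    # evaluated in the raw parameterization (no relabelling) for speed
    if kind == "full_single":
        return 1.0 - np.exp2(-t / 10.0 ** x[0])
    if kind == "single_plus_immobile":
        return x[0] * (1.0 - np.exp2(-t / 10.0 ** x[1]))
    if free_total:
        m, phi, ltf, lts = x
    else:
        m, (phi, ltf, lts) = 1.0, x
    return m * (
        phi * (1.0 - np.exp2(-t / 10.0 ** ltf))
        + (1.0 - phi) * (1.0 - np.exp2(-t / 10.0 ** lts))
    )


def _start_points(
    kind: str, lo: float, hi: float, n_starts: int, free_total: bool
) -> list[np.ndarray]:
    """Multistart grid: log-spaced half-times crossed with fraction splits."""
    splits = (0.25, 0.5, 0.75)
    starts: list[np.ndarray] = []
    if kind == "full_single":
        for lt in np.linspace(lo, hi, n_starts):
            starts.append(np.array([lt]))
    elif kind == "single_plus_immobile":
        n_t = max(2, math.ceil(n_starts / len(splits)))
        for lt in np.linspace(lo, hi, n_t):
            for fr in splits:
                starts.append(np.array([fr, lt]))
    else:
        n_t = max(3, math.ceil(math.sqrt(2 * n_starts / len(splits))) + 1)
        grid = np.linspace(lo, hi, n_t)
        for i in range(n_t):
            for j in range(i + 1, n_t):
                for phi in splits:
                    head = [0.9, phi] if free_total else [phi]
                    starts.append(np.array(head + [grid[i], grid[j]]))
    if len(starts) > n_starts:  # deterministic even subsample of the grid
        idx = np.linspace(0, len(starts) - 1, n_starts).round().astype(int)
        starts = [starts[i] for i in idx]
    return starts


def _aicc(rss: float, n: int, p: int) -> float:
    k = p + 1  # +1 for the residual variance
    rss = max(rss, n * 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_recovery(
    trace: NormalizedTrace,
    model_kind: str = "two_population",
    n_starts: int = 16,
    seed: int = 0,
    n_boot: int = 0,
    free_total: bool = False,
) -> FitResult:
    """Fit a recovery model to a normalized trace by bounded least squares.

    Half-times are optimized in log10 space within ``[dt/10, 100 * t_end]``
    (``dt`` the median sampling interval) from a multistart grid of
    log-spaced half-times crossed with fraction splits {0.25, 0.5, 0.75};
    the lowest-RSS solution wins.  A two-population result is always
    reported with ``tf_half < ts_half``.

    By default the two-population model is *closed*: the fast and slow
    fractions sum to 1, as in reported complementary percentages (85%
    slow / 15% fast).  With ``free_total=True`` the total mobile fraction
    ``f + s`` is itself a free parameter in [0, 1], leaving an implicit
    immobile remainder; on short observation windows this variant is
    poorly identified because a large slow half-time trades off against
    the mobile total.  Set ``n_boot > 0`` for residual-bootstrap standard
    errors (seeded, hence reproducible).
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    t = trace.times
    y = trace.values
    if t.size < MIN_POST_BLEACH:
        raise ValueError(f"need at least {MIN_POST_BLEACH} post-bleach points")
    p = _n_free(model_kind, free_total)
    if t.size <= p:
        raise ValueError("more observations than free parameters required")

    dt = float(np.median(np.diff(t)))
    t_end = float(t[-1])
    lo, hi = math.log10(dt / 10.0), math.log10(100.0 * t_end)
    if model_kind == "full_single":
        lb, ub = np.array([lo]), np.array([hi])
    elif model_kind == "single_plus_immobile":
        lb, ub = np.array([0.0, lo]), np.array([1.0, hi])
    elif free_total:
        lb = np.array([0.0, 0.0, lo, lo])
        ub = np.array([1.0, 1.0, hi, hi])
    else:
        lb = np.array([0.0, lo, lo])
        ub = np.array([1.0, hi, hi])

    if np.allclose(y, 0.0):
        warnings.warn("flat zero trace: returning the degenerate plateau-0 fit")
        if model_kind == "full_single":
            params = RecoveryParams(model_kind, f=1.0, tf_half=100.0 * t_end)
            rss = float(np.sum((model_recovery(t, params) - y) ** 2))
        elif model_kind == "single_plus_immobile":
            params = RecoveryParams(model_kind, f=0.0, tf_half=t_end)
            rss = 0.0
        else:
            params = RecoveryParams(
                model_kind, f=0.0, s=0.0, tf_half=t_end, ts_half=2 * t_end
            )
            rss = 0.0
        return FitResult(params, rss, t.size, _aicc(rss, t.size, p), True, 0, p)

    def resid(x, target=y):
        return _model_from_x(model_kind, x, t, free_total) - target

    best_x, best_rss, converged = None, math.inf, False
    starts = _start_points(model_kind, lo, hi, n_starts, free_total)
    for x0 in starts:
        try:
            sol = least_squares(
                resid, x0, bounds=(lb, ub), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if sol.status > 0:
            converged = True
        if rss < best_rss:
            best_rss, best_x = rss, sol.x

    if best_x is None:
        # every start failed outright; report a non-converged placeholder
        x0 = _start_points(model_kind, lo, hi, 1, free_total)[0]
        params = _unpack_params(model_kind, x0, free_total)
        return FitResult(params, math.inf, t.size, math.inf, False, len(starts), p)

    params = _unpack_params(model_kind, best_x, free_total)
    aicc = _aicc(best_rss, t.size, p)

    se = None
    if n_boot > 0:
        se = _bootstrap_se(
            trace, model_kind, best_x, n_starts=max(4, n_starts // 4),
            n_boot=n_boot, seed=seed, free_total=free_total,
        )

    return FitResult(params, best_rss, t.size, aicc, converged, len(starts), p, se)


def _bootstrap_se(trace, model_kind, x_hat, n_starts, n_boot, seed, free_total):
    """Residual-bootstrap standard errors for the fitted parameters."""
    t, y = trace.times, trace.values
    fitted = _model_from_x(model_kind, x_hat, t, free_total)
    resids = y - fitted
    rng = np.random.default_rng(seed)
    draws = {"f": [], "s": [], "tf_half": [], "ts_half": []}
    for _ in range(n_boot):
        y_star = fitted + rng.choice(resids, size=resids.size, replace=True)
        y_star[0] = 0.0
        boot = NormalizedTrace(times=t, values=y_star)
        res = fit_recovery(
            boot, model_kind, n_starts=n_starts, seed=0, free_total=free_total
        )
        draws["f"].append(res.params.f)
        draws["s"].append(res.params.s)
        draws["tf_half"].append(res.params.tf_half)
        draws["ts_half"].append(res.params.ts_half)
    return {k: float(np.std(v, ddof=1)) for k, v in draws.items()}


def select_model(
    trace: NormalizedTrace,
    candidates: tuple[str, ...] = MODEL_KINDS,
    seed: int = 0,
    n_starts: int = 16,
) -> tuple[str, dict[str, FitResult], bool]:
    """Fit all candidate models and pick the lowest-AICc one.

    Returns ``(best_kind, table, indeterminate)`` where ``table`` maps each
    candidate to its :class:`FitResult` and ``indeterminate`` flags a best
    margin of less than 2 AICc units over the runner-up, in which case the
    data do not clearly discriminate the candidates.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    table = {
        kind: fit_recovery(trace, kind, n_starts=n_starts, seed=seed)
        for kind in candidates
    }
    ranked = sorted(table, key=lambda k: table[k].aicc)
    best = ranked[0]
    indeterminate = table[ranked[1]].aicc - table[best].aicc < 2.0
    return best, table, indeterminate
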