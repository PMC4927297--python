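"""Quantifying exocytotic capacitance jumps and fitting the endocytotic
recovery.

Membrane capacitance is an electrical proxy for plasma-membrane area: each
depolarizing pulse adds a step (exocytosis) and the subsequent decay reports
membrane retrieval.  The recovery limb is described by a plateau (membrane
never retrieved on the recording timescale) plus one or two exponentials:

    C_norm(t) = p + (1 - p) * sum_i a_i * exp(-t / tau_i),   sum_i a_i = 1

with amplitude fractions a_i expressed as fractions of the *recoverable*
decay (consistent with a plateau term and the normalized endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .scenarios import StimulusProtocol
from .traces import TimeSeries

__all__ = [
    "JumpSeries",
    "measure_jumps",
    "normalize_capacitance",
    "CapFitResult",
    "ExponentialRecovery",
    "fit_endocytosis",
    "endpoint_metric",
]


@dataclass
class JumpSeries:
    """Per-pulse capacitance increments for one train."""

    per_pulse_dCm_pF: np.ndarray
    total_dCm_pF: float
    normalized: np.ndarray  # first-normalized, normalized[0] = 1

    def __post_init__(self) -> None:
        self.per_pulse_dCm_pF = np.asarray(self.per_pulse_dCm_pF, float)
        self.normalized = np.asarray(self.normalized, float)


def _back_extrapolate(t: np.ndarray, v: np.ndarray, t0: float) -> float:
    """Linear back-extrapolation of a short window to ``t0``.

    Removes the bias that ongoing endocytotic decay inside the measurement
    window would otherwise introduce; degrades to the window mean when the
    window holds fewer than 3 samples.
    """
    if t.size < 3:
        return float(v.mean())
    slope, intercept = np.polyfit(t - t0, v, 1)
    return float(intercept)


def measure_jumps(cm: TimeSeries, protocol: StimulusProtocol,
                  pre_window_s: float = 0.05,
                  post_window_s: tuple[float, float] = (0.05, 0.15),
                  back_extrapolate: bool = True) -> JumpSeries:
    """Per-pulse capacitance jumps: post-pulse window estimate minus
    pre-pulse window mean.

    Windows default to 50 ms before pulse onset and 50-150 ms after pulse
    offset (the gap after the offset skips stimulation transients).  By
    default the post-window samples are back-extrapolated linearly to the
    pulse offset, so decay already under way inside the window does not bias
    the jump; ``back_extrapolate=False`` reverts to the window mean.  Raises
    if a post window would collide with the next pulse, naming the pulses.
    """
    shift = protocol.last_offset
    onsets = protocol.onsets - shift
    offsets = protocol.offsets - shift
    lo, hi = post_window_s
    if not 0 <= lo < hi:
        raise ValueError("post window must satisfy 0 <= lo < hi")
    eps = 1e-9
    jumps = []
    for i, (t_on, t_off) in enumerate(zip(onsets, offsets)):
        if i + 1 < len(onsets) and t_off + hi > onsets[i + 1] + eps:
            raise ValueError(
                f"post window of pulse {i} ([{t_off + lo:.3f}, {t_off + hi:.3f}] s) "
                f"collides with onset of pulse {i + 1} at {onsets[i + 1]:.3f} s"
            )
        pre = (cm.t >= t_on - pre_window_s - eps) & (cm.t < t_on - eps)
        post = (cm.t >= t_off + lo - eps) & (cm.t <= t_off + hi + eps)
        if not pre.any() or not post.any():
            raise ValueError(f"no samples in measurement window of pulse {i}")
        if back_extrapolate:
            level = _back_extrapolate(cm.t[post], cm.v[post], t_off)
        else:
            level = float(cm.v[post].mean())
        jumps.append(level - cm.v[pre].mean())
    jumps = np.asarray(jumps)
    if jumps[0] != 0:
        norm = jumps / jumps[0]
    else:  # flat trace: define the first-normalized series as the raw zeros, anchor 1
        norm = jumps.copy()
        norm[0] = 1.0
    return JumpSeries(jumps, float(jumps.sum()), norm)


def normalize_capacitance(cm: TimeSeries, baseline_window_s: float = 5.0,
                          jump_window_s: float = 0.5) -> TimeSeries:
    """Normalize a capacitance trace to its stimulus-evoked jump.

    Baseline is the mean over ``baseline_window_s`` before the first pulse
    onset (falling back to the trace start); the jump amplitude is the
    post-stimulus level over ``jump_window_s`` from t = 0, back-extrapolated
    linearly to t = 0 so early decay does not shrink it.  Returns
    (C - baseline)/jump so the recovery limb starts at ~1.
    """
    onsets = cm.meta.get("pulse_onsets")
    t_first = float(np.min(onsets)) if onsets is not None else 0.0
    base_mask = (cm.t >= t_first - baseline_window_s) & (cm.t < t_first)
    if not base_mask.any():
        base_mask = cm.t < t_first
    if not base_mask.any():
        raise ValueError("no pre-stimulus samples to estimate the baseline")
    baseline = float(cm.v[base_mask].mean())
    jump_mask = (cm.t >= 0) & (cm.t <= jump_window_s)
    if not jump_mask.any():
        raise ValueError("no samples in the jump window at stimulus end")
    jump = _back_extrapolate(cm.t[jump_mask], cm.v[jump_mask], 0.0) - baseline
    if jump <= 0:
        raise ValueError(f"non-positive stimulus-evoked jump ({jump:.4g})")
    out = cm.copy_with(v=(cm.v - baseline) / jump)
    out.units = "norm"
    out.meta.update(norm_baseline=baseline, norm_jump=jump)
    return out


@dataclass
class CapFitResult:
    """Plateau + exponential-mixture decomposition of a recovery limb."""

    plateau: float
    components: list[tuple[float, float]]  # (amplitude_frac, tau_s), fast first
    sse: float
    n_points: int
    model: str  # "mono" | "bi"
    flags: dict[str, Any] = field(default_factory=dict)


class ExponentialRecovery(BaseEstimator):
    """Least-squares fit of ``p + (1-p) * sum a_i exp(-t/tau_i)``.

    Multistart initialization over a logarithmic tau grid guards against
    local minima; for the bi-exponential model fast/slow ordering is
    enforced by sorting after the fit, a time constant pinned at its bound
    is flagged, and near-equal time constants are flagged as a degenerate
    (effectively mono-exponential) solution rather than an error.

    Parameters
    ----------
    model : {"bi", "mono"}
    fit_plateau : bool
        If False the plateau is fixed at ``fixed_plateau``.
    tau_bounds : (float, float), seconds
        Search bounds; the multistart grid is log-spaced inside them.
    n_starts : int
        Starts per tau axis (``n_starts**2`` for the bi model).
    """

    def __init__(self, model: str = "bi", fit_plateau: bool = True,
                 fixed_plateau: float = 0.0, tau_bounds: tuple[float, float] = (0.5, 500.0),
                 n_starts: int = 5, normalize: bool = True):
        self.model = model
        self.fit_plateau = fit_plateau
        self.fixed_plateau = fixed_plateau
        self.tau_bounds = tau_bounds
        self.n_starts = n_starts
        self.normalize = normalize

    def _predict_theta(self, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
        if self.model == "bi":
            p, a, tau_f, tau_s = (theta if self.fit_plateau
                                  else (self.fixed_plateau, *theta))
            return p + (1 - p) * (a * np.exp(-t / tau_f) + (1 - a) * np.exp(-t / tau_s))
        p, tau = theta if self.fit_plateau else (self.fixed_plateau, theta[0])
        return p + (1 - p) * np.exp(-t / tau)

    def fit(self, t: np.ndarray, y: np.ndarray) -> "ExponentialRecovery":
        if self.model not in ("bi", "mono"):
            raise ValueError("model must be 'bi' or 'mono'")
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        if t.size < 10:
            raise ValueError("recovery limb must contain at least 10 samples")
        scale = 1.0
        if self.normalize:
            scale = float(np.interp(t[0], t, y))
            if scale <= 0:
                raise ValueError("cannot normalize: value at fit start <= 0")
            y = y / scale
        t = t - t[0]
        lo, hi = self.tau_bounds
        taus0 = np.geomspace(lo * 2, hi / 2, self.n_starts)
        starts = ([(tf, ts) for tf in taus0 for ts in taus0 if tf <= ts]
                  if self.model == "bi" else [(tau,) for tau in taus0])
        best = None
        for start in starts:
            if self.model == "bi":
                x0 = [0.1, 0.5, *start] if self.fit_plateau else [0.5, *start]
                lb = ([0.0, 0.0, lo, lo] if self.fit_plateau else [0.0, lo, lo])
                ub = ([1.0, 1.0, hi, hi] if self.fit_plateau else [1.0, hi, hi])
            else:
                x0 = [0.1, *start] if self.fit_plateau else [*start]
                lb = [0.0, lo] if self.fit_plateau else [lo]
                ub = [1.0, hi] if self.fit_plateau else [hi]
            try:
                res = least_squares(lambda th: self._predict_theta(th, t) - y, x0,
                                    bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            sse = float((res.fun ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, res.x)
        if best is None:
            raise RuntimeError(
                f"recovery fit failed to converge from any of {len(starts)} starts "
                f"(model={self.model}, n={t.size})"
            )
        sse, x = best
        flags: dict[str, Any] = {}
        if self.model == "bi":
            p = float(x[0]) if self.fit_plateau else self.fixed_plateau
            a, tau_f, tau_s = ((float(x[1]), float(x[2]), float(x[3])) if self.fit_plateau
                               else (float(x[0]), float(x[1]), float(x[2])))
            comps = sorted([(a, tau_f), (1 - a, tau_s)], key=lambda c: c[1])
            if comps[1][1] > 0 and comps[0][1] / comps[1][1] > 0.95:
                flags["degenerate_mono"] = True
            taus = [tau for _, tau in comps]
        else:
            p = float(x[0]) if self.fit_plateau else self.fixed_plateau
            tau = float(x[1]) if self.fit_plateau else float(x[0])
            comps = [(1.0, tau)]
            taus = [tau]
        if any(tau < lo * 1.001 or tau > hi * 0.999 for tau in taus):
            flags["tau_at_bound"] = True
        self.plateau_ = p
        self.components_ = comps
        self.sse_ = sse
        self.n_points_ = int(t.size)
        self.scale_ = scale
        self.flags_ = flags
        self._t0_ = 0.0
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.full_like(t, self.plateau_, dtype=float)
        for a, tau in self.components_:
            out += (1 - self.plateau_) * a * np.exp(-t / tau)
        return out * self.scale_

    def result(self) -> CapFitResult:
        return CapFitResult(self.plateau_, list(self.components_), self.sse_,
                            self.n_points_, self.model, dict(self.flags_))


def fit_endocytosis(cm: TimeSeries, model: str = "bi", fit_plateau: bool = True,
                    t_start: float = 0.0, t_end: float | None = None,
                    **kw: Any) -> CapFitResult:
    """Fit the endocytotic recovery of a jump-normalized capacitance trace.

    The fit window runs from ``t_start`` (default: stimulus end) to
    ``t_end`` (default: end of trace); the trace is renormalized internally
    to its value at ``t_start`` so the fit is scale-equivariant.
    """
    t_end = cm.t[-1] if t_end is None else t_end
    mask = (cm.t >= t_start) & (cm.t <= t_end)
    est = ExponentialRecovery(model=model, fit_plateau=fit_plateau, **kw)
    est.fit(cm.t[mask], cm.v[mask])
    return est.result()


def endpoint_metric(trace: TimeSeries, t_s: float) -> float:
    """Normalized trace value at ``t_s`` by nearest-two linear interpolation."""
    return float(trace.interp(t_s))
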