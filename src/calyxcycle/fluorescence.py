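"""Raw ROI fluorescence to normalized quench traces, puff metrics, and
surface-density arithmetic.

The pH reporter is fluorescent in the acidic vesicle lumen and quenched at
the neutral extracellular pH, so stimulation produces a downward deflection
that recovers as retrieved organelles re-acidify.  Analysis proceeds by
(optional) photobleaching correction against an unstimulated neighbor ROI,
background subtraction, normalization, and inversion into a quench trace
Q(t) with Q = 1 at stimulus end and Q = 0 at full recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .scenarios import PuffEvent
from .traces import TimeSeries

__all__ = [
    "BleachCorrector",
    "bleach_correct",
    "QuenchTrace",
    "normalize_invert",
    "endpoint_metric",
    "PuffMetrics",
    "puff_dequench",
    "surface_density",
]


class BleachCorrector(BaseEstimator):
    """Photobleaching correction referenced to an unstimulated neighbor ROI.

    A line or a single exponential is fitted to the normalized neighbor
    trace (``auto`` picks whichever has the lower sse); the fitted time
    course, minus its value at the trace start, is subtracted from the
    normalized target.  An already flat reference therefore leaves the
    target unchanged.
    """

    def __init__(self, model: str = "auto"):
        self.model = model

    def fit(self, neighbor: TimeSeries) -> "BleachCorrector":
        if self.model not in ("linear", "exponential", "auto"):
            raise ValueError("model must be linear|exponential|auto")
        t = neighbor.t - neighbor.t[0]
        y = neighbor.v / np.mean(neighbor.v[: max(3, len(neighbor) // 20)])

        lin = np.polyfit(t, y, 1)
        sse_lin = float(((np.polyval(lin, t) - y) ** 2).sum())

        def expo(tt: np.ndarray, a: float, r: float) -> np.ndarray:
            return a * np.exp(-r * tt)

        try:
            r0 = max(-lin[0] / max(lin[1], 1e-9), 1e-6)
            popt, _ = curve_fit(expo, t, y, p0=[y[0], r0], maxfev=10000)
            sse_exp = float(((expo(t, *popt) - y) ** 2).sum())
        except RuntimeError:
            popt, sse_exp = None, np.inf

        if self.model == "linear" or (self.model == "auto" and sse_lin <= sse_exp):
            self.model_ = "linear"
            self.params_ = tuple(float(c) for c in lin)
            self.sse_ = sse_lin
        else:
            if popt is None:
                raise RuntimeError("exponential bleach fit did not converge")
            self.model_ = "exponential"
            self.params_ = tuple(float(c) for c in popt)
            self.sse_ = sse_exp
        self.sse_by_model_ = {"linear": sse_lin, "exponential": sse_exp}
        self._t0_ = float(neighbor.t[0])
        return self

    def bleach_curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float) - self._t0_
        if self.model_ == "linear":
            return np.polyval(self.params_, t)
        a, r = self.params_
        return a * np.exp(-r * t)

    def transform(self, target: TimeSeries) -> TimeSeries:
        """Subtract the fitted bleach course (re-anchored to the target's
        own start time and scaled to its initial level) from the target."""
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the corrector before transforming")
        b = self.bleach_curve(target.t)
        b0 = self.bleach_curve(np.array([target.t[0]]))[0]
        level = float(np.mean(target.v[: max(3, len(target) // 20)]))
        corrected = target.v - level * (b - b0)
        out = target.copy_with(v=corrected)
        out.meta["bleach_correction"] = {"model": self.model_, "params": list(self.params_)}
        return out


def bleach_correct(target: TimeSeries, neighbor: TimeSeries,
                   model: str = "auto") -> TimeSeries:
    """Fit-and-subtract photobleaching using a neighbor ROI reference."""
    if neighbor.t[-1] < target.t[-1] - 1e-9 or neighbor.t[0] > target.t[0] + 1e-9:
        raise ValueError("neighbor trace does not cover the target's span")
    return BleachCorrector(model=model).fit(neighbor).transform(target)


@dataclass
class QuenchTrace:
    """Normalized, inverted fluorescence: 1 = fully quenched at stimulus
    end, 0 = full recovery."""

    trace: TimeSeries
    normalization_mode: str
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.trace.t

    @property
    def v(self) -> np.ndarray:
        return self.trace.v


def normalize_invert(f: TimeSeries, mode: str = "delta_f",
                     stim_end_s: float = 0.0, background: float = 0.0,
                     baseline_window_s: float | None = None) -> QuenchTrace:
    """Background-subtract, normalize, and invert a fluorescence trace.

    The resting level is the pre-stimulus mean (over ``baseline_window_s``
    before the first pulse onset, or all pre-stimulus samples); the
    stimulus-end sample is the first sample at/after ``stim_end_s``.  The
    quench value is (rest - F)/(rest - F_end): 1 at stimulus end, 0 at full
    recovery.  ``mode`` records whether intensities were first normalized to
    the initial intensity or to the stimulus-evoked deltaF — the two differ
    by an overall affine rescaling that the inversion removes, so the quench
    values are identical; the mode is kept as provenance.
    """
    if mode not in ("initial", "delta_f"):
        raise ValueError("mode must be initial|delta_f")
    onsets = f.meta.get("pulse_onsets")
    t_first = float(np.min(onsets)) if onsets is not None else stim_end_s
    base_mask = f.t < t_first
    if baseline_window_s is not None:
        base_mask &= f.t >= t_first - baseline_window_s
    if not base_mask.any():
        raise ValueError("no pre-stimulus samples for the resting level")
    v = f.v - background
    rest = float(v[base_mask].mean())
    end_idx = int(np.searchsorted(f.t, stim_end_s - 1e-9))
    if end_idx >= len(f):
        raise ValueError("stimulus end beyond trace span")
    d_f = rest - float(v[end_idx])
    if d_f <= 0:
        raise ValueError(f"non-positive stimulus-evoked deltaF ({d_f:.4g})")
    q = (rest - v) / d_f
    ts = TimeSeries(f.t.copy(), q, "norm", dict(f.meta))
    ts.meta.update(rest_f=rest, delta_f=d_f, stim_end_sample_s=float(f.t[end_idx]))
    return QuenchTrace(ts, mode, {"background": background})


def endpoint_metric(q: QuenchTrace | TimeSeries, t_s: float) -> float:
    """Quench value at ``t_s`` by nearest-two linear interpolation."""
    trace = q.trace if isinstance(q, QuenchTrace) else q
    return float(trace.interp(t_s))


@dataclass
class PuffMetrics:
    """Surface-pool readout from paired pre/post acid puffs."""

    pre_dF: float
    post_dF: float
    ratio: float
    all_dF: list[float] = field(default_factory=list)


def puff_dequench(f: TimeSeries, puffs: list[PuffEvent],
                  n_baseline: int = 3) -> PuffMetrics:
    """De-quench amplitude of each acid puff: peak during the puff minus the
    mean of ``n_baseline`` samples before onset.

    Peak (rather than plateau) amplitude is used because a 5-s puff sampled
    at 0.5 Hz yields only 2-3 samples.  Needs at least a pre- and a
    post-stimulus puff; raises if a puff spans no samples.
    """
    if len(puffs) < 2:
        raise ValueError("need at least two puffs (pre- and post-stimulus)")
    events = sorted(puffs, key=lambda p: p.onset_s)
    dfs = []
    for ev in events:
        before = np.nonzero(f.t < ev.onset_s)[0]
        if before.size < n_baseline:
            raise ValueError(f"fewer than {n_baseline} baseline samples before puff at {ev.onset_s} s")
        base = float(f.v[before[-n_baseline:]].mean())
        during = (f.t >= ev.onset_s) & (f.t < ev.onset_s + ev.duration_s)
        if not during.any():
            raise ValueError(
                f"puff at {ev.onset_s} s spans no samples at this sampling rate"
            )
        dfs.append(float(f.v[during].max() - base))
    pre, post = dfs[0], dfs[-1]
    if pre == 0:
        raise ValueError("pre-stimulus puff deltaF is zero; ratio undefined")
    return PuffMetrics(pre, post, post / pre, dfs)


def surface_density(pre_dF: float | np.ndarray, basal_cm_pF: float | np.ndarray,
                    jump_dF: float | np.ndarray, jump_cm_pF: float | np.ndarray
                    ) -> tuple[Any, Any, Any]:
    """Reporter density per membrane area for the surface-stranded and the
    vesicular pool.

    surface = pre_dF / basal_cm_pF, vesicular = jump_dF / jump_cm_pF,
    ratio = vesicular / surface.  Accepts arrays for per-cell computation
    (aggregate with mean/SEM afterwards).
    """
    pre_dF = np.asarray(pre_dF, float)
    basal = np.asarray(basal_cm_pF, float)
    jump_dF = np.asarray(jump_dF, float)
    jump_cm = np.asarray(jump_cm_pF, float)
    if np.any(basal <= 0) or np.any(jump_cm <= 0) or np.any(pre_dF <= 0) or np.any(jump_dF <= 0):
        raise ValueError("all inputs must be > 0")
    surf = pre_dF / basal
    ves = jump_dF / jump_cm
    ratio = ves / surf
    if surf.ndim == 0:
        return float(surf), float(ves), float(ratio)
    return surf, ves, ratio
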