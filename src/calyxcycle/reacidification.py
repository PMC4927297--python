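"""Henderson–Hasselbalch mapping, organelle recovery kernel, convolution
forward model, and least-squares recovery of the re-acidification kinetics.

The central quantity is the quench trace Q(t): the normalized, inverted
reporter fluorescence, 1 when all stimulus-exposed reporter sits at the
neutral surface pH and 0 at full re-acidification.  Retrieval of membrane is
read from the capacitance recovery; each retrieved organelle then re-acidifies
after an onset delay, following an exponential pH relaxation mapped through
the reporter's titration curve.  Summed over the endocytic flux this is a
convolution:

    Q(t) = 1 - integral_0^t e(t') g(t - t') dt'

with e(t) = -dC_norm/dt the normalized endocytic flux and g the per-organelle
de-quench kernel.  Fitting Q against a measured quench trace by exhaustive
grid search plus local simplex refinement recovers the onset delay and the
re-acidification time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import least_squares, minimize, minimize_scalar
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .scenarios import ReacidificationParams
from .traces import TimeSeries

__all__ = [
    "hh_fluorescence",
    "recovery_kernel",
    "estimate_flux",
    "predict_quench",
    "ReacidFitResult",
    "ConvolutionReacidification",
    "fit_reacidification",
    "DelayedExponential",
    "fit_delayed_exponential",
]


def hh_fluorescence(pH: float | np.ndarray, params: ReacidificationParams | None = None,
                    *, pKa: float | None = None, hill: float | None = None) -> float | np.ndarray:
    """Relative fluorescence of the reporter at a given pH.

    Henderson–Hasselbalch titration with the protonated (acidic) form
    fluorescent: ``phi(pH) = 1 / (1 + 10**(hill * (pH - pKa)))``.
    With the defaults (pKa 7.05, Hill 1): phi(5.5) = 0.9726, phi(7.4) = 0.3088.
    """
    if params is None:
        params = ReacidificationParams()
    pKa = params.pKa if pKa is None else pKa
    hill = params.hill if hill is None else hill
    pH = np.asarray(pH, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (hill * (pH - pKa)))
    return float(out) if out.ndim == 0 else out


def recovery_kernel(s: float | np.ndarray, params: ReacidificationParams) -> float | np.ndarray:
    """Fractional de-quench of one organelle, ``s`` seconds after retrieval.

    Zero during the onset delay; afterwards the lumen pH relaxes
    exponentially from ``pH_surface`` to ``pH_lumen`` and the kernel is the
    titration-mapped pH, normalized so its endpoints are exactly 0 and 1.
    """
    s = np.asarray(s, dtype=float)
    run = np.clip(s - params.delay_s, 0.0, None)
    pH = params.pH_lumen + (params.pH_surface - params.pH_lumen) * np.exp(-run / params.tau_acid_s)
    phi_s = hh_fluorescence(params.pH_surface, params)
    phi_l = hh_fluorescence(params.pH_lumen, params)
    g = (hh_fluorescence(pH, params) - phi_s) / (phi_l - phi_s)
    g = np.where(s < params.delay_s, 0.0, g)
    out = np.clip(g, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def estimate_flux(cm_norm: TimeSeries, bin_s: float = 2.0, smooth: bool = True,
                  t_start: float = 0.0) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Endocytic flux e(t) = -dC_norm/dt from a normalized capacitance trace.

    The recovery limb (t >= t_start) is averaged into ``bin_s`` bins, made
    monotone non-increasing by isotonic regression (raw imaging-rate noise
    would otherwise dominate the derivative), differentiated by central
    differences, and clipped at zero.  Returns bin centers, flux values, and
    a diagnostics dict (records a warning if the raw limb was non-monotone
    beyond tolerance).
    """
    mask = cm_norm.t >= t_start
    t = cm_norm.t[mask]
    v = cm_norm.v[mask]
    if t.size < 3:
        raise ValueError("recovery limb has fewer than 3 samples")
    dt_native = float(np.median(np.diff(t)))
    if bin_s > dt_native * 1.5:
        edges = np.arange(t[0], t[-1] + bin_s, bin_s)
        idx = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
        centers = np.array([t[idx == i].mean() for i in range(len(edges) - 1) if np.any(idx == i)])
        binned = np.array([v[idx == i].mean() for i in range(len(edges) - 1) if np.any(idx == i)])
    else:
        centers, binned = t, v
    diag: dict[str, Any] = {}
    rises = np.diff(binned)
    if rises.size and rises.max() > 0.02:
        diag["warning"] = f"non-monotone recovery limb (max rise {rises.max():.3g})"
    if centers[0] > t_start:
        # the trace is jump-normalized: anchor the limb at (t_start, 1)
        centers = np.concatenate([[t_start], centers])
        binned = np.concatenate([[1.0], binned])
    if smooth:
        iso = IsotonicRegression(increasing=False)
        binned = iso.fit_transform(centers, binned)
    flux = np.clip(-np.gradient(binned, centers), 0.0, None)
    return centers, flux, diag


def _smooth_cm(cm_norm: TimeSeries, bin_s: float = 2.0, smooth: bool = True,
               t_start: float = 0.0) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Monotone piecewise-linear representation of the recovery limb.

    Bin-averaged (against imaging-rate noise), isotonic-decreasing, and
    anchored at (t_start, 1): the trace is jump-normalized so the recovery
    limb starts at 1 by construction.
    """
    mask = cm_norm.t >= t_start
    t = cm_norm.t[mask]
    v = cm_norm.v[mask]
    if t.size < 3:
        raise ValueError("recovery limb has fewer than 3 samples")
    dt_native = float(np.median(np.diff(t)))
    if bin_s > dt_native * 1.5:
        edges = np.arange(t[0], t[-1] + bin_s, bin_s)
        idx = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
        keep = [i for i in range(len(edges) - 1) if np.any(idx == i)]
        centers = np.array([t[idx == i].mean() for i in keep])
        binned = np.array([v[idx == i].mean() for i in keep])
    else:
        centers, binned = t, v
    diag: dict[str, Any] = {}
    rises = np.diff(binned)
    if rises.size and rises.max() > 0.02:
        diag["warning"] = f"non-monotone recovery limb (max rise {rises.max():.3g})"
    if centers[0] > t_start:
        centers = np.concatenate([[t_start], centers])
        binned = np.concatenate([[1.0], binned])
    if smooth:
        iso = IsotonicRegression(increasing=False)
        binned = iso.fit_transform(centers, binned)
    return centers, binned, diag


def _absorbed(q_t: np.ndarray, knots_t: np.ndarray, knots_v: np.ndarray,
              params: ReacidificationParams, du: float = 0.05) -> np.ndarray:
    """Re-acidified fraction by Stieltjes quadrature against the kernel.

    Integration by parts of the flux convolution gives
    ``absorbed(t) = integral_0^t (1 - C(t - u)) dg(u)`` (the kernel is 0 at
    lag 0), which needs no numerical differentiation of the capacitance.
    """
    t_max = float(q_t.max()) if q_t.size else 0.0
    if t_max <= knots_t[0]:
        return np.zeros_like(q_t)
    u_edges = np.arange(knots_t[0], t_max + du, du)
    dg = np.diff(recovery_kernel(u_edges - knots_t[0], params))
    u_mid = 0.5 * (u_edges[1:] + u_edges[:-1])
    lag = q_t[:, None] - u_mid[None, :]
    c = np.interp(lag, knots_t, knots_v, left=1.0)
    retrieved = np.where(lag >= knots_t[0], 1.0 - c, 0.0)
    return retrieved @ dg


def _convolve_quench(q_t: np.ndarray, knots_t: np.ndarray, knots_v: np.ndarray,
                     params: ReacidificationParams, mode: str) -> np.ndarray:
    """Q at times ``q_t`` for a smoothed normalized capacitance limb."""
    if mode == "global_delay":
        p0 = ReacidificationParams(0.0, params.tau_acid_s, params.pH_surface,
                                   params.pH_lumen, params.pKa, params.hill)
        shifted = 1.0 - _absorbed(np.clip(q_t - params.delay_s, knots_t[0], None),
                                  knots_t, knots_v, p0)
        return np.where(q_t < params.delay_s + knots_t[0], 1.0, shifted)
    if mode != "per_organelle":
        raise ValueError("mode must be per_organelle|global_delay")
    return 1.0 - _absorbed(q_t, knots_t, knots_v, params)


def predict_quench(cm_norm: TimeSeries, params: ReacidificationParams,
                   mode: str = "per_organelle", out_t: np.ndarray | None = None,
                   bin_s: float = 2.0) -> TimeSeries:
    """Forward-model the quench trace from a normalized capacitance trace.

    ``per_organelle`` applies the onset delay inside the kernel (each
    organelle is held at surface pH for ``delay_s`` after its own
    retrieval); ``global_delay`` instead holds the whole curve at 1 until
    ``delay_s`` after stimulus end and then convolves with the delay-free
    kernel.  The two agree exactly when all endocytosis occurs at a single
    instant.
    """
    knots_t, knots_v, diag = _smooth_cm(cm_norm, bin_s=bin_s)
    t_out = np.asarray(out_t, float) if out_t is not None else cm_norm.t[cm_norm.t >= 0]
    q = _convolve_quench(t_out, knots_t, knots_v, params, mode)
    meta = {"mode": mode, **diag}
    return TimeSeries(t_out, np.clip(q, 0.0, 1.0), "norm", meta)


@dataclass
class ReacidFitResult:
    """Best-fit onset delay and re-acidification time constant."""

    delay_s: float
    tau_acid_s: float
    sse: float
    mode: str
    grid_surface: dict[tuple[float, float], float] = field(repr=False, default_factory=dict)
    boundary_flag: bool = False
    meta: dict[str, Any] = field(default_factory=dict)


class ConvolutionReacidification(BaseEstimator):
    """Recover (delay, tau_acid) by least squares against a quench trace.

    Exhaustive grid search over onset delay and re-acidification time
    constant, followed by coordinate-wise golden-section refinement around
    the grid minimum; the full sse surface is retained for diagnostics and a
    minimum on the grid boundary is flagged rather than silently returned.

    Parameters
    ----------
    mode : {"per_organelle", "global_delay"}
        Delay semantics of the forward model.
    delay_grid : array-like of float, seconds
        Delays searched exhaustively (default 0..40 s step 1 s).
    tau_grid : array-like of float, seconds
        Time constants searched (default 40 log-spaced in [5, 200] s).
    refine : bool
        Golden-section refinement to ~0.1 s in delay and ~0.5 % in tau.
    bin_s : float
        Bin width for the endocytic-flux estimate.
    """

    def __init__(self, mode: str = "per_organelle", delay_grid=None, tau_grid=None,
                 refine: bool = True, bin_s: float = 2.0,
                 reacid_template: ReacidificationParams | None = None):
        self.mode = mode
        self.delay_grid = delay_grid
        self.tau_grid = tau_grid
        self.refine = refine
        self.bin_s = bin_s
        self.reacid_template = reacid_template

    def _params(self, delay: float, tau: float) -> ReacidificationParams:
        tpl = self.reacid_template or ReacidificationParams()
        return ReacidificationParams(delay, tau, tpl.pH_surface, tpl.pH_lumen, tpl.pKa, tpl.hill)

    def fit(self, cm_norm: TimeSeries, q: TimeSeries) -> "ConvolutionReacidification":
        """Fit against a measured quench trace.

        ``cm_norm`` is the jump-normalized capacitance trace, ``q`` the
        quench trace; both must overlap on the recovery limb.
        """
        delays = np.asarray(self.delay_grid if self.delay_grid is not None
                            else np.arange(0.0, 40.0 + 1e-9, 1.0), float)
        taus = np.asarray(self.tau_grid if self.tau_grid is not None
                          else np.geomspace(5.0, 200.0, 40), float)
        t_lo = max(0.0, cm_norm.t[cm_norm.t >= 0][0])
        mask = (q.t >= t_lo) & (q.t <= cm_norm.t[-1])
        if mask.sum() < 4:
            raise ValueError("quench and capacitance traces do not overlap enough")
        qt, qv = q.t[mask], q.v[mask]
        knots_t, knots_v, diag = _smooth_cm(cm_norm, bin_s=self.bin_s)

        if self.mode == "per_organelle":
            # the retrieved-fraction matrix does not depend on (delay, tau):
            # precompute it so each grid evaluation is one kernel pass + matvec
            du = 0.05
            u_edges = np.arange(knots_t[0], float(qt.max()) + du, du)
            u_mid = 0.5 * (u_edges[1:] + u_edges[:-1])
            lag = qt[:, None] - u_mid[None, :]
            c = np.interp(lag, knots_t, knots_v, left=1.0)
            retrieved = np.where(lag >= knots_t[0], 1.0 - c, 0.0)
            t0 = knots_t[0]

            def sse(delay: float, tau: float) -> float:
                dg = np.diff(recovery_kernel(u_edges - t0, self._params(delay, tau)))
                pred = 1.0 - retrieved @ dg
                return float(((pred - qv) ** 2).sum())
        else:
            def sse(delay: float, tau: float) -> float:
                pred = _convolve_quench(qt, knots_t, knots_v,
                                        self._params(delay, tau), self.mode)
                return float(((pred - qv) ** 2).sum())

        surface = {(float(d), float(tau)): sse(d, tau) for d in delays for tau in taus}
        (d0, tau0) = min(surface, key=surface.get)
        best = surface[(d0, tau0)]
        i_d = int(np.searchsorted(delays, d0))
        i_t = int(np.searchsorted(taus, tau0))
        on_edge = i_d in (0, len(delays) - 1) or i_t in (0, len(taus) - 1)

        d_best, tau_best = d0, tau0
        if self.refine:
            # delay and tau trade off along a diagonal sse valley, so refine
            # both jointly (Nelder-Mead in (delay, log tau)) from the grid min
            d_step = float(np.median(np.diff(delays))) if len(delays) > 1 else 0.5
            ltau_step = (float(np.median(np.diff(np.log(taus))))
                         if len(taus) > 1 else 0.05)
            x0 = np.array([d0, np.log(tau0)])
            simplex = np.array([x0, x0 + [d_step, 0.0], x0 + [0.0, ltau_step]])
            res = minimize(
                lambda x: sse(max(x[0], 0.0), float(np.exp(x[1]))), x0,
                method="Nelder-Mead",
                options={"initial_simplex": simplex, "xatol": 0.02,
                         "fatol": 0.0, "maxiter": 400},
            )
            d_best = max(float(res.x[0]), 0.0)
            tau_best = float(np.exp(res.x[1]))
            best = sse(d_best, tau_best)

        # flat surfaces (e.g. re-acidification block) are unidentifiable
        spread = max(surface.values()) - min(surface.values())
        unidentifiable = spread < 1e-6 * max(1.0, max(surface.values()))

        self.delay_ = d_best
        self.tau_acid_ = tau_best
        self.sse_ = best
        self.grid_surface_ = surface
        self.boundary_flag_ = bool(on_edge or unidentifiable)
        self.meta_ = {**diag, "unidentifiable": unidentifiable, "n_points": int(mask.sum())}
        self._knots_ = (knots_t, knots_v)
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Predicted quench values at times ``t`` for the fitted parameters."""
        knots_t, knots_v = self._knots_
        return _convolve_quench(np.asarray(t, float), knots_t, knots_v,
                                self._params(self.delay_, self.tau_acid_), self.mode)

    def result(self) -> ReacidFitResult:
        return ReacidFitResult(self.delay_, self.tau_acid_, self.sse_, self.mode,
                               self.grid_surface_, self.boundary_flag_, dict(self.meta_))


def fit_reacidification(cm_norm: TimeSeries, q: TimeSeries,
                        grid: tuple | None = None,
                        mode: str = "per_organelle", **kw: Any) -> ReacidFitResult:
    """Functional wrapper over :class:`ConvolutionReacidification`.

    ``grid`` may be ``(delay_array, tau_array)`` to override the defaults.
    """
    delay_grid, tau_grid = (None, None) if grid is None else grid
    est = ConvolutionReacidification(mode=mode, delay_grid=delay_grid, tau_grid=tau_grid, **kw)
    return est.fit(cm_norm, q).result()


class DelayedExponential(BaseEstimator):
    """Delayed single-exponential description of a quench trace.

    Model: Q(t) = A + (1 - A) * min(1, exp(-(t - d)/tau)) — held at 1 during
    the onset delay d, then a mono-exponential decay to the asymptote A.
    The delay is scanned on the sample grid (with a continuous refinement);
    (A, tau) are fitted by least squares for each candidate delay.
    """

    def __init__(self, asymptote: str = "free", fixed_asymptote: float = 0.0,
                 tau_bounds: tuple[float, float] = (0.5, 2000.0)):
        self.asymptote = asymptote
        self.fixed_asymptote = fixed_asymptote
        self.tau_bounds = tau_bounds

    def _sub_fit(self, t: np.ndarray, y: np.ndarray, d: float) -> tuple[float, float, float]:
        lo, hi = self.tau_bounds

        def model(theta: np.ndarray) -> np.ndarray:
            a, tau = (self.fixed_asymptote, theta[0]) if self.asymptote == "fixed" else theta
            return a + (1 - a) * np.minimum(1.0, np.exp(-(t - d) / tau))

        tau_init = np.clip((t[-1] - d) / 3 if t[-1] > d else 10.0, lo, hi)
        if self.asymptote == "fixed":
            x0, bounds = [tau_init], ([lo], [hi])
        else:
            x0, bounds = [0.1, tau_init], ([0.0, lo], [0.999, hi])
        res = least_squares(lambda th: model(th) - y, x0, bounds=bounds)
        if self.asymptote == "fixed":
            a, tau = self.fixed_asymptote, float(res.x[0])
        else:
            a, tau = float(res.x[0]), float(res.x[1])
        return a, tau, float((res.fun ** 2).sum())

    def fit(self, t: np.ndarray, y: np.ndarray) -> "DelayedExponential":
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        if t.size < 10:
            raise ValueError("recovery limb needs at least 10 samples")
        cands = t[(t >= t[0]) & (t <= t[0] + 0.75 * (t[-1] - t[0]))]
        fits = {float(d): self._sub_fit(t, y, d) for d in cands}
        d0 = min(fits, key=lambda d: fits[d][2])
        res = minimize_scalar(lambda d: self._sub_fit(t, y, d)[2],
                              bounds=(max(t[0], d0 - 2.5), d0 + 2.5),
                              method="bounded", options={"xatol": 0.02})
        self.delay_ = float(res.x)
        self.asymptote_, self.tau_, self.sse_ = self._sub_fit(t, y, self.delay_)
        lo, hi = self.tau_bounds
        self.boundary_flag_ = bool(self.tau_ < lo * 1.01 or self.tau_ > hi * 0.99)
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        a = self.asymptote_
        return a + (1 - a) * np.minimum(1.0, np.exp(-(t - self.delay_) / self.tau_))


def fit_delayed_exponential(q: TimeSeries, asymptote: str = "free",
                            fixed_asymptote: float = 0.0) -> tuple[float, float, float, float]:
    """Fit the delayed single-exponential; returns (delay, tau, asymptote, sse)."""
    mask = q.t >= 0
    est = DelayedExponential(asymptote=asymptote, fixed_asymptote=fixed_asymptote)
    est.fit(q.t[mask], q.v[mask])
    return est.delay_, est.tau_, est.asymptote_, est.sse_
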