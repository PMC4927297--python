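"""Seeded forward simulation of paired capacitance / reporter experiments.

The generator emits what the analysis stack consumes: a capacitance trace
(baseline + exocytotic step jumps + recovery decay, pF, at ``cap_hz``), a
raw reporter-fluorescence trace (quenching on exocytosis, de-quenching as
retrieved organelles re-acidify, imaged at ``imaging_hz`` with optional
photobleaching and Gaussian noise), a neighbor-ROI bleach-reference trace,
and acid-puff transients reporting the surface pool.  A per-time state log
(surface / endocytosed-unacidified / acidified reporter fractions) carries
the ground truth for recovery tests.

Time convention: t = 0 at the offset of the last stimulus pulse; recovery
fits concern the limb t >= 0.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .reacidification import hh_fluorescence, recovery_kernel
from .scenarios import PuffEvent, ReacidificationParams, ScenarioParams
from .traces import TimeSeries

__all__ = [
    "rng_stream",
    "simulate_capacitance",
    "simulate_reporter",
    "simulate_neighbor_roi",
    "simulate_acid_puff",
    "simulate_scenario",
]

_FINE_DT = 0.02  # s; internal grid for the noise-free forward model


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Independent, named, reproducible random stream.

    Streams are derived from (seed, crc32(name)) so adding a new consumer
    never perturbs the draws of existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _pulse_times(scn: ScenarioParams) -> tuple[np.ndarray, np.ndarray]:
    """Pulse onsets/offsets in trace time (last offset at t = 0)."""
    shift = scn.protocol.last_offset
    return scn.protocol.onsets - shift, scn.protocol.offsets - shift


def _recovery(t: np.ndarray, scn: ScenarioParams) -> np.ndarray:
    """Normalized retained-membrane fraction R(t) for one unit jump at t=0."""
    p = scn.endo.plateau_frac
    out = np.full_like(t, p, dtype=float)
    for frac, tau in scn.endo.components:
        out += (1 - p) * frac * np.exp(-np.clip(t, 0, None) / tau)
    return np.where(t < 0, 1.0, out)


def _cm_clean(t: np.ndarray, scn: ScenarioParams) -> np.ndarray:
    """Noise-free capacitance in pF on an arbitrary time grid."""
    onsets, offsets = _pulse_times(scn)
    steps = np.zeros_like(t)
    for w, t_off in zip(scn.per_pulse_weights, offsets):
        steps += np.where(t >= t_off, w, 0.0)
    if scn.endo_onset == "train_end":
        # retrieval of the whole train's recoverable membrane starts at the
        # last pulse offset (endocytosis suppressed during the short train)
        cum = scn.jump_total_pF * steps * _recovery(t, scn)
    else:  # per_pulse superposition, each pulse recovering from its own offset
        cum = np.zeros_like(t)
        for w, t_off in zip(scn.per_pulse_weights, offsets):
            cum += scn.jump_total_pF * w * np.where(t >= t_off, _recovery(t - t_off, scn), 0.0)
    return scn.baseline_cm_pF + cum


def _time_grid(scn: ScenarioParams, hz: float) -> np.ndarray:
    n_pre = int(round(scn.pre_s * hz))
    n_post = int(round(scn.duration_s * hz))
    return np.arange(-n_pre, n_post + 1) / hz


def simulate_capacitance(scn: ScenarioParams) -> TimeSeries:
    """Capacitance trace at ``cap_hz`` with additive Gaussian noise
    (sd = noise_sd * jump_total_pF)."""
    t = _time_grid(scn, scn.cap_hz)
    v = _cm_clean(t, scn)
    if scn.noise_sd > 0:
        v = v + rng_stream(scn.seed, "cm").normal(0.0, scn.noise_sd * scn.jump_total_pF, t.size)
    onsets, offsets = _pulse_times(scn)
    meta = {
        "scenario": scn.name, "seed": scn.seed, "kind": "capacitance",
        "t0": "last pulse offset", "pulse_onsets": onsets, "pulse_offsets": offsets,
        "baseline_cm_pF": scn.baseline_cm_pF, "jump_total_pF": scn.jump_total_pF,
    }
    return TimeSeries(t, v, "pF", meta)


def _bleach_factor(t: np.ndarray, scn: ScenarioParams) -> np.ndarray:
    model, rate = scn.bleach
    rel = t - t[0]
    if model == "none" or rate == 0:
        return np.ones_like(t)
    if model == "linear":
        return np.clip(1.0 - rate * rel, 0.0, None)
    return np.exp(-rate * rel)


def _state_fractions(scn: ScenarioParams) -> tuple[np.ndarray, pd.DataFrame]:
    """Fine-grid reporter bookkeeping, normalized to the exposed pool.

    Columns: ``exposed`` (cumulative exocytosed reporter), ``surface``
    (exposed reporter still at surface pH on the plasma membrane),
    ``endocytosed`` (retrieved, not yet acidified), ``acidified``.  For
    t >= 0 the three disjoint states sum to ``exposed`` = 1 exactly.
    """
    t = np.arange(round(-scn.pre_s / _FINE_DT), round(scn.duration_s / _FINE_DT) + 1) * _FINE_DT
    onsets, offsets = _pulse_times(scn)
    exposed = np.zeros_like(t)
    for w, t_off in zip(scn.per_pulse_weights, offsets):
        exposed += np.where(t >= t_off - 1e-12, w, 0.0)

    p = scn.endo.plateau_frac
    strand = scn.stranding_frac

    def retrieved_unit(u: np.ndarray) -> np.ndarray:
        # cumulative retrieved fraction of a unit pool recovering from u = 0
        out = np.zeros_like(u)
        for frac, tau in scn.endo.components:
            out += (1 - p) * frac * (1.0 - np.exp(-np.clip(u, 0, None) / tau))
        return np.where(u < 0, 0.0, out)

    def acidified_unit(n: int) -> np.ndarray:
        # absorbed fraction on grid indices 0..n-1 after a unit pool starts
        # recovering at index 0: exact cell masses of the analytic flux
        # convolved with the kernel at cell midpoints (second order in dt)
        u = np.arange(n) * _FINE_DT
        dm = np.diff(retrieved_unit(u))
        g_mid = recovery_kernel((np.arange(n - 1) + 0.5) * _FINE_DT, scn.reacid)
        return np.concatenate([[0.0], np.convolve(dm, g_mid)[: n - 1]])

    if scn.endo_onset == "train_end":
        retrieved = retrieved_unit(t)
        if not scn.reacid_blocked:
            i0 = int(np.searchsorted(t, -1e-12))
            acid = acidified_unit(t.size - i0)
            acidified_ret = np.concatenate([np.zeros(i0), acid])
    else:
        retrieved = np.zeros_like(t)
        acidified_ret = np.zeros_like(t)
        for w, t_off in zip(scn.per_pulse_weights, offsets):
            retrieved += w * retrieved_unit(t - t_off)
            if not scn.reacid_blocked:
                i0 = int(np.searchsorted(t, t_off - 1e-12))
                acid = acidified_unit(t.size - i0)
                acidified_ret[i0:] += w * acid
    if scn.reacid_blocked:
        acidified_ret = np.zeros_like(t)

    surface = strand * exposed + (1 - strand) * (exposed - retrieved)
    endocytosed = (1 - strand) * (retrieved - acidified_ret)
    acidified = (1 - strand) * acidified_ret
    log = pd.DataFrame({
        "time_s": t, "exposed": exposed, "surface": surface,
        "endocytosed": endocytosed, "acidified": acidified,
    })
    return t, log


def simulate_reporter(scn: ScenarioParams, cm: TimeSeries | None = None
                      ) -> tuple[TimeSeries, pd.DataFrame]:
    """Raw reporter-fluorescence trace at ``imaging_hz`` plus the state log.

    The noise-free quench dynamics are computed internally on a fine grid
    (the capacitance trace argument is validated for provenance only);
    fluorescence is F(t) = (1 - df_over_f * unacidified_exposed(t)) *
    bleach(t) + noise, with noise sd = noise_sd * df_over_f.
    """
    if cm is not None:
        if cm.meta.get("scenario") != scn.name or cm.meta.get("seed") != scn.seed:
            raise ValueError(
                "capacitance trace provenance does not match the scenario "
                f"({cm.meta.get('scenario')!r}/{cm.meta.get('seed')} vs {scn.name!r}/{scn.seed})"
            )
    t_fine, log = _state_fractions(scn)
    unacid = log["exposed"].to_numpy() - log["acidified"].to_numpy()
    t_img = _time_grid(scn, scn.imaging_hz)
    u_img = np.interp(t_img, t_fine, unacid)
    f = (1.0 - scn.df_over_f * u_img) * _bleach_factor(t_img, scn)
    if scn.noise_sd > 0:
        f = f + rng_stream(scn.seed, "fluor").normal(0.0, scn.noise_sd * scn.df_over_f, t_img.size)
    onsets, offsets = _pulse_times(scn)
    meta = {
        "scenario": scn.name, "seed": scn.seed, "kind": "fluorescence",
        "t0": "last pulse offset", "pulse_onsets": onsets, "pulse_offsets": offsets,
        "df_over_f": scn.df_over_f, "bleach": list(scn.bleach),
    }
    return TimeSeries(t_img, f, "au", meta), log


def simulate_neighbor_roi(scn: ScenarioParams, level: float = 1.0) -> TimeSeries:
    """Unstimulated neighbor-ROI trace: constant level x bleach(t) + noise."""
    t = _time_grid(scn, scn.imaging_hz)
    v = level * _bleach_factor(t, scn)
    if scn.noise_sd > 0:
        v = v + rng_stream(scn.seed, "neighbor").normal(0.0, scn.noise_sd * scn.df_over_f, t.size)
    return TimeSeries(t, v, "au", {"scenario": scn.name, "seed": scn.seed, "kind": "neighbor"})


def simulate_acid_puff(scn: ScenarioParams, fluor: TimeSeries, state_log: pd.DataFrame,
                       puffs: list[PuffEvent]) -> TimeSeries:
    """Superimpose acid-puff de-quench transients on a fluorescence trace.

    During each puff the surface pool (pre-existing stranded reporter,
    ``surface_stranded_density``, plus any exposed reporter still on the
    membrane) fluoresces in proportion to the titration contrast of the puff
    pH.  Each transient's normalized amplitude is recorded in
    ``meta['puff_dF']``.
    """
    if not puffs:
        return fluor
    events = sorted(puffs, key=lambda p: p.onset_s)
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.onset_s + a.duration_s:
            raise ValueError(f"puffs at {a.onset_s} s and {b.onset_s} s overlap")
    t0, t1 = fluor.span
    v = fluor.v.copy()
    phi_s = hh_fluorescence(scn.reacid.pH_surface, scn.reacid)
    phi_l = hh_fluorescence(scn.reacid.pH_lumen, scn.reacid)
    dfs = []
    for ev in events:
        if ev.onset_s < t0 or ev.onset_s + ev.duration_s > t1:
            raise ValueError(f"puff at {ev.onset_s} s outside trace span {fluor.span}")
        surf = np.interp(ev.onset_s, state_log["time_s"], state_log["surface"])
        pool = scn.surface_stranded_density + surf
        contrast = (hh_fluorescence(ev.pH, scn.reacid) - phi_s) / (phi_l - phi_s)
        d_f = pool * contrast
        dfs.append(float(d_f))
        in_puff = (fluor.t >= ev.onset_s) & (fluor.t < ev.onset_s + ev.duration_s)
        v[in_puff] += scn.df_over_f * d_f
    out = fluor.copy_with(v=v)
    out.meta["puff_dF"] = dfs
    out.meta["puffs"] = [(p.onset_s, p.duration_s, p.pH) for p in events]
    return out


def simulate_scenario(scn: ScenarioParams, puffs: list[PuffEvent] | None = None
                      ) -> dict[str, object]:
    """Run the full generator for one scenario.

    Returns a dict with keys ``capacitance``, ``fluorescence``, ``neighbor``
    (TimeSeries), ``state_log`` (DataFrame) and ``truth`` (ground-truth
    parameter dict for recovery tests).
    """
    cm = simulate_capacitance(scn)
    fluor, log = simulate_reporter(scn, cm)
    if puffs:
        fluor = simulate_acid_puff(scn, fluor, log, puffs)
    neighbor = simulate_neighbor_roi(scn)
    truth = {
        "scenario": scn.name, "seed": scn.seed,
        "jump_total_pF": scn.jump_total_pF, "baseline_cm_pF": scn.baseline_cm_pF,
        "plateau_frac": scn.endo.plateau_frac,
        "endo_components": [list(c) for c in scn.endo.components],
        "delay_s": scn.reacid.delay_s, "tau_acid_s": scn.reacid.tau_acid_s,
        "stranding_frac": scn.stranding_frac, "reacid_blocked": scn.reacid_blocked,
        "surface_stranded_density": scn.surface_stranded_density,
    }
    return {"capacitance": cm, "fluorescence": fluor, "neighbor": neighbor,
            "state_log": log, "truth": truth}
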