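"""Whole-cell electrophysiology analysis.

Miniature postsynaptic current (mPSC) detection by scaled-template
matching (Clements & Bekkers criterion), per-event kinetics, passive
membrane properties from a -5 mV seal-test pulse, and firing/rheobase
analysis of current-step families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

__all__ = [
    "SweepTrace",
    "PscEvent",
    "psc_template",
    "detect_mpsc",
    "event_kinetics",
    "passive_properties",
    "fi_analysis",
    "distribution_compare",
]


@dataclass
class SweepTrace:
    """One sweep of current (pA, voltage clamp) or voltage (mV, current clamp)."""

    samples: np.ndarray
    fs_hz: float
    mode: str = "voltage_clamp"  # or "current_clamp"
    command: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise ValueError("mode must be voltage_clamp or current_clamp")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs_hz


@dataclass
class PscEvent:
    t_peak_s: float
    amplitude_pA: float  # baseline-to-peak magnitude
    rise_10_90_ms: float | None = None
    decay_tau_ms: float | None = None
    iei_s: float | None = None  # to previous event
    flagged: bool = False


def psc_template(
    rise_ms: float, decay_ms: float, fs_hz: float, length_factor: float = 5.0
) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak."""
    if not decay_ms > rise_ms > 0:
        raise ValueError("require decay_ms > rise_ms > 0")
    n = int(round(length_factor * decay_ms / 1000.0 * fs_hz))
    t = np.arange(n) / fs_hz
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def _template_fit(x: np.ndarray, template: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sliding least-squares fit of scale*template + offset at every start
    position, via running sums.  Returns (scale, t_statistic) where the
    t-statistic is scale / SE(scale) — the template-fit detection
    criterion."""
    n = len(template)
    if len(x) < n:
        raise ValueError("template longer than trace")
    e = template
    se = e.sum()
    sse = (e * e).sum()
    ones = np.ones(n)
    sx = np.convolve(x, ones, mode="valid")
    sxx = np.convolve(x * x, ones, mode="valid")
    sex = np.correlate(x, e, mode="valid")
    denom = sse - se * se / n
    scale = (sex - se * sx / n) / denom
    offset = (sx - scale * se) / n
    sse_fit = (
        sxx
        + scale**2 * sse
        + n * offset**2
        - 2 * (scale * sex + offset * sx - scale * offset * se)
    )
    sse_fit = np.maximum(sse_fit, 0.0)
    # small absolute noise floor keeps the statistic finite and sharply
    # peaked at the true alignment on noiseless traces
    sigma2 = np.maximum(sse_fit / max(n - 2, 1), 1e-6)
    se_scale = np.sqrt(sigma2 / denom)
    se_scale[se_scale == 0] = np.finfo(float).tiny
    with np.errstate(over="ignore", invalid="ignore"):
        tstat = scale / se_scale
    return scale, np.nan_to_num(tstat, posinf=1e12, neginf=-1e12)


def detect_mpsc(
    trace: SweepTrace,
    rise_ms: float = 0.5,
    decay_ms: float = 5.0,
    criterion_threshold: float = 5.0,
    polarity: int = -1,
    compute_kinetics: bool = True,
    min_scale_pA: float = 0.0,
) -> list[PscEvent]:
    """Detect miniature PSCs by iterative scaled-template fitting.

    A difference-of-exponentials template is least-squares fitted (scale +
    offset) at every position; the detection criterion is the fitted
    scale divided by its standard error.  Events are accepted greedily:
    the best-matching position is taken, its fitted template subtracted,
    and the criterion recomputed locally, so an event sitting on another
    event's decay is still resolved and decay tails do not retrigger.
    ``polarity`` -1 detects inward (negative) events, +1 outward.
    """
    if trace.mode != "voltage_clamp":
        raise ValueError("mPSC detection requires a voltage-clamp trace")
    x = polarity * trace.samples  # positive-going deflections
    template = psc_template(rise_ms, decay_ms, trace.fs_hz)
    n = len(template)
    work = x.astype(float).copy()
    scale, crit = _template_fit(work, template)
    peak_offset = int(np.argmax(template))
    peak_search = max(2 * peak_offset, 2)
    max_events = int(200 * trace.duration_s) + 10

    # left-to-right scan: accept the locally best alignment, subtract the
    # fitted event, refresh the criterion over the affected span, continue.
    # Sequential order keeps fits from straddling earlier subtractions.
    events: list[PscEvent] = []
    taken = np.zeros(len(work), dtype=bool)
    ptr = 0
    while len(events) < max_events and ptr < len(crit):
        ahead = crit[ptr:] >= criterion_threshold
        rel = int(np.argmax(ahead))
        if not ahead[rel]:
            break
        j = ptr + rel
        # align to the best criterion within one peak offset, then
        # hill-climb so a gradual approach still lands on the true peak
        win_end = min(j + peak_offset + 1, len(crit))
        jj = j + int(np.argmax(crit[j:win_end]))
        while jj + 1 < len(crit) and crit[jj + 1] > crit[jj]:
            jj += 1
        sc = scale[jj]
        if sc <= min_scale_pA:
            ptr = jj + 1
            continue
        seg = work[jj : min(jj + peak_search, len(work))]
        p = jj + int(np.argmax(seg))
        if taken[p]:  # residual of an already-accepted event
            ptr = jj + 1
            continue
        taken[max(p - peak_offset, 0) : p + peak_offset + 1] = True
        events.append(PscEvent(t_peak_s=p / trace.fs_hz, amplitude_pA=np.nan))
        stop = min(jj + n, len(work))
        work[jj:stop] -= sc * template[: stop - jj]
        lo = max(jj - n + 1, 0)
        hi = min(jj + n, len(crit))
        s_loc, c_loc = _template_fit(work[lo : min(hi + n - 1, len(work))], template)
        scale[lo : lo + len(s_loc)] = s_loc
        crit[lo : lo + len(c_loc)] = c_loc
        ptr = jj + 1

    for ev in events:
        p = int(round(ev.t_peak_s * trace.fs_hz))
        if compute_kinetics:
            _fill_kinetics(ev, x, p, trace.fs_hz, decay_ms)
        else:
            base = np.median(x[max(p - int(0.010 * trace.fs_hz), 0) : max(p - 2, 1)])
            ev.amplitude_pA = float(x[p] - base)
    events.sort(key=lambda e: e.t_peak_s)
    for prev, cur in zip(events, events[1:]):
        cur.iei_s = cur.t_peak_s - prev.t_peak_s
    return events


def _fill_kinetics(
    ev: PscEvent, x: np.ndarray, p: int, fs: float, decay_ms: float
) -> None:
    """Measure amplitude, 10-90% rise and decay tau around peak index `p`
    of the positive-going trace `x` (in place on `ev`)."""
    pre = int(round(0.010 * fs))  # 10 ms pre-event baseline
    onset_back = max(int(round(0.002 * fs)), 2)  # peak is ~a rise time past onset
    b0 = max(p - onset_back - pre, 0)
    b1 = max(p - onset_back, b0 + 1)
    baseline = float(np.median(x[b0:b1]))
    amp = float(x[p] - baseline)
    ev.amplitude_pA = amp
    if amp <= 0:
        ev.flagged = True
        return

    lo, hi = baseline + 0.1 * amp, baseline + 0.9 * amp
    i = p
    while i > 0 and x[i] > lo:
        i -= 1
    rise_seg = x[i : p + 1]
    t_cross = {}
    for level, name in ((lo, "lo"), (hi, "hi")):
        crossings = np.flatnonzero((rise_seg[:-1] < level) & (rise_seg[1:] >= level))
        if len(crossings):
            k = crossings[-1]
            frac = (level - rise_seg[k]) / (rise_seg[k + 1] - rise_seg[k])
            t_cross[name] = (i + k + frac) / fs
    if "lo" in t_cross and "hi" in t_cross:
        ev.rise_10_90_ms = (t_cross["hi"] - t_cross["lo"]) * 1000.0

    # decay fit toward baseline over ~4 tau, starting a fraction of a tau
    # past the peak so the residual rise component does not bias tau
    start = p + max(int(round(0.2 * decay_ms / 1000.0 * fs)), 1)
    n_fit = int(round(4 * decay_ms / 1000.0 * fs))
    seg = x[start : start + n_fit]
    if len(seg) < max(int(round(1.5 * decay_ms / 1000.0 * fs)), 5):
        ev.flagged = True  # event at trace edge, incomplete decay
        return
    t = np.arange(len(seg)) / fs
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t,
            seg,
            p0=(amp, decay_ms / 1000.0, baseline),
            bounds=([0.0, 1e-5, -np.inf], [np.inf, 1.0, np.inf]),
            maxfev=2000,
        )
        tau = popt[1]
        if tau <= 0 or tau > 20 * decay_ms / 1000.0:
            ev.flagged = True
        else:
            ev.decay_tau_ms = float(tau * 1000.0)
    except RuntimeError:
        ev.flagged = True


def event_kinetics(
    trace: SweepTrace, peak_index: int, decay_ms: float = 5.0, polarity: int = -1
) -> PscEvent:
    """Kinetics of a single event whose peak sample index is known."""
    x = polarity * trace.samples
    ev = PscEvent(t_peak_s=peak_index / trace.fs_hz, amplitude_pA=np.nan)
    _fill_kinetics(ev, x, peak_index, trace.fs_hz, decay_ms)
    return ev


def passive_properties(
    pulse: SweepTrace, dV_mV: float | None = None
) -> dict[str, float]:
    """Estimate Rs, Rm and Cm from the current response to a voltage step.

    Rs from the instantaneous (extrapolated t=0) peak current, Rm from the
    steady-state deflection, Cm from the single-exponential relaxation time
    constant via Cm = tau / (Rs*Rm/(Rs+Rm)).  The pulse window is taken
    from ``pulse.command['pulse_window_s']``.
    """
    if dV_mV is None:
        dV_mV = pulse.command.get("dV_mV", -5.0)
    window = pulse.command.get("pulse_window_s")
    if window is None:
        raise ValueError("pulse.command must contain 'pulse_window_s'")
    fs = pulse.fs_hz
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    x = pulse.samples
    baseline = float(np.mean(x[: max(i0 - 2, 1)]))
    seg = x[i0:i1] - baseline
    n_ss = max(int(0.25 * len(seg)), 1)
    i_ss = float(np.mean(seg[-n_ss:]))
    if abs(i_ss) < 1e-9:
        raise ValueError("steady-state current is zero; cannot estimate resistances")

    # fit transient: I(t) = Iss + A exp(-t/tau), extrapolate to t=0 for the peak
    p_idx = int(np.argmax(np.abs(seg[: max(len(seg) // 2, 2)])))
    t = np.arange(len(seg)) / fs
    a0 = seg[p_idx] - i_ss
    tau0 = max((len(seg) / fs) * 0.05, 2.0 / fs)
    popt, _ = optimize.curve_fit(
        lambda tt, a, tau, c: c + a * np.exp(-tt / tau),
        t,
        seg,
        p0=(a0, tau0, i_ss),
        maxfev=5000,
    )
    a_fit, tau_s, iss_fit = popt
    i_peak = float(a_fit + iss_fit)
    if abs(i_peak) < 1e-9:
        raise ValueError("peak current is zero; cannot estimate Rs")

    rs_mohm = 1000.0 * dV_mV / i_peak  # mV/pA = GOhm
    r_total = 1000.0 * dV_mV / iss_fit
    rm_mohm = r_total - rs_mohm
    result = {
        "Rs_MOhm": rs_mohm,
        "Rm_MOhm": rm_mohm,
        "tau_ms": float(tau_s * 1000.0),
        "Cm_pF": np.nan,
        "Rm_flagged": rm_mohm <= 0,
    }
    if rm_mohm > 0:
        r_par = rs_mohm * rm_mohm / (rs_mohm + rm_mohm)
        result["Cm_pF"] = 1000.0 * float(tau_s * 1000.0) / r_par  # ms/MOhm = nF
    return result


def _ap_peaks(
    v: np.ndarray, fs: float, threshold_mV: float = 0.0, min_slope_mV_per_ms: float = 2.0
) -> np.ndarray:
    """Indices of action-potential upward threshold crossings with a
    minimum preceding depolarization slope."""
    above = v >= threshold_mV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    keep = []
    for c in crossings:
        j0 = max(c - max(int(round(0.001 * fs)), 1), 0)
        slope = (v[c] - v[j0]) / ((c - j0) / fs * 1000.0)
        if slope >= min_slope_mV_per_ms:
            keep.append(c)
    return np.asarray(keep, dtype=int)


def fi_analysis(
    sweeps: Sequence[SweepTrace],
    threshold_mV: float = 0.0,
    min_slope_mV_per_ms: float = 2.0,
) -> pd.DataFrame:
    """Count action potentials per current step and find the rheobase.

    Each sweep's command metadata must carry ``step_pA`` and
    ``step_window_s``.  Returns a table sorted by step amplitude with AP
    counts and mean AP interevent intervals; the rheobase (smallest step
    with at least one AP) is attached as ``df.attrs['rheobase_pA']``
    (NaN when no step fires).
    """
    rows = []
    for sw in sweeps:
        if sw.mode != "current_clamp":
            raise ValueError("F-I analysis requires current-clamp sweeps")
        step = sw.command.get("step_pA")
        if step is None:
            raise ValueError("sweep.command must contain 'step_pA'")
        w = sw.command.get("step_window_s", (0.0, sw.duration_s))
        i0, i1 = int(round(w[0] * sw.fs_hz)), int(round(w[1] * sw.fs_hz))
        peaks = _ap_peaks(sw.samples[i0:i1], sw.fs_hz, threshold_mV, min_slope_mV_per_ms)
        ieis = np.diff(peaks) / sw.fs_hz
        rows.append(
            {
                "step_pA": float(step),
                "n_ap": int(len(peaks)),
                "mean_iei_s": float(np.mean(ieis)) if len(ieis) else np.nan,
            }
        )
    df = pd.DataFrame(rows).sort_values("step_pA", ignore_index=True)
    firing = df.loc[df["n_ap"] >= 1, "step_pA"]
    df.attrs["rheobase_pA"] = float(firing.iloc[0]) if len(firing) else float("nan")
    return df


def distribution_compare(
    events_a: Sequence[PscEvent],
    events_b: Sequence[PscEvent],
    metric: str = "amplitude",
) -> dict:
    """Two-sample KS comparison of pooled event amplitudes or IEIs."""
    getter = {
        "amplitude": lambda e: e.amplitude_pA,
        "iei": lambda e: e.iei_s,
    }
    if metric not in getter:
        raise ValueError("metric must be 'amplitude' or 'iei'")
    a = np.array([getter[metric](e) for e in events_a if getter[metric](e) is not None])
    b = np.array([getter[metric](e) for e in events_b if getter[metric](e) is not None])
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 events per group")
    ks = stats.ks_2samp(a, b)
    return {
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": len(a),
        "n_b": len(b),
    }
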