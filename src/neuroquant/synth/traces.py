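"""Synthetic electrophysiology traces with ground truth.

Poisson trains of difference-of-exponential miniature events on a noisy
baseline, RC seal-test current transients, and a leaky integrate-and-fire
sweep family for firing-rate analysis, all digitized at a configurable
sampling rate (10 kHz default, matching the acquisition emulated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..ephys import SweepTrace, psc_template

__all__ = ["generate_mpsc_trace", "generate_test_pulse", "generate_lif_family", "lif_rheobase_pA"]


def generate_mpsc_trace(
    rate_hz: float,
    amp_mean_pA: float = 20.0,
    amp_cv: float = 0.3,
    rise_ms: float = 0.5,
    decay_ms: float = 5.0,
    noise_sd_pA: float = 4.0,
    duration_s: float = 60.0,
    fs_hz: float = 10_000.0,
    seed: int = 0,
    polarity: int = -1,
) -> tuple[SweepTrace, pd.DataFrame]:
    """Poisson train of mPSC-shaped events on Gaussian noise.

    Event peak amplitudes are Normal(amp_mean, cv*amp_mean) truncated to
    positive; ``polarity`` -1 renders inward (negative) currents.  Returns
    the trace and a truth table (t_s, amp_pA) of event peak times and
    magnitudes.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if not decay_ms > rise_ms > 0:
        raise ValueError("require decay_ms > rise_ms > 0")
    if rise_ms / 1000.0 * fs_hz < 2:
        raise ValueError("sampling rate too low to resolve the rise time")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    x = rng.normal(0.0, noise_sd_pA, size=n) if noise_sd_pA > 0 else np.zeros(n)

    n_events = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0, duration_s, size=n_events))
    amps = np.abs(rng.normal(amp_mean_pA, amp_cv * amp_mean_pA, size=n_events))
    amps = np.maximum(amps, 0.05 * amp_mean_pA)

    kernel = psc_template(rise_ms, decay_ms, fs_hz)
    peak_offset = int(np.argmax(kernel))
    rows = []
    for t0, a in zip(onsets, amps):
        j = int(round(t0 * fs_hz))
        seg = kernel[: n - j]
        if len(seg) == 0:
            continue
        x[j : j + len(seg)] += polarity * a * seg
        rows.append({"t_s": (j + min(peak_offset, len(seg) - 1)) / fs_hz, "amp_pA": a})
    truth = pd.DataFrame(rows, columns=["t_s", "amp_pA"])
    trace = SweepTrace(
        samples=x,
        fs_hz=fs_hz,
        mode="voltage_clamp",
        command={"holding_mV": -70.0},
    )
    return trace, truth


def generate_test_pulse(
    Rs_MOhm: float = 10.0,
    Rm_MOhm: float = 150.0,
    Cm_pF: float = 100.0,
    dV_mV: float = -5.0,
    fs_hz: float = 10_000.0,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
    pre_s: float = 0.01,
    pulse_s: float = 0.05,
    post_s: float = 0.02,
) -> SweepTrace:
    """Current response of a series-Rs / parallel Rm-Cm cell to a voltage step.

    Instantaneous peak dV/Rs, steady state dV/(Rs+Rm), single-exponential
    relaxation with tau = Cm * (Rs*Rm/(Rs+Rm)).  Units: mV/MOhm -> nA,
    reported in pA; pF*MOhm -> microseconds.
    """
    if min(Rs_MOhm, Rm_MOhm, Cm_pF) <= 0:
        raise ValueError("RC parameters must be positive")
    rng = np.random.default_rng(seed)
    n = int(round((pre_s + pulse_s + post_s) * fs_hz))
    t = np.arange(n) / fs_hz
    i_peak = 1000.0 * dV_mV / Rs_MOhm  # pA
    i_ss = 1000.0 * dV_mV / (Rs_MOhm + Rm_MOhm)
    tau_s = Cm_pF * (Rs_MOhm * Rm_MOhm / (Rs_MOhm + Rm_MOhm)) * 1e-6

    def _step(u: np.ndarray) -> np.ndarray:
        return np.where(u >= 0, i_ss + (i_peak - i_ss) * np.exp(-np.maximum(u, 0) / tau_s), 0.0)

    x = _step(t - pre_s) - _step(t - pre_s - pulse_s)
    if noise_sd_pA > 0:
        x = x + rng.normal(0.0, noise_sd_pA, size=n)
    return SweepTrace(
        samples=x,
        fs_hz=fs_hz,
        mode="voltage_clamp",
        command={"dV_mV": dV_mV, "pulse_window_s": (pre_s, pre_s + pulse_s)},
    )


def lif_rheobase_pA(
    R_MOhm: float, v_rest_mV: float, v_thresh_mV: float
) -> float:
    """Steady-state rheobase of the leaky integrate-and-fire cell:
    smallest constant current driving V to threshold, (Vth - Vrest)/R."""
    return 1000.0 * (v_thresh_mV - v_rest_mV) / R_MOhm


def generate_lif_family(
    steps_pA: np.ndarray | list[float],
    R_MOhm: float = 150.0,
    tau_ms: float = 15.0,
    v_rest_mV: float = -70.0,
    v_thresh_mV: float = -45.0,
    v_reset_mV: float = -60.0,
    spike_peak_mV: float = 30.0,
    refractory_ms: float = 2.0,
    step_duration_s: float = 0.3,
    pre_s: float = 0.05,
    post_s: float = 0.05,
    fs_hz: float = 10_000.0,
    noise_sd_mV: float = 0.0,
    seed: int = 0,
) -> list[SweepTrace]:
    """Leaky integrate-and-fire responses to a family of current steps.

    On threshold crossing a two-sample spike to ``spike_peak_mV`` is
    pasted in (so a 0 mV-crossing AP detector sees it) and V resets after
    an absolute refractory period.  Step timing and amplitude are recorded
    in each sweep's command metadata.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_hz
    n = int(round((pre_s + step_duration_s + post_s) * fs_hz))
    i0, i1 = int(round(pre_s * fs_hz)), int(round((pre_s + step_duration_s) * fs_hz))
    refr = int(round(refractory_ms / 1000.0 * fs_hz))
    sweeps = []
    for step in steps_pA:
        v = np.empty(n)
        v[0] = v_rest_mV
        vm = v_rest_mV
        k = 1
        while k < n:
            i_inj = step if i0 <= k < i1 else 0.0
            dv = (-(vm - v_rest_mV) + R_MOhm * i_inj / 1000.0) * dt / (tau_ms / 1000.0)
            vm = vm + dv
            if vm >= v_thresh_mV and i0 <= k < i1:
                v[k] = spike_peak_mV
                if k + 1 < n:
                    v[k + 1] = spike_peak_mV
                k += 2
                stop = min(k + refr, n)
                v[k:stop] = v_reset_mV
                k = stop
                vm = v_reset_mV
                continue
            v[k] = vm
            k += 1
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, size=n)
        sweeps.append(
            SweepTrace(
                samples=v,
                fs_hz=fs_hz,
                mode="current_clamp",
                command={"step_pA": float(step), "step_window_s": (pre_s, pre_s + step_duration_s)},
            )
        )
    return sweeps
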