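"""Ground-truth network simulator.

A chaotic three-coordinate Roessler driver (subnetwork X) feeds forward onto a
population of leaky tanh rate units (subnetwork Y):

    tau0 dx1/dt = -x2 - x3
    tau0 dx2/dt =  x1 + alpha*x2
    tau0 dx3/dt =  beta + x3*(x1 - gamma)
    tau0 dy/dt  = -lam*y + 10*tanh(J_YX x + J_YY y + I) [+ pulse input]

with J_YX = g * ones (every Y unit receives the summed driver) and J_YY drawn
i.i.d. from N(0, g_r).  There is no feedback from Y to X, which is the
ground-truth causal asymmetry every downstream inference stage is validated
against.  Integration is fixed-step 4th-order Runge-Kutta; weak private
dynamical noise (``sigma_dyn``) is added to the Y units after each step in
Euler-Maruyama fashion.  Identical parameters (including the seed) give
bit-identical output.
"""

from __future__ import annotations

import numpy as np

from .datatypes import EnsembleTimeSeries, NoiseSpec, PerturbationSession, SimulatorParams

__all__ = [
    "simulate_network",
    "inject_noise",
    "run_perturbation_session",
    "make_trial_onsets",
    "poissonify",
    "unit_names",
]

OVERFLOW_GUARD = 1e6


def unit_names(params: SimulatorParams) -> tuple[list[str], list[str]]:
    """Unit ids (x1..x3, y4..y{3+n_y}) and subnetwork labels."""
    ids = [f"x{i + 1}" for i in range(params.n_x)] + [
        f"y{params.n_x + i + 1}" for i in range(params.n_y)
    ]
    labels = ["X"] * params.n_x + ["Y"] * params.n_y
    return ids, labels


def _draw_network(params: SimulatorParams, rng: np.random.Generator):
    """Weights and initial conditions; draw order is fixed so that perturbed
    and unperturbed runs with the same seed share them exactly."""
    J_yx = params.g * np.ones((params.n_y, params.n_x))
    J_yy = rng.normal(0.0, params.g_r, size=(params.n_y, params.n_y)) if params.g_r > 0 else np.zeros(
        (params.n_y, params.n_y)
    )
    x0 = rng.uniform(-1.0, 1.0, size=params.n_x)
    x0[2] = abs(x0[2])  # start x3 on the attractor side
    y0 = rng.uniform(-1.0, 1.0, size=params.n_y)
    return J_yx, J_yy, x0, y0


def _integrate(params: SimulatorParams, pulse: tuple[int, float, np.ndarray] | None) -> np.ndarray:
    """RK4 integration of the full (n_x + n_y)-dim system.

    ``pulse`` is ``(unit_index, strength, onset_offset_pairs)`` with times in
    absolute simulation time; input is piecewise-constant over each RK4 step
    (evaluated at the step's start), so a zero-strength pulse reproduces the
    unperturbed trajectory bit-exactly.
    """
    rng = np.random.default_rng(params.seed)
    J_yx, J_yy, x, y = _draw_network(params, rng)
    a, b, c = params.alpha, params.beta, params.gamma
    lam, I, tau0, dt = params.lam, params.I, params.tau0, params.dt
    n_steps = int(round(params.duration / dt))
    n_skip = int(round(params.transient / dt))
    out = np.empty((params.n_units, n_steps - n_skip))

    u_x = np.zeros(params.n_x)
    u_y = np.zeros(params.n_y)
    if pulse is not None:
        p_idx, p_strength, p_intervals = pulse

    sqrt_dt = np.sqrt(dt)

    def deriv(x, y, u_x, u_y):
        dx = np.array(
            [
                -x[1] - x[2],
                x[0] + a * x[1],
                b + x[2] * (x[0] - c),
            ]
        )
        dx = (dx + u_x) / tau0
        dy = (-lam * y + 10.0 * np.tanh(J_yx @ x + J_yy @ y + I) + u_y) / tau0
        return dx, dy

    for step in range(n_steps):
        if pulse is not None:
            t = step * dt
            active = bool(np.any((p_intervals[:, 0] <= t) & (t < p_intervals[:, 1])))
            if p_idx < params.n_x:
                u_x[p_idx] = p_strength if active else 0.0
            else:
                u_y[p_idx - params.n_x] = p_strength if active else 0.0
        k1x, k1y = deriv(x, y, u_x, u_y)
        k2x, k2y = deriv(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, u_x, u_y)
        k3x, k3y = deriv(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, u_x, u_y)
        k4x, k4y = deriv(x + dt * k3x, y + dt * k3y, u_x, u_y)
        x = x + (dt / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        y = y + (dt / 6.0) * (k1y + 2 * k2y + 2 * k3y + k4y)
        if params.sigma_dyn > 0:
            y = y + params.sigma_dyn * sqrt_dt * rng.standard_normal(params.n_y)
        if max(np.abs(x).max(), np.abs(y).max()) > OVERFLOW_GUARD:
            raise FloatingPointError(
                f"trajectory diverged (|value| > {OVERFLOW_GUARD:g}) at t={step * dt:.3f} "
                f"with g={params.g}, g_r={params.g_r}, lam={params.lam}, I={params.I}"
            )
        if step >= n_skip:
            out[: params.n_x, step - n_skip] = x
            out[params.n_x :, step - n_skip] = y
    return out


def simulate_network(params: SimulatorParams) -> EnsembleTimeSeries:
    """Simulate the unperturbed network; returns post-transient activity."""
    values = _integrate(params, pulse=None)
    ids, labels = unit_names(params)
    return EnsembleTimeSeries(values, params.dt, ids, labels)


def make_trial_onsets(
    n_trials: int,
    record_duration: float,
    pulse_duration: float = 1.0,
    window: float = 2.0,
    seed: int = 0,
    gap_factor: float = 10.0,
) -> np.ndarray:
    """Jittered non-overlapping trial onsets in recording time.

    Trials are laid on a regular lattice with inter-trial gap at least
    ``gap_factor * pulse_duration`` and uniform jitter within each slot.
    """
    rng = np.random.default_rng(seed)
    slot = pulse_duration + 2 * window + gap_factor * pulse_duration
    lead = window  # room for the pre window of the first trial
    tail = pulse_duration + window
    avail = record_duration - lead - tail
    if avail < n_trials * slot:
        raise ValueError(
            f"recording of {record_duration} too short for {n_trials} trials "
            f"(needs >= {lead + tail + n_trials * slot:.1f})"
        )
    jitter_span = avail / n_trials - slot
    starts = lead + np.arange(n_trials) * (avail / n_trials)
    return starts + rng.uniform(0, jitter_span, size=n_trials) + window


def run_perturbation_session(params: SimulatorParams, session: PerturbationSession) -> EnsembleTimeSeries:
    """Re-run the simulation with pulse input on the stimulated unit.

    With the same ``params.seed`` the weights, initial conditions and
    dynamical-noise draws match :func:`simulate_network` exactly, so a
    zero-strength pulse returns a bit-identical trajectory.  The perturbed
    recording is attached to ``session.recording``.
    """
    ids, labels = unit_names(params)
    if session.stimulated_unit not in ids:
        raise ValueError(f"unknown stimulated unit {session.stimulated_unit!r}")
    record_duration = params.duration - params.transient
    lo = session.trial_onsets.min() - session.window
    hi = session.trial_onsets.max() + session.pulse_duration + session.window
    if lo < 0 or hi > record_duration:
        raise ValueError(
            f"trial windows [{lo:.3f}, {hi:.3f}] fall outside the recording [0, {record_duration:.3f})"
        )
    intervals = np.column_stack(
        [
            session.trial_onsets + params.transient,
            session.trial_onsets + params.transient + session.pulse_duration,
        ]
    )
    p_idx = ids.index(session.stimulated_unit)
    values = _integrate(params, pulse=(p_idx, session.pulse_strength, intervals))
    ts = EnsembleTimeSeries(values, params.dt, ids, labels)
    session.recording = ts
    return ts


def inject_noise(ts: EnsembleTimeSeries, spec: NoiseSpec) -> EnsembleTimeSeries:
    """Add observational Gaussian noise at an exact per-unit SNR.

    The realized noise is rescaled so that the *measured* SNR,
    10*log10(sd(signal)/sd(noise)) with sd taken over time per unit, equals
    ``spec.snr_db`` exactly.  ``private`` draws an independent realization per
    unit; ``shared`` adds one scalar realization (per-unit scaled) to all
    units.
    """
    rng = np.random.default_rng(spec.seed)
    sd_signal = ts.values.std(axis=1)
    if np.any(sd_signal == 0):
        bad = [ts.unit_ids[i] for i in np.nonzero(sd_signal == 0)[0]]
        raise ValueError(f"zero-variance signal for units {bad}")
    sd_noise = sd_signal * 10.0 ** (-spec.snr_db / 10.0)
    T = ts.n_samples
    if spec.mode == "private":
        e = rng.standard_normal((ts.n_units, T))
        e = e - e.mean(axis=1, keepdims=True)
        e = e / e.std(axis=1, keepdims=True) * sd_noise[:, None]
    else:
        z = rng.standard_normal(T)
        z = (z - z.mean()) / z.std()
        e = sd_noise[:, None] * z[None, :]
    return EnsembleTimeSeries(ts.values + e, ts.dt, list(ts.unit_ids), ts.subnetwork_labels)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def poissonify(ts: EnsembleTimeSeries, gain: float, bin_width: float, seed: int = 0) -> EnsembleTimeSeries:
    """Emulate electrode spike-count observations.

    The latent rate is ``gain * softplus(activity)`` (nonnegative by
    construction); counts per unit per bin are Poisson with mean equal to the
    rate integrated over the bin.
    """
    if bin_width < ts.dt:
        raise ValueError("bin width must be >= sampling interval dt")
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    rng = np.random.default_rng(seed)
    step = int(round(bin_width / ts.dt))
    n_bins = ts.n_samples // step
    rate = gain * _softplus(ts.values[:, : n_bins * step])
    lam = rate.reshape(ts.n_units, n_bins, step).mean(axis=2) * (step * ts.dt)
    counts = rng.poisson(lam).astype(float)
    return EnsembleTimeSeries(counts, step * ts.dt, list(ts.unit_ids), ts.subnetwork_labels)
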