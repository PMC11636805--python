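"""Core containers shared across the pipeline.

Conventions used throughout the package (enforced by ``validate_directed_matrix``):

* time is measured in simulator time units; samples use 0-based indices and
  half-open windows ``[t0, t1)``;
* every N x N directed-connectivity matrix is oriented with **rows = targets**
  (the unit whose activity is used / affected) and **columns = sources** (the
  unit whose influence is scored), so column ``j`` is the causal-flow vector
  ``f^(j)`` or the perturbation vector ``s^(j)``;
* undefined entries (diagonals, unstimulated sources, constant units) are NaN
  and must be False in the significance mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EnsembleTimeSeries",
    "SimulatorParams",
    "NoiseSpec",
    "PerturbationSession",
    "DelayMatrix",
    "CFMatrix",
    "ICMatrix",
    "BaselineMatrix",
    "ArrayGeometry",
    "TwinSet",
    "SurrogateEnsemble",
    "validate_directed_matrix",
]


@dataclass
class EnsembleTimeSeries:
    """Units x time activity matrix with a fixed sampling interval.

    ``values[i, t]`` is the activity of unit ``unit_ids[i]`` at time ``t * dt``
    (relative to the start of the recording). ``subnetwork_labels`` optionally
    tags each unit as belonging to the driver subnetwork ``"X"`` or the driven
    subnetwork ``"Y"``.
    """

    values: np.ndarray
    dt: float
    unit_ids: list[str]
    subnetwork_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (units x time) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/inf")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.unit_ids = [str(u) for u in self.unit_ids]
        if len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids length does not match number of rows")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit ids")
        if self.subnetwork_labels is not None and len(self.subnetwork_labels) != len(self.unit_ids):
            raise ValueError("subnetwork_labels length does not match unit count")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def index_of(self, unit_id: str) -> int:
        return self.unit_ids.index(str(unit_id))

    def series(self, unit_id: str) -> np.ndarray:
        return self.values[self.index_of(unit_id)]

    def subset(self, unit_ids: Sequence[str]) -> "EnsembleTimeSeries":
        idx = [self.index_of(u) for u in unit_ids]
        labels = None
        if self.subnetwork_labels is not None:
            labels = [self.subnetwork_labels[i] for i in idx]
        return EnsembleTimeSeries(self.values[idx], self.dt, [self.unit_ids[i] for i in idx], labels)

    def bin(self, bin_width: float) -> "EnsembleTimeSeries":
        """Window-average the series at a coarser sampling interval.

        Emulates binned activity (spike-count style) at ``bin_width``; the
        trailing partial bin is dropped.
        """
        if bin_width < self.dt:
            raise ValueError("bin_width must be >= dt")
        step = int(round(bin_width / self.dt))
        n_bins = self.n_samples // step
        if n_bins < 2:
            raise ValueError("bin_width too large for series length")
        v = self.values[:, : n_bins * step].reshape(self.n_units, n_bins, step).mean(axis=2)
        return EnsembleTimeSeries(v, step * self.dt, list(self.unit_ids), self.subnetwork_labels)


@dataclass
class SimulatorParams:
    """Parameters of the ground-truth driver->driven rate network.

    Three units (subnetwork X) follow chaotic Roessler dynamics with
    coefficients ``alpha, beta, gamma`` and are fed forward — via ``J_YX = g *
    ones`` — onto ``n_y`` leaky tanh rate units (subnetwork Y) with random
    recurrent weights ``J_YY ~ N(0, g_r)``.  The base network is
    deterministic; ``sigma_dyn > 0`` optionally adds private dynamical noise
    to the Y units (intrinsic variability of the driven population) for
    robustness studies.  Even at ``sigma_dyn = 0`` each driven unit's
    trajectory depends on the full 100-dimensional recurrent state, not on
    the driver alone, so single driven units are poorly reconstructible from
    the driver's delay embedding — the asymmetry cross-mapping exploits.
    """

    alpha: float = 0.2
    beta: float = 0.2
    gamma: float = 5.7
    tau0: float = 1.0
    lam: float = 1.0
    g: float = 0.1
    g_r: float = 0.05
    I: float = 0.0
    n_x: int = 3
    n_y: int = 100
    dt: float = 0.01
    duration: float = 220.0
    transient: float = 20.0
    sigma_dyn: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_x != 3:
            raise ValueError("the Roessler driver defines exactly three coordinates (n_x=3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.transient < self.duration:
            raise ValueError("transient must be smaller than duration")
        if self.g < 0 or self.g_r < 0:
            raise ValueError("coupling strengths must be nonnegative")
        if self.sigma_dyn < 0:
            raise ValueError("sigma_dyn must be nonnegative")

    @property
    def n_units(self) -> int:
        return self.n_x + self.n_y


@dataclass
class NoiseSpec:
    """Observational-noise specification at a controlled SNR.

    ``snr_db`` follows the convention 10*log10(sigma_signal / sigma_noise)
    (ratio of standard deviations, in dB). ``mode="private"`` draws i.i.d.
    noise per unit; ``mode="shared"`` adds a single scalar realization (scaled
    per unit) to every unit, emulating a common input.
    """

    mode: str
    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("private", "shared"):
            raise ValueError("mode must be 'private' or 'shared'")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass
class PerturbationSession:
    """Pulse-stimulation protocol for one source unit.

    Onsets are expressed in recording time (0 = first post-transient sample).
    On the package's time convention (1 time unit = 100 ms equivalent) the
    defaults are a 100 ms pulse and 200 ms comparison windows.  The pulse
    adds ``pulse_strength`` to the stimulated unit's rate equation during
    each half-open interval ``[onset, onset + pulse_duration)``.  The
    pre window is ``[onset - window, onset)`` and the post window is
    ``[offset, offset + window)`` where ``offset = onset + pulse_duration``.
    After :func:`causalflow.simulator.run_perturbation_session` the perturbed
    trajectory is attached as ``recording``.
    """

    stimulated_unit: str
    trial_onsets: np.ndarray
    pulse_strength: float = 10.0
    pulse_duration: float = 1.0
    window: float = 2.0
    recording: EnsembleTimeSeries | None = None

    def __post_init__(self) -> None:
        self.trial_onsets = np.sort(np.asarray(self.trial_onsets, dtype=float))
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if len(self.trial_onsets) == 0:
            raise ValueError("at least one trial onset required")
        min_gap = self.pulse_duration + 2 * self.window
        gaps = np.diff(self.trial_onsets)
        bad = np.nonzero(gaps < min_gap)[0]
        if bad.size:
            raise ValueError(
                f"overlapping trials after padding by pulse_duration + 2*window: "
                f"onsets at {self.trial_onsets[bad].tolist()} are closer than {min_gap}"
            )

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)


@dataclass
class DelayMatrix:
    """Takens delay-coordinate embedding of one scalar series.

    Row ``r`` is the delay vector
    ``X(t) = [x(t), x(t - tau), ..., x(t - (d-1)*tau)]`` at ``t = t_index[r]``
    (0-based sample index into the source series).
    """

    values: np.ndarray
    d: int
    tau: int
    t_index: np.ndarray

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def theiler(self) -> int:
        """Temporal-exclusion window: the span of one delay vector."""
        return (self.d - 1) * self.tau


def validate_directed_matrix(values: np.ndarray, sig_mask: np.ndarray, unit_ids: Sequence[str]) -> None:
    """Shared validator for the rows=targets / columns=sources convention."""
    values = np.asarray(values)
    sig_mask = np.asarray(sig_mask)
    n = len(unit_ids)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} unit ids")
    if sig_mask.shape != values.shape:
        raise ValueError("sig_mask shape does not match values")
    if sig_mask.dtype != bool:
        raise ValueError("sig_mask must be boolean")
    if np.any(sig_mask & ~np.isfinite(values)):
        raise ValueError("sig_mask must be False wherever values are missing")


@dataclass
class _DirectedMatrix:
    values: np.ndarray
    unit_ids: list[str]
    sig_mask: np.ndarray = None  # type: ignore[assignment]
    pvals: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unit_ids = [str(u) for u in self.unit_ids]
        if self.sig_mask is None:
            self.sig_mask = np.zeros_like(self.values, dtype=bool)
        self.sig_mask = np.asarray(self.sig_mask, dtype=bool)
        validate_directed_matrix(self.values, self.sig_mask, self.unit_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n_units, dtype=bool)

    def column(self, source_id: str) -> np.ndarray:
        return self.values[:, self.unit_ids.index(str(source_id))]


@dataclass
class CFMatrix(_DirectedMatrix):
    """Causal-flow matrix: ``values[i, j]`` is the cross-validated Fisher-z
    accuracy of reconstructing source ``j``'s series from target ``i``'s delay
    embedding; column ``j`` is the CF vector ``f^(j)``. Diagonal is NaN."""


@dataclass
class ICMatrix(_DirectedMatrix):
    """Interventional connectivity: ``values[i, j]`` is the KS statistic
    between target ``i``'s pre- and post-stimulation window activity when
    source ``j`` is stimulated; column ``j`` is the perturbation vector
    ``s^(j)``. Columns of unstimulated sources are NaN."""

    n_trials: dict = field(default_factory=dict)
    window: float = 0.2


@dataclass
class BaselineMatrix(_DirectedMatrix):
    """Directed scores from an information-based estimator (GC/MGC/EGC/NGC/TE),
    same orientation as :class:`CFMatrix`."""

    method: str = ""


@dataclass
class ArrayGeometry:
    """Unit positions on a (synthetic) electrode array, in pitch units."""

    unit_ids: list[str]
    coordinates: np.ndarray
    pitch: float = 1.0

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.unit_ids), 2):
            raise ValueError("coordinates must be (n_units, 2)")
        if len({tuple(c) for c in self.coordinates.tolist()}) != len(self.unit_ids):
            raise ValueError("unit coordinates must be unique")

    def distance_matrix(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff**2).sum(axis=2)) * self.pitch


@dataclass
class TwinSet:
    """Partition of embedded states into twin classes (identical neighbor sets
    at the chosen recurrence radius)."""

    neighbor_radius: float
    class_of: np.ndarray  # state index -> class id
    classes: list[np.ndarray]  # class id -> member state indices

    @property
    def n_per_class(self) -> np.ndarray:
        return np.array([len(c) for c in self.classes])

    @property
    def n_states(self) -> int:
        return len(self.class_of)


@dataclass
class SurrogateEnsemble:
    """Stack of twin-surrogate series (each re-threads the original trajectory,
    so every surrogate value occurs in the original series)."""

    series: np.ndarray  # (n_surrogates, length)
    seeds: list[int]
    params: dict = field(default_factory=dict)

    @property
    def n_surrogates(self) -> int:
        return self.series.shape[0]
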