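"""Synthetic spine datasets and intrinsic-signal recordings with known truth.

The generators emulate the statistical structure of the two imaging
modalities so that every analysis stage has an exercisable input with known
ground truth:

* ``simulate_spine_dataset`` builds dendritic segments as 1-D paths carrying
  spines placed by a Poisson process thinned to a hard-core minimum spacing,
  log-normally distributed baseline sizes, per-session additions and
  eliminations, a spatially correlated field of true size changes, and
  multiplicative log-normal measurement noise on the intensity triplets.
* ``simulate_clustered_changes`` draws the change field itself: marginally
  Normal(global_shift, change_sd^2), with the correlation between adjacent
  spines set by ``neighbor_rho``.  The default mechanism is a first-order
  autoregression along the position order (lag-1 correlation equals
  ``neighbor_rho`` exactly); a squared-exponential Gaussian-process
  alternative with a length scale mapped from ``neighbor_rho`` at the mean
  adjacent spacing is selectable for distance-aware correlation.
* ``simulate_isi_recording`` builds a pixel-grid movie whose every pixel
  oscillates at the stimulus frequency,
  ``amp(i,j) * cos(2*pi*f*t + phase(i,j))``, with a retinotopic phase
  gradient along rows, plus a slow linear drift and white noise.

Randomness: one root seed; per-dendrite substreams are spawned from it so
datasets are bit-identical for a given configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spines import DendriteSegment, SpineDataset, SpineTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SpineSimConfig",
    "ISISimConfig",
    "GeometryError",
    "simulate_clustered_changes",
    "simulate_spine_dataset",
    "simulate_isi_recording",
    "gaussian_amp_map",
]

#: Nominal background and net-shaft camera counts used to synthesize the
#: intensity triplets.  Only their ratio structure matters: the
#: shaft-normalized size recovers the true size exactly at zero noise.
_BACKGROUND_LEVEL = 100.0
_SHAFT_NET_LEVEL = 1000.0

#: True changes are clipped to this magnitude before being converted to
#: post-manipulation sizes, so the implied size stays finite.  At the default
#: change_sd this is a >4.9-sigma event.
_MAX_ABS_CHANGE = 0.99


class GeometryError(RuntimeError):
    """Spine placement infeasible: requested rate and spacing cannot coexist."""


@dataclass
class SpineSimConfig:
    """Study conditions for the spine-dataset generator.

    The default schedule mirrors an every-other-day imaging design around a
    manipulation between day 0 and day 1: sessions on days -3..4 with
    baseline days -3..0.  Rates are per session transition.  ``neighbor_rho``
    is the lag-1 correlation of true changes between adjacent spines;
    ``noise_cv`` the coefficient of variation of the multiplicative
    measurement noise applied to the net spine and shaft intensities.
    """

    n_dendrites: int = 100
    dendrite_length: float = 20.0
    spine_rate: float = 0.4
    min_spacing: float = 0.5
    sessions: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3, 4)
    baseline_sessions: tuple[int, ...] = (-3, -2, -1, 0)
    addition_rate: float = 0.05
    elimination_rate: float = 0.05
    size_log_mean: float = 0.0
    size_log_sd: float = 0.5
    global_shift: float = 0.0
    change_sd: float = 0.2
    neighbor_rho: float = 0.0
    noise_cv: float = 0.05
    mechanism: str = "ar1"
    seed: int = 0

    def __post_init__(self):
        self.sessions = tuple(int(s) for s in self.sessions)
        self.baseline_sessions = tuple(int(s) for s in self.baseline_sessions)
        if self.n_dendrites < 1:
            raise ValueError("n_dendrites must be >= 1")
        if self.dendrite_length <= 0:
            raise ValueError("dendrite_length must be positive")
        if self.spine_rate < 0:
            raise ValueError("spine_rate must be non-negative")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be non-negative")
        if len(self.sessions) < 2:
            raise ValueError("need at least two sessions")
        if not self.baseline_sessions:
            raise ValueError("need at least one baseline session")
        if self.sessions[: len(self.baseline_sessions)] != self.baseline_sessions:
            raise ValueError("baseline sessions must be a prefix of sessions")
        for name in ("addition_rate", "elimination_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.neighbor_rho <= 1:
            raise ValueError("neighbor_rho must lie in [0, 1]")
        if self.change_sd < 0 or self.noise_cv < 0 or self.size_log_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.mechanism not in ("ar1", "gp"):
            raise ValueError("mechanism must be 'ar1' or 'gp'")


@dataclass
class ISISimConfig:
    """Study conditions for the intrinsic-signal movie generator.

    Frame rate defaults to 7.5 Hz (30 Hz acquisition binned by four frames);
    the periodic bar stimulus repeats at ``stim_freq`` (default one sweep per
    8 s).  ``contra_amp_map`` / ``ipsi_amp_map`` are per-pixel response
    amplitudes in dR/R units; ``phase_gradient`` (radians per pixel row) sets
    the retinotopic phase progression.
    """

    grid_height: int = 64
    grid_width: int = 64
    frame_rate: float = 7.5
    n_cycles: int = 15
    stim_freq: float = 0.125
    contra_amp_map: np.ndarray | None = None
    ipsi_amp_map: np.ndarray | None = None
    phase_gradient: float = 0.02
    phase_offset: float = 0.0
    noise_sd: float = 0.0
    drift_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.stim_freq >= self.frame_rate / 2:
            raise ValueError("stim_freq must be below the Nyquist frequency")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        shape = (self.grid_height, self.grid_width)
        if self.contra_amp_map is None:
            self.contra_amp_map = gaussian_amp_map(*shape, peak=3e-4)
        if self.ipsi_amp_map is None:
            self.ipsi_amp_map = gaussian_amp_map(*shape, peak=1.5e-4)
        self.contra_amp_map = np.asarray(self.contra_amp_map, dtype=float)
        self.ipsi_amp_map = np.asarray(self.ipsi_amp_map, dtype=float)
        for name, amp in (
            ("contra_amp_map", self.contra_amp_map),
            ("ipsi_amp_map", self.ipsi_amp_map),
        ):
            if amp.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            if np.any(amp < 0):
                raise ValueError(f"{name} must be non-negative")


def gaussian_amp_map(height, width, peak=3e-4, center=None, sigma=None):
    """Smooth single-blob amplitude map (a stand-in responsive region)."""
    if center is None:
        center = ((height - 1) / 2, (width - 1) / 2)
    if sigma is None:
        sigma = min(height, width) / 4
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return peak * np.exp(-d2 / (2 * sigma**2))


def simulate_clustered_changes(
    positions, config: SpineSimConfig, rng=None
) -> np.ndarray:
    """True size changes along one dendrite, spatially correlated.

    ``positions`` must be sorted ascending.  Values are marginally
    Normal(global_shift, change_sd^2).  With the default AR(1) mechanism the
    correlation between consecutive spines (in position order) is exactly
    ``neighbor_rho``; with ``mechanism="gp"`` a squared-exponential kernel is
    used whose length scale reproduces ``neighbor_rho`` at the mean adjacent
    spacing, so correlation decays with actual distance.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        return np.zeros(0)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = positions.size
    rho = config.neighbor_rho
    if rho >= 1.0:  # degenerate cap: one shared value per dendrite
        z = np.full(n, rng.standard_normal())
    elif config.mechanism == "ar1" or rho == 0.0:
        z = np.empty(n)
        z[0] = rng.standard_normal()
        innovations = rng.standard_normal(n - 1)
        scale = np.sqrt(1 - rho**2)
        for k in range(1, n):
            z[k] = rho * z[k - 1] + scale * innovations[k - 1]
    else:
        spacings = np.diff(positions)
        mean_gap = float(spacings.mean()) if spacings.size else 1.0
        if mean_gap <= 0:
            mean_gap = 1.0
        length_scale = mean_gap / np.sqrt(-2.0 * np.log(rho))
        d = positions[:, None] - positions[None, :]
        cov = np.exp(-(d**2) / (2 * length_scale**2))
        cov[np.diag_indices(n)] += 1e-10  # jitter for Cholesky stability
        z = np.linalg.cholesky(cov) @ rng.standard_normal(n)
    return config.global_shift + config.change_sd * z


def _place_positions(rng, length, rate, min_spacing):
    """Poisson-count placement with hard-core thinning.

    Draws a Poisson(rate * length) target count, then inserts uniform
    positions sequentially, rejecting candidates closer than ``min_spacing``
    to an accepted spine.  Fails explicitly when the geometry cannot
    accommodate the drawn count within a bounded number of attempts.
    """
    target = int(rng.poisson(rate * length))
    if target == 0:
        return np.zeros(0)
    if min_spacing > 0 and (target - 1) * min_spacing >= length:
        raise GeometryError(
            f"cannot place {target} spines with spacing >= {min_spacing} um "
            f"on a {length} um segment"
        )
    accepted: list[float] = []
    attempts = 0
    max_attempts = 200 * target + 200
    while len(accepted) < target:
        if attempts >= max_attempts:
            raise GeometryError(
                f"placed only {len(accepted)}/{target} spines after "
                f"{max_attempts} attempts; spine_rate x min_spacing too high"
            )
        candidate = float(rng.uniform(0, length))
        attempts += 1
        if all(abs(candidate - p) >= min_spacing for p in accepted):
            accepted.append(candidate)
    return np.sort(np.asarray(accepted))


def _noise_factors(rng, cv, size):
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _change_to_size_ratio(delta):
    """Post/baseline size ratio implied by a bounded change value."""
    return (1.0 + delta) / (1.0 - delta)


def simulate_spine_dataset(config: SpineSimConfig) -> SpineDataset:
    """Generate a full longitudinal spine dataset.

    Initial spines are present at the first session; at every session
    transition each present spine is eliminated with ``elimination_rate`` and
    Binomial(n_present, addition_rate) new spines appear at fresh positions
    respecting the hard-core spacing.  Eliminated spines stay absent
    (re-addition is off).  Initial-cohort spines carry a true change value
    from the correlated field; their post-manipulation true size is
    ``baseline * (1 + delta) / (1 - delta)`` so the bounded change score of a
    noiseless measurement recovers ``delta`` exactly.  Spines added during
    the experiment have no defined change (they cannot be persistent).
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_dendrites)
    n_sessions = len(config.sessions)
    n_baseline = len(config.baseline_sessions)
    dendrites = []
    for d_index, child in enumerate(children):
        rng = np.random.default_rng(child)
        positions = _place_positions(
            rng, config.dendrite_length, config.spine_rate, config.min_spacing
        )
        changes = simulate_clustered_changes(positions, config, rng)
        changes = np.clip(changes, -_MAX_ABS_CHANGE, _MAX_ABS_CHANGE)
        spines = []
        next_id = 0
        for pos, delta in zip(positions, changes):
            base = float(
                rng.lognormal(config.size_log_mean, config.size_log_sd)
            )
            true_size = np.empty(n_sessions)
            true_size[:n_baseline] = base
            true_size[n_baseline:] = base * _change_to_size_ratio(delta)
            spines.append(
                {
                    "id": next_id,
                    "position": float(pos),
                    "present": np.zeros(n_sessions, dtype=bool),
                    "true_size": true_size,
                    "true_change": float(delta),
                }
            )
            spines[-1]["present"][0] = True
            next_id += 1
        for k in range(1, n_sessions):
            alive = [s for s in spines if s["present"][k - 1]]
            for s in alive:
                if rng.random() < config.elimination_rate:
                    continue  # eliminated: stays absent from session k on
                s["present"][k] = True
            n_added = (
                int(rng.binomial(len(alive), config.addition_rate))
                if alive
                else 0
            )
            for _ in range(n_added):
                occupied = [
                    s["position"] for s in spines if s["present"][k]
                ]
                placed = None
                for _attempt in range(200):
                    candidate = float(rng.uniform(0, config.dendrite_length))
                    if all(
                        abs(candidate - p) >= config.min_spacing
                        for p in occupied
                    ):
                        placed = candidate
                        break
                if placed is None:
                    logger.debug(
                        "dendrite %d day %s: no room for an added spine",
                        d_index, config.sessions[k],
                    )
                    continue
                base = float(
                    rng.lognormal(config.size_log_mean, config.size_log_sd)
                )
                present = np.zeros(n_sessions, dtype=bool)
                present[k] = True
                spines.append(
                    {
                        "id": next_id,
                        "position": placed,
                        "present": present,
                        "true_size": np.full(n_sessions, base),
                        "true_change": float("nan"),
                    }
                )
                next_id += 1
        trajectories = []
        for s in spines:
            present = s["present"]
            spine_noise = _noise_factors(rng, config.noise_cv, n_sessions)
            shaft_noise = _noise_factors(rng, config.noise_cv, n_sessions)
            spine_int = np.full(n_sessions, np.nan)
            shaft_int = np.full(n_sessions, np.nan)
            bg_int = np.full(n_sessions, np.nan)
            idx = np.flatnonzero(present)
            spine_int[idx] = (
                _BACKGROUND_LEVEL
                + s["true_size"][idx] * _SHAFT_NET_LEVEL * spine_noise[idx]
            )
            shaft_int[idx] = (
                _BACKGROUND_LEVEL + _SHAFT_NET_LEVEL * shaft_noise[idx]
            )
            bg_int[idx] = _BACKGROUND_LEVEL
            true_size = s["true_size"].copy()
            true_size[~present] = np.nan
            trajectories.append(
                SpineTrajectory(
                    id=s["id"],
                    position=s["position"],
                    present=present,
                    spine_intensity=spine_int,
                    shaft_intensity=shaft_int,
                    background_intensity=bg_int,
                    true_size=true_size,
                    true_change=s["true_change"],
                )
            )
        dendrites.append(
            DendriteSegment(
                id=d_index,
                length=config.dendrite_length,
                spines=trajectories,
            )
        )
    return SpineDataset(
        dendrites=dendrites,
        sessions=config.sessions,
        baseline_sessions=config.baseline_sessions,
    )


def simulate_isi_recording(config: ISISimConfig, eye: str = "contra", rng=None):
    """Generate an intrinsic-signal movie for one eye.

    Returns an :class:`spinisi.isi.ISIRecording` whose frames span an integer
    number of stimulus cycles:
    ``frame[t, i, j] = amp(i, j) * cos(2 pi f t + phase(i, j)) + drift + noise``
    with ``phase(i, j) = phase_offset + phase_gradient * i`` (retinotopy along
    rows) and a linear drift spanning ``drift_amp`` over the recording.  The
    ground-truth amplitude and phase maps travel with the recording.
    """
    from .isi import ISIRecording, wrap_phase

    if eye not in ("contra", "ipsi"):
        raise ValueError("eye must be 'contra' or 'ipsi'")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0 if eye == "contra" else 1])
        )
    frames_per_cycle = config.frame_rate / config.stim_freq
    n_frames = int(round(config.n_cycles * frames_per_cycle))
    if abs(n_frames - config.n_cycles * frames_per_cycle) > 1.0:
        raise ValueError(
            "recording cannot span whole stimulus cycles: "
            f"{config.n_cycles} cycles x {frames_per_cycle} frames/cycle "
            "is more than one frame from an integer"
        )
    amp = (
        config.contra_amp_map if eye == "contra" else config.ipsi_amp_map
    )
    height, width = amp.shape
    phase = wrap_phase(
        config.phase_offset
        + config.phase_gradient * np.arange(height)[:, None]
        + np.zeros((1, width))
    )
    t = np.arange(n_frames) / config.frame_rate
    oscillation = np.cos(
        2 * np.pi * config.stim_freq * t[:, None, None] + phase[None, :, :]
    )
    frames = amp[None, :, :] * oscillation
    if config.drift_amp:
        ramp = config.drift_amp * (t / t[-1] - 0.5)
        frames = frames + ramp[:, None, None]
    if config.noise_sd:
        frames = frames + rng.normal(
            0.0, config.noise_sd, size=frames.shape
        )
    return ISIRecording(
        frames=frames,
        frame_rate=config.frame_rate,
        stim_freq=config.stim_freq,
        eye=eye,
        truth_amplitude=amp.copy(),
        truth_phase=phase,
    )
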