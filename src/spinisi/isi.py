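"""Intrinsic-signal imaging: periodic-response extraction and ocular dominance.

A periodic visual stimulus (a bar sweeping the screen) drives a reflectance
oscillation at the stimulus frequency in responsive cortex.  Per pixel, the
amplitude and phase of that oscillation are extracted at the DFT bin nearest
the stimulus frequency, fitted jointly with an intercept and a linear drift
term; on a cycle-aligned recording of a pure cosine of amplitude A the
estimator returns exactly A, with phase equal to the cosine phase.

Ocular dominance is quantified within a binocular region of interest derived
from the ipsilateral-eye response map: the map is smoothed with a 5x5 uniform
kernel and thresholded at 40% of its peak.  For each ROI pixel the ocular
dominance score is (C - I)/(C + I), where C and I are the response magnitudes
to contralateral- and ipsilateral-eye stimulation; the ocular dominance index
(ODI) is the mean score over the ROI.  ODI lies in [-1, +1]: positive values
mean contralateral dominance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ISIRecording",
    "ResponseMap",
    "ODResult",
    "FrequencyAlignmentError",
    "EmptyROIError",
    "wrap_phase",
    "fourier_response",
    "average_amplitude",
    "smooth_map",
    "binocular_roi",
    "ocular_dominance",
]


class FrequencyAlignmentError(ValueError):
    """Stimulus frequency falls between DFT bins: trim to whole cycles."""


class EmptyROIError(ValueError):
    """No pixel passes the ROI threshold."""


def wrap_phase(phase):
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phase, dtype=float) + np.pi, 2 * np.pi) - np.pi


@dataclass
class ISIRecording:
    """A frame stack with its acquisition metadata.

    ``frames`` has shape (n_frames, height, width); ``frame_rate`` is the
    post-binning rate in Hz and ``stim_freq`` the stimulus repetition
    frequency.  The stack must span an integer number of stimulus cycles to
    within one frame, and ``stim_freq`` must be below Nyquist.  Ground-truth
    maps (for synthetic recordings) ride along in ``truth_amplitude`` /
    ``truth_phase``.
    """

    frames: np.ndarray
    frame_rate: float
    stim_freq: float
    eye: str = "contra"
    truth_amplitude: np.ndarray | None = None
    truth_phase: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, height, width)")
        if self.stim_freq >= self.frame_rate / 2:
            raise ValueError("stim_freq must be below the Nyquist frequency")
        n = self.frames.shape[0]
        cycles = n * self.stim_freq / self.frame_rate
        frames_off = abs(cycles - round(cycles)) * self.frame_rate / self.stim_freq
        if round(cycles) < 1 or frames_off > 1.0:
            raise ValueError(
                f"stack of {n} frames spans {cycles:.3f} stimulus cycles; "
                "must cover whole cycles to within one frame"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ResponseMap:
    """Per-pixel response at the stimulus frequency.

    ``amplitude`` is non-negative, in the units of the frames (dR/R);
    ``phase`` is in radians, wrapped to [-pi, pi).
    """

    amplitude: np.ndarray
    phase: np.ndarray


def fourier_response(recording: ISIRecording) -> ResponseMap:
    """Amplitude and phase at the stimulus frequency, per pixel.

    Each pixel's time series is projected on the quadrature pair at the DFT
    bin nearest the stimulus frequency, jointly with an intercept and a
    linear trend (per-pixel detrending folded into the same least-squares
    fit).  A pure cosine of amplitude A yields exactly A, and a linear drift
    contributes nothing; on cycle-aligned data the estimator coincides with
    the ``2 |c| / n``-scaled single-bin Fourier coefficient of the detrended
    series.  If the stimulus frequency misses the bin grid by more than about
    one frame's worth of cycle, the recording must be trimmed to whole cycles
    first.
    """
    frames = recording.frames
    n = frames.shape[0]
    k_exact = recording.stim_freq * n / recording.frame_rate
    k = int(round(k_exact))
    # allow ~1.5 frames of cycle misalignment (matches the stack invariant)
    if k < 1 or abs(k_exact - k) > 1.5 * recording.stim_freq / recording.frame_rate:
        raise FrequencyAlignmentError(
            f"stimulus frequency {recording.stim_freq} Hz is "
            f"{abs(k_exact - k):.4f} bins off the DFT grid of this "
            f"{n}-frame stack; trim the recording to whole stimulus cycles"
        )
    t = np.arange(n)
    omega = 2 * np.pi * k / n
    # joint least squares of intercept, linear trend and the stimulus
    # quadrature pair: equivalent to the DFT bin with the slow-trend
    # components orthogonalized out, so a linear drift cannot leak into the
    # stimulus-frequency estimate
    design = np.column_stack(
        [np.ones(n), t - t.mean(), np.cos(omega * t), np.sin(omega * t)]
    )
    flat = frames.reshape(n, -1)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    a_cos = coef[2].reshape(frames.shape[1:])
    b_sin = coef[3].reshape(frames.shape[1:])
    amplitude = np.hypot(a_cos, b_sin)
    phase = wrap_phase(np.arctan2(-b_sin, a_cos))
    return ResponseMap(amplitude=amplitude, phase=phase)


def average_amplitude(maps) -> np.ndarray:
    """Pixel-wise mean of repeated amplitude measurements.

    Response amplitude is conventionally averaged over at least four
    measurements; fewer trigger a warning.
    """
    maps = [np.asarray(m, dtype=float) for m in maps]
    if not maps:
        raise ValueError("need at least one amplitude map")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError(
                f"amplitude maps have mismatched shapes {m.shape} vs {shape}"
            )
    if len(maps) < 4:
        warnings.warn(
            f"averaging only {len(maps)} amplitude maps (at least 4 "
            "recommended)",
            stacklevel=2,
        )
    return np.mean(maps, axis=0)


def smooth_map(amplitude_map) -> np.ndarray:
    """5x5 uniform (moving-average) low-pass filter with reflect borders."""
    amplitude_map = np.asarray(amplitude_map, dtype=float)
    if amplitude_map.ndim != 2 or min(amplitude_map.shape) < 5:
        raise ValueError("amplitude map must be 2-D and at least 5x5")
    return ndimage.uniform_filter(amplitude_map, size=5, mode="reflect")


def binocular_roi(
    ipsi_amplitude, threshold_frac: float = 0.4, presmoothed: bool = False
) -> np.ndarray:
    """Binocular ROI from the ipsilateral-eye response map.

    The map is smoothed (5x5 uniform kernel) unless ``presmoothed``, then
    thresholded at ``threshold_frac`` of its peak; boundary equality is
    included.  The mask is invariant to positive rescaling of the map.
    """
    ipsi_amplitude = np.asarray(ipsi_amplitude, dtype=float)
    if np.any(ipsi_amplitude < 0):
        raise ValueError("amplitude map must be non-negative")
    smoothed = ipsi_amplitude if presmoothed else smooth_map(ipsi_amplitude)
    peak = smoothed.max()
    if peak <= 0:
        raise EmptyROIError("all-zero response map: no ROI")
    return smoothed >= threshold_frac * peak


@dataclass
class ODResult:
    """Ocular-dominance scores over the binocular ROI.

    ``score_map`` holds (C - I)/(C + I) on ROI pixels with C + I > 0 and NaN
    elsewhere; ``odi`` is the mean score; ``n_excluded`` counts ROI pixels
    dropped because both responses were zero.
    """

    roi: np.ndarray
    score_map: np.ndarray
    odi: float
    c_mean: float
    i_mean: float
    n_roi_pixels: int
    n_excluded: int


def ocular_dominance(contra_map, ipsi_map, roi) -> ODResult:
    """Per-pixel ocular-dominance scores and their ROI average (the ODI)."""
    contra = np.asarray(contra_map, dtype=float)
    ipsi = np.asarray(ipsi_map, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if contra.shape != ipsi.shape or contra.shape != roi.shape:
        raise ValueError("contra, ipsi and roi must share one shape")
    if not roi.any():
        raise EmptyROIError("empty ROI")
    total = contra + ipsi
    valid = roi & (total > 0)
    n_excluded = int(roi.sum() - valid.sum())
    if not valid.any():
        raise EmptyROIError("no ROI pixel with a non-zero summed response")
    score_map = np.full(contra.shape, np.nan)
    score_map[valid] = (contra[valid] - ipsi[valid]) / total[valid]
    return ODResult(
        roi=roi,
        score_map=score_map,
        odi=float(np.nanmean(score_map[roi])),
        c_mean=float(contra[roi].mean()),
        i_mean=float(ipsi[roi].mean()),
        n_roi_pixels=int(roi.sum()),
        n_excluded=n_excluded,
    )
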