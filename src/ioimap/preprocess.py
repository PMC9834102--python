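"""Turn raw acquisitions into an analysis-ready reflectance sequence.

Raw intraoperative stacks arrive either as single-channel frames (568 nm
bandpass setup) or as RGB video (microscope-integrated camera), possibly
contaminated by frame-to-frame motion. This module extracts the green
channel from RGB data, compensates global translation, and removes
per-pixel linear drift prior to spectral analysis.

Coordinate convention: stacks are ``(time, rows, cols)``; masks and maps
are ``(rows, cols)`` with the origin at the top-left, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulusParadigm",
    "ReflectanceSequence",
    "extract_green_channel",
    "compensate_motion",
    "detrend_pixelwise",
]


@dataclass(frozen=True)
class StimulusParadigm:
    """Block-design stimulation paradigm: alternating rest and stimulation.

    The default paradigm is 9 cycles of 30 s rest followed by 30 s
    stimulation, imaged at 2 frames/s, which puts the stimulation
    fundamental at ``f_stim = 1/60 Hz`` and yields 1080 frames.

    Parameters
    ----------
    rest_duration, stim_duration:
        Epoch lengths in seconds; each cycle is rest followed by
        stimulation.
    cycles:
        Number of rest+stimulation repetitions in the record.
    frame_rate:
        Acquisition rate in frames per second. Must divide each cycle
        into a whole number of frames so the stimulation frequency falls
        on an exact DFT bin.
    """

    rest_duration: float = 30.0
    stim_duration: float = 30.0
    cycles: int = 9
    frame_rate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("rest_duration", "stim_duration", "frame_rate"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        fpc = self.cycle_duration * self.frame_rate
        if abs(fpc - round(fpc)) > 1e-9:
            raise ValueError(
                f"frame_rate x cycle duration = {fpc} is not a whole number of "
                "frames per cycle; choose a frame rate that divides the cycle"
            )

    @property
    def cycle_duration(self) -> float:
        """Length of one rest+stimulation cycle in seconds."""
        return self.rest_duration + self.stim_duration

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.cycle_duration * self.frame_rate))

    @property
    def total_frames(self) -> int:
        return self.cycles * self.frames_per_cycle

    @property
    def total_duration(self) -> float:
        return self.cycles * self.cycle_duration

    @property
    def f_stim(self) -> float:
        """Stimulation fundamental frequency in Hz (1/cycle duration)."""
        return 1.0 / self.cycle_duration

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    def boxcar(self) -> np.ndarray:
        """0/1 stimulus indicator per frame (1 during stimulation epochs)."""
        t = np.arange(self.total_frames) / self.frame_rate
        return ((t % self.cycle_duration) >= self.rest_duration).astype(float)


@dataclass
class ReflectanceSequence:
    """A ``(time, rows, cols)`` stack of cortical reflectance frames.

    Attributes
    ----------
    frames:
        Real-valued stack, converted to float64 on construction. Raw
        camera digitization (12-bit or 8-bit) is *not* rescaled: the
        downstream activity-map ratio is invariant to global gain.
    frame_interval:
        Seconds between consecutive frames (uniform sampling assumed).
    channel_origin:
        Provenance of the intensity values: ``filtered_568nm``,
        ``rgb_green`` or ``synthetic``.
    preprocessing_log:
        Ordered record of the steps applied to this sequence.
    """

    frames: np.ndarray
    frame_interval: float
    channel_origin: str = "synthetic"
    preprocessing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) stack")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial grid (rows, cols)."""
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray, log_entry: str) -> "ReflectanceSequence":
        return replace(
            self,
            frames=frames,
            preprocessing_log=[*self.preprocessing_log, log_entry],
        )


def extract_green_channel(
    rgb_stack: np.ndarray,
    frame_interval: float = 0.5,
) -> ReflectanceSequence:
    """Extract the green channel of an RGB stack as the reflectance signal.

    With a broadband (unfiltered) RGB camera the green channel is the
    closest available surrogate for the hemoglobin-sensitive band, so it
    carries the stimulation-locked blood-volume signal.

    Parameters
    ----------
    rgb_stack:
        ``(time, rows, cols, 3)`` array; any integer dtype accepted.
    frame_interval:
        Seconds between frames of the resulting sequence.
    """
    rgb_stack = np.asarray(rgb_stack)
    if rgb_stack.ndim != 4 or rgb_stack.shape[-1] != 3:
        raise ValueError(
            f"expected a (time, rows, cols, 3) RGB stack, got shape {rgb_stack.shape}"
        )
    return ReflectanceSequence(
        frames=rgb_stack[..., 1].astype(np.float64),
        frame_interval=frame_interval,
        channel_origin="rgb_green",
        preprocessing_log=["extract_green_channel"],
    )


def _integer_shift(frame: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    """Translate ``frame`` by (dr, dc); exposed borders take ``fill``."""
    out = np.full_like(frame, fill)
    rows, cols = frame.shape
    r_src = slice(max(0, -dr), min(rows, rows - dr))
    c_src = slice(max(0, -dc), min(cols, cols - dc))
    r_dst = slice(max(0, dr), min(rows, rows + dr))
    c_dst = slice(max(0, dc), min(cols, cols + dc))
    out[r_dst, c_dst] = frame[r_src, c_src]
    return out


def _correlation_shift(reference: np.ndarray, frame: np.ndarray) -> tuple[int, int]:
    """Integer shift maximizing circular cross-correlation with reference.

    Means are removed first so the estimate is insensitive to global
    brightness. Constant frames (zero variance) correlate equally at all
    lags; the tie is broken to (0, 0).
    """
    a = reference - reference.mean()
    b = frame - frame.mean()
    if not a.any() or not b.any():
        return (0, 0)
    corr = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape)
    flat = int(np.argmax(corr))
    dr, dc = np.unravel_index(flat, corr.shape)
    rows, cols = corr.shape
    if dr > rows // 2:
        dr -= rows
    if dc > cols // 2:
        dc -= cols
    return (int(dr), int(dc))


def compensate_motion(
    seq: ReflectanceSequence,
    reference_index: int = 0,
) -> ReflectanceSequence:
    """Rigid (integer-pixel translation) motion compensation.

    Each frame is translated by the integer shift that maximizes its
    cross-correlation with the reference frame; border pixels exposed by
    the translation are filled with that frame's median. This is a
    deliberately simple, falsifiable registration stand-in — deformable
    registration is out of scope (see the methods note), and the
    function is the extension point for plugging in anything richer.
    """
    if seq.n_frames < 2:
        raise ValueError("motion compensation needs at least 2 frames")
    if not 0 <= reference_index < seq.n_frames:
        raise ValueError(
            f"reference_index {reference_index} out of range [0, {seq.n_frames})"
        )
    reference = seq.frames[reference_index]
    out = np.empty_like(seq.frames)
    shifts: list[tuple[int, int]] = []
    for i in range(seq.n_frames):
        dr, dc = _correlation_shift(reference, seq.frames[i])
        shifts.append((dr, dc))
        if (dr, dc) == (0, 0):
            out[i] = seq.frames[i]
        else:
            out[i] = _integer_shift(
                seq.frames[i], dr, dc, float(np.median(seq.frames[i]))
            )
    log = f"compensate_motion(reference_index={reference_index}, shifts={shifts})"
    new = seq.with_frames(out, log)
    new.motion_shifts = shifts  # type: ignore[attr-defined]
    return new


def detrend_pixelwise(seq: ReflectanceSequence) -> ReflectanceSequence:
    """Subtract the per-pixel least-squares linear trend (incl. mean).

    Slow monotone drift (illumination, physiology) otherwise leaks
    broadband power into the very-low-frequency band and biases the
    vasomotion denominator of the activity map. Components at exact DFT
    bins over whole cycles are orthogonal to the linear trend, so the
    stimulation-locked signal is untouched.
    """
    if seq.n_frames < 3:
        raise ValueError("detrending needs at least 3 frames")
    n = seq.n_frames
    t = np.arange(n, dtype=np.float64)
    t -= t.mean()
    flat = seq.frames.reshape(n, -1)
    mean = flat.mean(axis=0)
    slope = (t @ flat) / (t @ t)
    detrended = flat - mean[None, :] - t[:, None] * slope[None, :]
    return seq.with_frames(
        detrended.reshape(seq.frames.shape), "detrend_pixelwise"
    )
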