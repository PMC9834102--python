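"""Seeded synthetic cortical-reflectance sequences with known ground truth.

Generates image stacks that mimic what an intraoperative camera sees over
an exposed cortex during a block-design stimulation paradigm: a baseline
reflectance, a stimulation-locked fractional decrease inside a true
activation region (blood-volume increase absorbs more light at the
hemoglobin-sensitive wavelength), shared slow vasomotion oscillations
below 0.04 Hz, a slow linear drift, white noise, and optional global
frame-to-frame motion. Truth masks (trepanation window, primary sensory
cortex band, activation ellipse) come back alongside the stack so every
downstream stage can be scored against a known answer.

All masks are synthetic stand-ins for the manual intraoperative
segmentations that real data would provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import ReflectanceSequence, StimulusParadigm

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_sequence",
    "simulate_rgb_sequence",
    "somatotopic_configs",
]

VLF_LIMIT_HZ = 0.04


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that defines one synthetic acquisition.

    Parameters
    ----------
    grid_rows, grid_cols:
        Spatial size of the simulated field of view in pixels.
    frame_rate:
        Frames per second; must divide the paradigm cycle into whole
        frames.
    paradigm:
        Rest/stimulation block design; default 9 cycles of 30 s + 30 s.
    baseline_level:
        Mean reflectance in arbitrary camera units (> 0). Default 128 so
        8-bit quantization of the RGB path is well inside range.
    activation_amplitude:
        Fractional reflectance change at the stimulation plateau inside
        the activation region. Negative for a blood-volume increase
        (more absorption); default -0.02, i.e. a 2 % decrease.
    response_delay:
        Hemodynamic onset lag in seconds before the response starts.
    response_tau:
        Time constant (s) of the exponential rise/decay of the response.
    vasomotion_components:
        ``(frequency_hz, fractional_amplitude, phase_rad)`` triples; all
        frequencies must lie below 0.04 Hz. Shared across all pixels, as
        vasomotion is a global vascular rhythm.
    noise_sd:
        Fractional SD of i.i.d. white noise per pixel per frame.
    drift_slope:
        Fractional reflectance change per minute, linear in time.
    motion_max_shift:
        Maximum absolute per-frame global translation in pixels (integer
        shifts drawn uniformly); 0 disables motion.
    seed:
        Single integer governing all randomness; fixed seed gives
        byte-identical output.

    Mask geometry (all in pixels / radians): the trepanation is a
    centered disc, the sensory-cortex band an oblique strip through it,
    and the activation an ellipse centered on the band, offset along it
    by ``activation_offset``.
    """

    grid_rows: int = 128
    grid_cols: int = 128
    frame_rate: float = 2.0
    paradigm: StimulusParadigm = field(default_factory=StimulusParadigm)
    baseline_level: float = 128.0
    activation_amplitude: float = -0.02
    response_delay: float = 2.0
    response_tau: float = 5.0
    vasomotion_components: tuple[tuple[float, float, float], ...] = (
        (0.008, 0.005, 0.0),
        (0.015, 0.005, 1.1),
        (0.030, 0.005, 2.3),
    )
    noise_sd: float = 0.005
    drift_slope: float = 0.002
    motion_max_shift: int = 0
    seed: int = 0
    trepanation_radius_frac: float = 0.42
    band_angle_rad: float = 0.5
    band_width: float = 16.0
    activation_offset: float = 0.0
    activation_semi_along: float = 12.0
    activation_semi_across: float = 6.0

    def __post_init__(self) -> None:
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ValueError("grid must be at least 4 x 4 pixels")
        if not self.baseline_level > 0:
            raise ValueError("baseline_level must be > 0")
        for name in ("activation_amplitude", "noise_sd", "drift_slope"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.motion_max_shift < 0:
            raise ValueError("motion_max_shift must be >= 0")
        for f, amp, _phase in self.vasomotion_components:
            if not f < VLF_LIMIT_HZ:
                raise ValueError(
                    f"vasomotion frequency {f} Hz is not below {VLF_LIMIT_HZ} Hz"
                )
            if amp < 0:
                raise ValueError("vasomotion amplitude must be >= 0")
        if self.frame_rate != self.paradigm.frame_rate:
            raise ValueError(
                "frame_rate must match paradigm.frame_rate "
                f"({self.frame_rate} != {self.paradigm.frame_rate})"
            )
        # StimulusParadigm already rejects non-integer frames per cycle.


@dataclass
class SimulationTruth:
    """Ground-truth masks and amplitude field for one simulated run.

    ``activation_mask`` marks where the stimulation-locked signal was
    injected; ``psc_mask`` and ``trepanation_mask`` are the synthetic
    sensory-cortex band and craniotomy window. Nesting
    activation ⊆ psc ⊆ trepanation always holds.
    """

    activation_mask: np.ndarray
    trepanation_mask: np.ndarray
    psc_mask: np.ndarray
    injected_amplitude_map: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.activation_mask.shape,
            self.trepanation_mask.shape,
            self.psc_mask.shape,
            self.injected_amplitude_map.shape,
        }
        if len(shapes) != 1:
            raise ValueError("truth masks must share one spatial grid")
        if np.any(self.activation_mask & ~self.psc_mask):
            raise ValueError("activation_mask must be contained in psc_mask")
        if np.any(self.psc_mask & ~self.trepanation_mask):
            raise ValueError("psc_mask must be contained in trepanation_mask")


def make_truth_masks(config: SimulationConfig) -> SimulationTruth:
    """Build trepanation disc, oblique PSC band and activation ellipse."""
    rows, cols = config.grid_rows, config.grid_cols
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    cr, ccol = (rows - 1) / 2.0, (cols - 1) / 2.0
    dr, dc = rr - cr, cc - ccol

    radius = config.trepanation_radius_frac * min(rows, cols)
    trepanation = dr**2 + dc**2 <= radius**2

    # Band direction u and its normal n; the band is |proj onto n| < w/2.
    u = np.array([np.sin(config.band_angle_rad), np.cos(config.band_angle_rad)])
    n = np.array([-u[1], u[0]])
    along = dr * u[0] + dc * u[1]
    across = dr * n[0] + dc * n[1]
    psc = (np.abs(across) <= config.band_width / 2.0) & trepanation

    ea = along - config.activation_offset
    activation = (
        (ea / config.activation_semi_along) ** 2
        + (across / config.activation_semi_across) ** 2
    ) <= 1.0
    activation &= psc

    amplitude_map = np.where(activation, config.activation_amplitude, 0.0)
    return SimulationTruth(
        activation_mask=activation,
        trepanation_mask=trepanation,
        psc_mask=psc,
        injected_amplitude_map=amplitude_map,
    )


def hemodynamic_response(config: SimulationConfig) -> np.ndarray:
    """Per-frame response weight in [0, 1]: delayed exponential follower.

    The stimulus boxcar, delayed by ``response_delay``, drives a
    first-order low-pass with time constant ``response_tau`` (exact
    exponential stepping, so the plateau saturates at 1 when the
    stimulation epoch is long compared to tau).
    """
    paradigm = config.paradigm
    n = paradigm.total_frames
    t = np.arange(n) / config.frame_rate
    shifted = t - config.response_delay
    boxcar = np.where(
        shifted >= 0,
        ((shifted % paradigm.cycle_duration) >= paradigm.rest_duration).astype(float),
        0.0,
    )
    decay = np.exp(-1.0 / (config.frame_rate * config.response_tau))
    response = np.empty(n)
    level = 0.0
    for i in range(n):
        level = boxcar[i] + (level - boxcar[i]) * decay
        response[i] = level
    return response


def _global_signals(config: SimulationConfig) -> np.ndarray:
    """Shared vasomotion + drift fractional signal per frame."""
    n = config.paradigm.total_frames
    t = np.arange(n) / config.frame_rate
    signal = np.zeros(n)
    for f, amp, phase in config.vasomotion_components:
        signal += amp * np.sin(2.0 * np.pi * f * t + phase)
    signal += config.drift_slope * (t / 60.0)
    return signal


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_sequence(
    config: SimulationConfig,
) -> tuple[ReflectanceSequence, SimulationTruth]:
    """Simulate one single-channel acquisition.

    Inside the activation mask the reflectance follows
    ``baseline * (1 + amplitude * response(t) + vasomotion(t) + drift(t))``
    plus white noise; outside, the stimulation term is absent. Returns
    the stack and the ground truth.
    """
    truth = make_truth_masks(config)
    paradigm = config.paradigm
    n = paradigm.total_frames
    rows, cols = config.grid_rows, config.grid_cols

    response = hemodynamic_response(config)
    shared = _global_signals(config)
    frames = config.baseline_level * (
        1.0
        + truth.injected_amplitude_map[None, :, :] * response[:, None, None]
        + shared[:, None, None]
    )
    rng = _rng(config.seed, 0)
    if config.noise_sd > 0:
        frames = frames + rng.normal(
            0.0, config.noise_sd * config.baseline_level, size=(n, rows, cols)
        )
    if config.motion_max_shift > 0:
        m = config.motion_max_shift
        shifts = rng.integers(-m, m + 1, size=(n, 2))
        from .preprocess import _integer_shift

        for i in range(n):
            dr, dc = int(shifts[i, 0]), int(shifts[i, 1])
            if (dr, dc) != (0, 0):
                frames[i] = _integer_shift(
                    frames[i], dr, dc, config.baseline_level
                )
    seq = ReflectanceSequence(
        frames=frames,
        frame_interval=1.0 / config.frame_rate,
        channel_origin="synthetic",
        preprocessing_log=[f"simulate_sequence(seed={config.seed})"],
    )
    return seq, truth


def simulate_rgb_sequence(
    config: SimulationConfig,
    quantize: bool = True,
) -> tuple[np.ndarray, SimulationTruth]:
    """Simulate an RGB acquisition (time, rows, cols, 3).

    The green channel carries the simulated reflectance — quantized to
    8 bit when ``quantize`` is on, mirroring per-channel 8-bit camera
    digitization — while red and blue carry the baseline plus
    independent noise only. With quantization off the green channel is
    bit-identical to :func:`simulate_sequence` output.
    """
    seq, truth = simulate_sequence(config)
    n, rows, cols = seq.frames.shape
    rng = _rng(config.seed, 1)
    rb = config.baseline_level + rng.normal(
        0.0, config.noise_sd * config.baseline_level, size=(n, rows, cols, 2)
    )
    stack = np.empty((n, rows, cols, 3), dtype=np.float64)
    stack[..., 0] = rb[..., 0]
    stack[..., 1] = seq.frames
    stack[..., 2] = rb[..., 1]
    if quantize:
        stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    return stack, truth


def somatotopic_configs(
    base: SimulationConfig,
    n_sites: int = 3,
    spacing: float | None = None,
) -> list[SimulationConfig]:
    """Configs for ``n_sites`` disjoint activation sites along the band.

    Emulates stimulating different body parts (leg, arm, hand, ...):
    each site is an activation ellipse at a distinct position along the
    sensory-cortex band, in order, sharing every other parameter. Used
    to exercise topographic composition against a known somatotopic
    ordering.
    """
    if spacing is None:
        spacing = 2.4 * base.activation_semi_along
    offsets = (np.arange(n_sites) - (n_sites - 1) / 2.0) * spacing
    return [replace(base, activation_offset=float(off)) for off in offsets]
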