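"""Pixelwise spectral activity mapping.

The core statistic of the pipeline: every pixel's time course is Fourier
transformed, the one-sided power at the stimulation fundamental
(``f_stim``, 1/60 Hz for 30 s + 30 s blocks) forms the map ``P_s``, the
summed power over the very-low-frequency vasomotion band (0 < f <
0.04 Hz, excluding DC and the stimulation bin) forms ``P_VLF``, and the
activity map is the per-pixel ratio ``P_s / P_VLF`` — the
stimulation-locked power expressed relative to the vasomotor background.

Power normalization
-------------------
One-sided power at bin k is ``s_k |X_k|^2 / N`` where ``X`` is the
unnormalized DFT of the N-frame trace and ``s_k`` is 2 for interior bins
(folding in the negative frequencies) and 1 for DC and Nyquist. Under
this convention the summed non-DC one-sided power equals ``N`` times the
trace's population variance (Parseval), and a pure sinusoid of amplitude
``a`` on an exact bin carries power ``a^2 N / 2``. The ratio map is
independent of the normalization constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ReflectanceSequence, StimulusParadigm

__all__ = [
    "PixelwiseSpectrum",
    "ActivityMap",
    "power_spectrum_pixelwise",
    "compute_activity_map",
]


@dataclass
class PixelwiseSpectrum:
    """One-sided per-pixel spectrum: ``power[k, r, c]`` at ``freqs[k]``.

    ``power`` holds |DFT|^2-based one-sided power under the documented
    normalization (or |DFT|-based amplitude when ``mode='amplitude'``).
    The DC bin (k = 0) is reported but carries mean brightness, not
    physiology — it is flagged so consumers exclude it.
    """

    power: np.ndarray
    freqs: np.ndarray
    n_frames: int
    frame_interval: float
    mode: str = "power"
    dc_bin_flagged: bool = True


@dataclass
class ActivityMap:
    """The P_s / P_VLF ratio map with its constituents and band metadata.

    ``ratio = p_s / p_vlf`` wherever ``p_vlf > 0``; pixels with zero
    vasomotion power get ratio 0 and are counted in
    ``n_zero_vlf_pixels``. ``excluded_bins`` lists the frequency-bin
    indices removed from the VLF sum (always DC; the stimulation bin
    ± 1 guard bin when exclusion is on).
    """

    ratio: np.ndarray
    p_s: np.ndarray
    p_vlf: np.ndarray
    f_stim: float
    vlf_band: tuple[float, float]
    excluded_bins: list[int]
    stim_bin: int
    n_zero_vlf_pixels: int = 0
    mode: str = "power"


def _one_sided_scale(n: int) -> np.ndarray:
    """Doubling factors for rfft bins: 1 at DC and (even n) Nyquist."""
    n_bins = n // 2 + 1
    scale = np.full(n_bins, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return scale


def power_spectrum_pixelwise(
    seq: ReflectanceSequence,
    mode: str = "power",
) -> PixelwiseSpectrum:
    """One-sided spectrum of every pixel's time course.

    Parameters
    ----------
    seq:
        Uniformly sampled reflectance sequence with >= 4 frames.
    mode:
        ``'power'`` (default) for one-sided power |X_k|^2-based maps, or
        ``'amplitude'`` for |X_k|-based maps (exploratory; the reported
        symbol names are powers).

    No window is applied: the record is designed to hold an integer
    number of stimulation cycles, so the stimulation component is
    bin-aligned and windowing would only smear it.
    """
    if seq.n_frames < 4:
        raise ValueError("spectral analysis needs at least 4 frames")
    if mode not in ("power", "amplitude"):
        raise ValueError(f"mode must be 'power' or 'amplitude', got {mode!r}")
    n = seq.n_frames
    fft = np.fft.rfft(seq.frames, axis=0)
    scale = _one_sided_scale(n)
    if mode == "power":
        power = scale[:, None, None] * (np.abs(fft) ** 2) / n
    else:
        power = np.sqrt(scale)[:, None, None] * np.abs(fft) / np.sqrt(n)
    freqs = np.fft.rfftfreq(n, d=seq.frame_interval)
    return PixelwiseSpectrum(
        power=power,
        freqs=freqs,
        n_frames=n,
        frame_interval=seq.frame_interval,
        mode=mode,
    )


def _stim_bin_index(n_frames: int, frame_interval: float, f_stim: float) -> int:
    """Exact DFT bin of f_stim, or a clear error with fixes suggested."""
    record = n_frames * frame_interval
    k = f_stim * record
    if abs(k - round(k)) > 1e-6 or round(k) < 1:
        lower = int(np.floor(k)) / f_stim / frame_interval
        upper = int(np.ceil(max(k, 1))) / f_stim / frame_interval
        raise ValueError(
            f"f_stim = {f_stim} Hz does not fall on an exact DFT bin for a "
            f"{n_frames}-frame record ({record} s); nearest record lengths "
            f"with whole cycles are {int(round(lower))} or {int(round(upper))} frames"
        )
    return int(round(k))


def compute_activity_map(
    seq: ReflectanceSequence,
    paradigm: StimulusParadigm,
    vlf_max: float = 0.04,
    exclude_stim_bin_from_vlf: bool = True,
    stim_guard_bins: int = 1,
    mode: str = "power",
) -> ActivityMap:
    """Compute the stimulation-to-vasomotion activity ratio map.

    ``p_s`` is the one-sided power at the stimulation bin; ``p_vlf``
    sums one-sided power over bins with 0 < f < ``vlf_max`` (half-open:
    a bin exactly at ``vlf_max`` is out), always excluding DC and, by
    default, the stimulation bin with a ±``stim_guard_bins`` guard —
    including the evoked signal in the vasomotor denominator would
    self-suppress true activations.
    """
    spectrum = power_spectrum_pixelwise(seq, mode=mode)
    k_stim = _stim_bin_index(seq.n_frames, seq.frame_interval, paradigm.f_stim)

    excluded = [0]
    vlf_sel = (spectrum.freqs > 0) & (spectrum.freqs < vlf_max)
    if exclude_stim_bin_from_vlf:
        lo = max(0, k_stim - stim_guard_bins)
        hi = min(len(spectrum.freqs) - 1, k_stim + stim_guard_bins)
        guard = list(range(lo, hi + 1))
        vlf_sel[guard] = False
        excluded.extend(g for g in guard if g != 0)

    p_s = spectrum.power[k_stim]
    p_vlf = spectrum.power[vlf_sel].sum(axis=0)
    positive = p_vlf > 0
    ratio = np.zeros_like(p_s)
    np.divide(p_s, p_vlf, out=ratio, where=positive)
    return ActivityMap(
        ratio=ratio,
        p_s=p_s,
        p_vlf=p_vlf,
        f_stim=paradigm.f_stim,
        vlf_band=(0.0, vlf_max),
        excluded_bins=sorted(set(excluded)),
        stim_bin=k_stim,
        n_zero_vlf_pixels=int(np.count_nonzero(~positive)),
        mode=mode,
    )
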