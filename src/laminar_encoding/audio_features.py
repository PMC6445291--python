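"""Sound-to-feature transforms for the two auditory encoding models.

Two feature spaces are produced from 16 kHz, 1 s waveforms:

* the *frequency* model: a time-averaged 128-channel auditory spectrogram
  (cochleogram), i.e. one energy value per log-spaced frequency channel
  between 180 and 7040 Hz (about 5.3 octaves);
* the *spectrotemporal modulation* model: modulation energy of the
  cochleogram extracted by a bank of 2-D Gabor-type filters with temporal
  rates of 1, 3, 9 and 27 Hz and spectral scales of 0.5, 1, 2 and
  4 cycles/octave, averaged over time and over 8 equal-octave frequency
  bins.  Both spaces have 128 features per sound.

The cochlear stage uses gammatone-family constant-Q magnitude filters
applied in the Fourier domain, full-wave envelope extraction with a
low-pass, 8 ms frame integration and logarithmic compression.  Full-wave
rectification makes every feature exactly invariant to sound polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import fft2, ifft2, irfft, next_fast_len, rfft, rfftfreq

DEFAULT_SAMPLE_RATE = 16_000

__all__ = [
    "CochlearFilterbankSpec",
    "Cochleogram",
    "ModulationFilterbankSpec",
    "FeatureMatrix",
    "preprocess_sound",
    "cochleogram",
    "frequency_features",
    "modulation_features",
    "build_feature_matrix",
]


class FeatureConfigError(ValueError):
    """Raised for invalid filterbank or sound configuration."""


@dataclass(frozen=True)
class CochlearFilterbankSpec:
    """First-stage (cochlear) filterbank.

    128 overlapping constant-Q bandpass channels spaced uniformly in
    log2-frequency from 180 to 7040 Hz (~5.29 octaves, reported as 5.3).
    ``bandwidth_oct`` is the half-power bandwidth of each channel in
    octaves; ``frame_step`` the spectrogram frame step in seconds;
    ``compression_floor`` the additive floor of the log compression.
    """

    n_channels: int = 128
    f_min: float = 180.0
    f_max: float = 7040.0
    frame_step: float = 0.008
    # 1/8 octave keeps spectral modulations up to the 4 cyc/oct filter
    # scale resolvable while neighbouring channels still overlap
    bandwidth_oct: float = 0.125
    compression_floor: float = 1e-4
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.f_min <= 0 or self.f_max <= self.f_min:
            raise FeatureConfigError("invalid cochlear filterbank configuration")
        if self.f_max >= self.sample_rate / 2:
            raise FeatureConfigError("f_max must lie below the Nyquist frequency")

    @property
    def octave_span(self) -> float:
        return float(np.log2(self.f_max / self.f_min))

    def center_frequencies(self) -> np.ndarray:
        """Geometric sequence of channel centre frequencies (Hz)."""
        return np.geomspace(self.f_min, self.f_max, self.n_channels)


@dataclass
class Cochleogram:
    """Frames x channels nonnegative energy matrix (auditory spectrogram)."""

    values: np.ndarray
    center_frequencies: np.ndarray
    frame_times: np.ndarray
    spec: CochlearFilterbankSpec

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ModulationFilterbankSpec:
    """Second-stage spectrotemporal modulation filterbank.

    4 temporal rates x 4 spectral scales, applied to the cochleogram in the
    2-D Fourier domain as log-Gaussian bandpass filters; outputs are summed
    into ``n_freq_bins`` equal-octave frequency bins, giving
    ``n_freq_bins * 4 * 4`` features (128 by default).
    """

    rates: Sequence[float] = (1.0, 3.0, 9.0, 27.0)
    scales: Sequence[float] = (0.5, 1.0, 2.0, 4.0)
    n_freq_bins: int = 8
    rate_sigma_log2: float = float(np.log2(3.0) / 2.0)  # half the rate spacing
    scale_sigma_log2: float = 0.5  # half the scale spacing (one octave apart)

    @property
    def n_features(self) -> int:
        return self.n_freq_bins * len(self.rates) * len(self.scales)


@dataclass
class FeatureMatrix:
    """Sounds x features representation of one model (W, S x F).

    ``labels`` is a pandas-free structure: for the frequency model a dict
    with ``cf`` (128 centre frequencies); for the modulation model a dict
    with per-feature ``bin_center_hz``, ``rate`` and ``scale`` arrays in
    bin-major order (bin, then rate ascending, then scale ascending).
    """

    values: np.ndarray
    model_tag: str
    labels: dict = field(default_factory=dict)
    sound_ids: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def preprocess_sound(
    wave: np.ndarray,
    target_rms: float = 0.05,
    ramp_s: float = 0.010,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> np.ndarray:
    """Apply 10 ms linear on/off ramps and equalise RMS energy.

    Ramping precedes scaling so the output RMS equals ``target_rms``
    exactly for every sound.  All-zero input raises ``ValueError`` since
    its RMS cannot be equalised.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    if not np.all(np.isfinite(wave)):
        raise ValueError("waveform contains non-finite samples")
    n_ramp = int(round(ramp_s * sample_rate))
    out = wave.copy()
    if n_ramp > 0:
        ramp = np.arange(n_ramp) / n_ramp  # starts at exactly 0
        out[:n_ramp] *= ramp
        out[-n_ramp:] *= ramp[::-1]
    rms = float(np.sqrt(np.mean(out**2)))
    if rms == 0.0:
        raise ValueError("cannot RMS-equalise an all-zero waveform")
    return out * (target_rms / rms)


_TRANSFER_CACHE: dict = {}


def _filter_transfer(spec: CochlearFilterbankSpec, freqs: np.ndarray) -> np.ndarray:
    """Magnitude transfer (n_channels, n_freqs) of the cochlear channels.

    Gammatone-family 4th-order magnitude response, constant-Q: the
    half-power bandwidth of each channel is ``bandwidth_oct`` octaves.
    """
    key = (spec, len(freqs), float(freqs[-1]) if len(freqs) else 0.0)
    if key in _TRANSFER_CACHE:
        return _TRANSFER_CACHE[key]
    cfs = spec.center_frequencies()
    # half-power full bandwidth in Hz per channel
    bw_hz = cfs * (2 ** (spec.bandwidth_oct / 2) - 2 ** (-spec.bandwidth_oct / 2))
    # 4th-order gammatone magnitude: |H| = (1 + u^2)^-2; power half at
    # u = sqrt(2^(1/4) - 1)
    u_half = np.sqrt(2 ** 0.25 - 1.0)
    b = (bw_hz / 2.0) / u_half
    u = (freqs[None, :] - cfs[:, None]) / b[:, None]
    out = (1.0 + u**2) ** -2
    _TRANSFER_CACHE[key] = out
    return out


def cochleogram(
    wave: np.ndarray,
    spec: CochlearFilterbankSpec | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> Cochleogram:
    """Auditory spectrogram of a mono waveform.

    Bandpass filtering in the Fourier domain, full-wave envelope
    extraction whose low-pass is the 8 ms boxcar frame integration, then
    logarithmic compression ``log1p(E / floor)`` (silence maps to 0).
    """
    spec = spec or CochlearFilterbankSpec()
    if sample_rate != spec.sample_rate:
        raise FeatureConfigError(
            f"sample rate {sample_rate} does not match filterbank "
            f"({spec.sample_rate} Hz)"
        )
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    n = wave.size
    step = int(round(spec.frame_step * sample_rate))
    n_frames = n // step
    if n_frames < 1:
        raise ValueError("waveform shorter than one frame")

    n_fft = next_fast_len(n, real=True)
    spectrum = rfft(wave, n=n_fft)
    freqs = rfftfreq(n_fft, d=1.0 / sample_rate)
    h = _filter_transfer(spec, freqs)
    subbands = irfft(spectrum[None, :] * h, n=n_fft, axis=1)[:, :n]

    # full-wave rectification (polarity invariant); the 8 ms boxcar frame
    # integration below doubles as the envelope low-pass
    env = np.abs(subbands)

    frames = env[:, : n_frames * step].reshape(spec.n_channels, n_frames, step)
    energy = frames.mean(axis=2).T  # (frames, channels)
    values = np.log1p(energy / spec.compression_floor)
    times = (np.arange(n_frames) + 0.5) * spec.frame_step
    return Cochleogram(values, spec.center_frequencies(), times, spec)


def frequency_features(coch: Cochleogram) -> np.ndarray:
    """Time-averaged spectrogram: one value per channel (128 parameters)."""
    if coch.values.size == 0:
        raise ValueError("empty cochleogram")
    return coch.values.mean(axis=0)


def _log_gaussian(f_abs: np.ndarray, center: float, sigma_log2: float) -> np.ndarray:
    """Gaussian bandpass on a log2 axis; exactly zero at f = 0."""
    out = np.zeros_like(f_abs)
    pos = f_abs > 0
    out[pos] = np.exp(-((np.log2(f_abs[pos] / center)) ** 2) / (2 * sigma_log2**2))
    return out


def channel_bins(cochlear_spec: CochlearFilterbankSpec, n_bins: int) -> np.ndarray:
    """Assign each channel to one of ``n_bins`` equal-octave frequency bins."""
    pos = np.log2(cochlear_spec.center_frequencies() / cochlear_spec.f_min)
    width = cochlear_spec.octave_span / n_bins
    return np.minimum((pos / width).astype(int), n_bins - 1)


def bin_center_frequencies(
    cochlear_spec: CochlearFilterbankSpec, n_bins: int
) -> np.ndarray:
    """Geometric centres (Hz) of the equal-octave frequency bins."""
    edges = cochlear_spec.f_min * 2 ** (
        cochlear_spec.octave_span * np.arange(n_bins + 1) / n_bins
    )
    return np.sqrt(edges[:-1] * edges[1:])


def modulation_features(
    coch: Cochleogram,
    spec: ModulationFilterbankSpec | None = None,
) -> np.ndarray:
    """Spectrotemporal modulation energy, time-averaged and frequency-binned.

    The cochleogram is mirrored in time (to limit boundary artefacts at the
    1 Hz rate on 1 s sounds) and filtered in its 2-D Fourier domain.  For
    each (rate, scale) pair the upward and downward ripple directions are
    analysed separately via their analytic (single-half-plane) responses
    and their energies averaged, making the output direction-agnostic.
    Features are ordered bin-major: (bin, rate ascending, scale ascending).
    """
    spec = spec or ModulationFilterbankSpec()
    cspec = coch.spec
    n_t, n_c = coch.values.shape
    if n_t * cspec.frame_step < 1.0 - 1e-9:
        raise ValueError(
            "cochleogram must span at least 1 s for the slowest (1 Hz) rate filter"
        )

    v = np.concatenate([coch.values, coch.values[::-1]], axis=0)  # time mirror
    nt2 = v.shape[0]
    spec2d = fft2(v)
    ft = np.fft.fftfreq(nt2, d=cspec.frame_step)  # temporal freq, Hz
    ch_spacing_oct = cspec.octave_span / (n_c - 1)
    fx = np.fft.fftfreq(n_c, d=ch_spacing_oct)  # spectral freq, cyc/oct

    sgn_t = np.sign(ft)[:, None]
    sgn_x = np.sign(fx)[None, :]
    half_t = (ft > 0).astype(float)[:, None] * 2.0  # analytic: positive rates only
    masks = [half_t * (sgn_t * sgn_x >= 0), half_t * (sgn_t * sgn_x <= 0)]

    bins = channel_bins(cspec, spec.n_freq_bins)
    bin_counts = np.bincount(bins, minlength=spec.n_freq_bins).astype(float)
    out = np.zeros((spec.n_freq_bins, len(spec.rates), len(spec.scales)))

    abs_ft = np.abs(ft)[:, None]
    abs_fx = np.abs(fx)[None, :]
    for ri, rate in enumerate(spec.rates):
        h_t = _log_gaussian(abs_ft, rate, spec.rate_sigma_log2)
        for si, scale in enumerate(spec.scales):
            h_x = _log_gaussian(abs_fx, scale, spec.scale_sigma_log2)
            h = h_t * h_x
            energy_c = np.zeros(n_c)
            for mask in masks:
                z = ifft2(spec2d * h * mask)[:n_t]  # crop the mirrored half
                energy_c += np.mean(np.abs(z) ** 2, axis=0)
            energy_c /= len(masks)
            out[:, ri, si] = np.bincount(
                bins, weights=energy_c, minlength=spec.n_freq_bins
            ) / bin_counts
    return out.reshape(-1)


def modulation_feature_labels(
    cochlear_spec: CochlearFilterbankSpec, spec: ModulationFilterbankSpec
) -> dict:
    """Per-feature (bin centre Hz, rate, scale) labels in bin-major order."""
    centers = bin_center_frequencies(cochlear_spec, spec.n_freq_bins)
    rates = np.asarray(spec.rates, dtype=float)
    scales = np.asarray(spec.scales, dtype=float)
    b, r, s = np.meshgrid(centers, rates, scales, indexing="ij")
    return {
        "bin_center_hz": b.reshape(-1),
        "rate": r.reshape(-1),
        "scale": s.reshape(-1),
        "bin_centers": centers,
        "rates": rates,
        "scales": scales,
    }


def build_feature_matrix(
    sounds,
    model_tag: str,
    cochlear_spec: CochlearFilterbankSpec | None = None,
    modulation_spec: ModulationFilterbankSpec | None = None,
) -> FeatureMatrix:
    """Feature matrix W (S x F) for a SoundSet under one model.

    ``model_tag`` is ``"frequency"`` or ``"modulation"``; row i holds the
    features of sound i in SoundSet order.
    """
    if model_tag not in ("frequency", "modulation"):
        raise ValueError(f"unknown model tag {model_tag!r}")
    cspec = cochlear_spec or CochlearFilterbankSpec()
    mspec = modulation_spec or ModulationFilterbankSpec()
    waves = sounds.waveforms
    sr = getattr(sounds, "sample_rate", DEFAULT_SAMPLE_RATE)

    rows = []
    for wave in waves:
        coch = cochleogram(np.asarray(wave), cspec, sample_rate=sr)
        if model_tag == "frequency":
            rows.append(frequency_features(coch))
        else:
            rows.append(modulation_features(coch, mspec))
    n_feat = cspec.n_channels if model_tag == "frequency" else mspec.n_features
    values = np.asarray(rows) if rows else np.empty((0, n_feat))
    if model_tag == "frequency":
        labels = {"cf": cspec.center_frequencies()}
    else:
        labels = modulation_feature_labels(cspec, mspec)
    sound_ids = getattr(sounds, "sound_id", None)
    if sound_ids is not None:
        sound_ids = np.asarray(sound_ids)
    return FeatureMatrix(values, model_tag, labels, sound_ids)
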