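"""Synthetic stimuli, designs and laminar voxel populations.

This module generates every input the analysis needs, with the statistical
structure the study design assumes:

* 144 one-second sounds at 16 kHz in 6 categories (24 each), RMS-equalised
  and ramped, divided into 4 category-balanced sets of 36;
* 12 event-related runs (one set per run, each set in 3 runs, so every
  sound is presented 3 times), ISI jittered over {2, 3, 4} TRs (TR 2.4 s),
  ~8% silent trials and ~6% flagged one-back repeat trials;
* ground-truth voxel populations on a cortical-depth grid: 9 depths
  (0.1-0.9), a myelin-related-contrast (MRC) value per grid point whose
  upper half defines primary auditory cortex (PAC), per-voxel tuning in
  either the frequency or the modulation feature space, and an SNR that
  is non-decreasing toward the cortical surface (emulating the
  surface-weighted GE-EPI signal);
* BOLD time series via a linear forward model: per-sound amplitude =
  true weights . feature vector, convolved with a per-voxel double-gamma
  HRF, plus AR(1) noise and low-order polynomial drift scaled by 1/SNR.

Sounds are synthesised from moving ripples riding on tone complexes plus
band-filtered noise, with category-specific (rate, scale, frequency)
distributions, so category structure is recoverable in the model feature
spaces.  No attempt is made at acoustic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .audio_features import (
    CochlearFilterbankSpec,
    DEFAULT_SAMPLE_RATE,
    FeatureConfigError,
    FeatureMatrix,
    ModulationFilterbankSpec,
    preprocess_sound,
)

SILENT = -1
DEPTHS = np.round(np.arange(1, 10) * 0.1, 1)  # 0.1 (deep) .. 0.9 (superficial)
DEFAULT_CATEGORIES = ("speech", "voice", "animal", "music", "tool", "nature")

__all__ = [
    "SILENT",
    "DEPTHS",
    "DEFAULT_CATEGORIES",
    "SoundSet",
    "EventDesign",
    "GroundTruthPopulation",
    "DepthGrid",
    "BoldTimeseries",
    "moving_ripple",
    "make_sounds",
    "split_sets",
    "make_design",
    "make_population",
    "simulate_bold",
    "double_gamma_hrf",
]


class DesignError(ValueError):
    """Raised when a requested experimental design is infeasible."""


@dataclass
class SoundSet:
    """The stimulus universe: waveforms with category and set labels."""

    waveforms: np.ndarray  # (n_sounds, n_samples)
    category: np.ndarray  # str per sound
    set_id: np.ndarray  # 1..n_sets, or 0 before assignment
    sound_id: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    @property
    def n_sounds(self) -> int:
        return len(self.sound_id)

    @property
    def categories(self) -> np.ndarray:
        _, idx = np.unique(self.category, return_index=True)
        return self.category[np.sort(idx)]


@dataclass
class EventDesign:
    """One run: trial onsets in volumes (TR units) with trial labels."""

    run_id: int
    set_id: int
    onsets: np.ndarray  # volume index per trial
    sound_id: np.ndarray  # SILENT for silent trials
    is_silent: np.ndarray
    is_repeat: np.ndarray
    n_volumes: int
    tr_s: float = 2.4

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.onsets)


@dataclass
class GroundTruthPopulation:
    """Per-voxel ground truth used by the forward model."""

    grid_index: np.ndarray  # grid point of each voxel
    depth_index: np.ndarray  # 1..9
    depth: np.ndarray  # 0.1..0.9
    region: np.ndarray  # "PAC" | "nonPAC"
    tuning_model: np.ndarray  # "frequency" | "modulation"
    true_weights: np.ndarray  # (n_voxels, n_features)
    snr: np.ndarray
    hrf_peak_s: np.ndarray
    hrf_undershoot: np.ndarray
    scenario: str = "default"

    @property
    def n_voxels(self) -> int:
        return len(self.depth_index)


@dataclass
class DepthGrid:
    """Grid points x 9 depths with MRC values and the PAC mask."""

    mrc: np.ndarray  # per grid point
    pac_mask: np.ndarray  # bool per grid point (top half of MRC)
    depths: np.ndarray  # the 9 canonical depth values
    voxel_index: np.ndarray  # (n_points, 9) -> voxel id
    pref_octave: np.ndarray | None = None  # ground-truth tonotopic gradient

    @property
    def n_points(self) -> int:
        return len(self.mrc)


@dataclass
class BoldTimeseries:
    """Per-run volumes x voxels signal matrices."""

    runs: list  # list of (n_volumes, n_voxels) arrays
    tr_s: float
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sounds


def moving_ripple(
    rate: float,
    scale: float,
    duration_s: float = 1.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    f_min: float = 180.0,
    f_max: float = 7040.0,
    n_components: int = 64,
    depth: float = 0.9,
    direction: int = +1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Broadband moving ripple: tone complex with a drifting spectral
    modulation of ``rate`` Hz and ``scale`` cycles/octave.

    Components are log-spaced between ``f_min`` and ``f_max`` with random
    phases; component i at octave position x_i is amplitude-modulated as
    1 + depth * sin(2*pi*(rate*t + direction*scale*x_i) + phi).
    """
    rng = rng or np.random.default_rng()
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    freqs = np.geomspace(f_min, f_max, n_components)
    x = np.log2(freqs / f_min)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    ripple_phase = rng.uniform(0, 2 * np.pi)
    carriers = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    env = 1.0 + depth * np.sin(
        2 * np.pi * (rate * t[None, :] + direction * scale * x[:, None]) + ripple_phase
    )
    # 1/f component weighting keeps the complex from being treble-heavy
    weights = 1.0 / np.sqrt(freqs)
    return (weights[:, None] * env * carriers).sum(axis=0)


def _band_noise(
    lo_hz: float,
    hi_hz: float,
    n_samples: int,
    sample_rate: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise band-limited to [lo_hz, hi_hz] via spectral shaping."""
    spec = rng.standard_normal(n_samples // 2 + 1) + 1j * rng.standard_normal(
        n_samples // 2 + 1
    )
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    spec[(freqs < lo_hz) | (freqs > hi_hz)] = 0.0
    out = np.fft.irfft(spec, n=n_samples)
    norm = np.sqrt(np.mean(out**2))
    return out / norm if norm > 0 else out


# per-category synthesis signatures: (rate range Hz, scale range cyc/oct,
# octave band within [0, 5.29] relative to 180 Hz, noise mix fraction).
# These are what make each category occupy a distinct region of the
# modulation feature space (e.g. speech-like = fast rates / low scales,
# music-like = slow rates / high scales).
_CATEGORY_SIGNATURES = (
    {"rate": (9.0, 27.0), "scale": (0.5, 1.0), "oct": (1.0, 4.0), "noise": 0.2},
    {"rate": (3.0, 9.0), "scale": (0.5, 2.0), "oct": (0.5, 3.0), "noise": 0.1},
    {"rate": (3.0, 27.0), "scale": (1.0, 4.0), "oct": (2.5, 5.29), "noise": 0.2},
    {"rate": (1.0, 3.0), "scale": (2.0, 4.0), "oct": (0.0, 3.0), "noise": 0.05},
    {"rate": (9.0, 27.0), "scale": (0.5, 1.0), "oct": (1.5, 5.29), "noise": 0.5},
    {"rate": (1.0, 3.0), "scale": (0.5, 1.0), "oct": (0.0, 5.29), "noise": 0.6},
)


def make_sounds(
    n_per_category: int = 24,
    categories=DEFAULT_CATEGORIES,
    seed: int | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    duration_s: float = 1.0,
    target_rms: float = 0.05,
    f_min: float = 180.0,
    f_max: float = 7040.0,
) -> SoundSet:
    """Synthesise the stimulus set: ``n_per_category`` sounds per category.

    Each sound is a mixture of two moving ripples plus band-filtered noise
    drawn from its category's (rate, scale, frequency-band) signature,
    then ramped (10 ms linear) and RMS-equalised.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    categories = list(categories)
    if len(set(categories)) != len(categories):
        raise ValueError("categories must be distinct")
    if duration_s <= 0 or sample_rate <= 0:
        raise FeatureConfigError("invalid duration or sample rate")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sample_rate))

    waves, labels = [], []
    for ci, cat in enumerate(categories):
        sig = _CATEGORY_SIGNATURES[ci % len(_CATEGORY_SIGNATURES)]
        for _ in range(n_per_category):
            lo_oct = rng.uniform(*sig["oct"])
            hi_oct = min(lo_oct + 1.5, np.log2(f_max / f_min))
            lo_oct = max(0.0, hi_oct - 1.5)
            band = (f_min * 2**lo_oct, f_min * 2**hi_oct)
            parts = []
            for _k in range(2):
                rate = np.exp(rng.uniform(*np.log(sig["rate"])))
                scale = np.exp(rng.uniform(*np.log(sig["scale"])))
                parts.append(
                    moving_ripple(
                        rate,
                        scale,
                        duration_s,
                        sample_rate,
                        band[0],
                        band[1],
                        n_components=48,
                        direction=rng.choice([-1, 1]),
                        rng=rng,
                    )
                )
            tonal = sum(p / np.sqrt(np.mean(p**2)) for p in parts)
            noise = _band_noise(band[0], band[1], n_samples, sample_rate, rng)
            mix = (1 - sig["noise"]) * tonal / np.sqrt(np.mean(tonal**2))
            mix = mix + sig["noise"] * noise
            waves.append(
                preprocess_sound(mix, target_rms, sample_rate=sample_rate)
            )
            labels.append(cat)

    n = len(waves)
    return SoundSet(
        waveforms=np.asarray(waves),
        category=np.asarray(labels),
        set_id=np.zeros(n, dtype=int),
        sound_id=np.arange(n),
        sample_rate=sample_rate,
    )


def split_sets(sounds: SoundSet, n_sets: int = 4, seed: int | None = None) -> SoundSet:
    """Pseudorandom category-balanced partition of the sounds into sets.

    Each category's exemplars are distributed equally over the sets
    (6 per category per set for the 144-sound default).
    """
    rng = np.random.default_rng(seed)
    set_id = np.zeros(sounds.n_sounds, dtype=int)
    for cat in np.unique(sounds.category):
        idx = np.flatnonzero(sounds.category == cat)
        if len(idx) % n_sets != 0:
            raise ValueError(
                f"category {cat!r} has {len(idx)} sounds, not divisible by "
                f"{n_sets} sets"
            )
        perm = rng.permutation(idx)
        for s in range(n_sets):
            per = len(idx) // n_sets
            set_id[perm[s * per : (s + 1) * per]] = s + 1
    return SoundSet(
        sounds.waveforms, sounds.category, set_id, sounds.sound_id, sounds.sample_rate
    )


def make_design(
    sounds: SoundSet,
    runs: int = 12,
    seed: int | None = None,
    tr_s: float = 2.4,
    isi_choices=(2, 3, 4),
    silent_frac: float = 0.08,
    repeat_frac: float = 0.06,
    start_offset: int = 2,
    tail_volumes: int = 10,
    run_volumes: int | None = None,
) -> list[EventDesign]:
    """Event designs for ``runs`` runs (one sound set per run).

    Each set is presented in ``runs / n_sets`` runs, so with the 12-run
    default every sound occurs exactly 3 times (excluding flagged one-back
    repeat trials).  Silent and repeat trial counts are the rounded target
    fractions of the total trial count.  When ``run_volumes`` is None the
    run length is the last onset plus ``tail_volumes``; a fixed
    ``run_volumes`` that cannot accommodate a run raises ``DesignError``.
    """
    if runs == 0:
        return []
    set_ids = np.unique(sounds.set_id)
    if set_ids.min() < 1:
        raise DesignError("sounds must be assigned to sets before make_design")
    n_sets = len(set_ids)
    if runs % n_sets != 0:
        raise DesignError(f"runs ({runs}) must be divisible by n_sets ({n_sets})")
    rng = np.random.default_rng(seed)

    run_sets = np.repeat(set_ids, runs // n_sets)
    rng.shuffle(run_sets)

    designs = []
    for run_id, sid in enumerate(run_sets, start=1):
        set_sounds = sounds.sound_id[sounds.set_id == sid]
        n_base = len(set_sounds)
        # fixed point of total = base + round(f_sil*total) + round(f_rep*total)
        total = n_base
        for _ in range(8):
            n_sil = int(round(silent_frac * total))
            n_rep = int(round(repeat_frac * total))
            new_total = n_base + n_sil + n_rep
            if new_total == total:
                break
            total = new_total

        order = rng.permutation(set_sounds)
        trials = [(s, False, False) for s in order]
        if n_rep > 0:
            if n_base < n_rep:
                raise DesignError("more repeat trials than sound trials")
            rep_after = rng.choice(n_base, size=n_rep, replace=False)
            for pos in sorted(rep_after, reverse=True):
                trials.insert(pos + 1, (trials[pos][0], False, True))
        for _ in range(n_sil):
            pos = rng.integers(0, len(trials) + 1)
            trials.insert(pos, (SILENT, True, False))

        isis = rng.choice(isi_choices, size=len(trials) - 1)
        onsets = start_offset + np.concatenate([[0], np.cumsum(isis)])
        needed = int(onsets[-1]) + tail_volumes
        if run_volumes is not None:
            if run_volumes < needed:
                raise DesignError(
                    f"run {run_id} needs {needed} volumes but run_volumes="
                    f"{run_volumes}"
                )
            n_vol = run_volumes
        else:
            n_vol = needed
        designs.append(
            EventDesign(
                run_id=run_id,
                set_id=int(sid),
                onsets=onsets.astype(int),
                sound_id=np.array([t[0] for t in trials]),
                is_silent=np.array([t[1] for t in trials]),
                is_repeat=np.array([t[2] for t in trials]),
                n_volumes=n_vol,
                tr_s=tr_s,
            )
        )
    return designs


# ---------------------------------------------------------------------------
# populations


def _gaussian_profile(n: int, center: float, sigma: float) -> np.ndarray:
    x = np.arange(n)
    return np.exp(-((x - center) ** 2) / (2 * sigma**2))


SCENARIOS = {
    # PAC deep/middle voxels frequency-tuned, PAC superficial and all
    # non-PAC voxels modulation-tuned; SNR grows gently toward the
    # surface.  The gradient is kept mild because a strong one makes the
    # between-model score difference itself grow with depth (a gain
    # artefact), masking the tuning-based laminar structure the scenario
    # is meant to carry.
    "default": {"snr": (1.9, 2.1), "tuning": "laminar"},
    # no laminar structure at all: everything frequency-tuned, flat SNR
    "null": {"snr": (2.0, 2.0), "tuning": "all_frequency"},
    # equal half/half tuning mixture at every depth, but depth-varying SNR:
    # a pure signal-strength gain with no model difference structure
    "gain_only": {"snr": (1.0, 3.0), "tuning": "mixture"},
}


def make_population(
    n_voxels_per_cell: int = 10,
    scenario: str = "default",
    seed: int | None = None,
    cochlear_spec: CochlearFilterbankSpec | None = None,
    modulation_spec: ModulationFilterbankSpec | None = None,
    hrf_peak_s: float = 5.0,
    hrf_peak_jitter_s: float = 0.5,
) -> tuple[GroundTruthPopulation, DepthGrid]:
    """Ground-truth voxel population and its cortical-depth grid.

    ``n_voxels_per_cell`` voxels per (region, depth) cell: the grid has
    ``2 * n_voxels_per_cell`` points (half PAC by the MRC median split),
    one voxel per (point, depth).  Grid points carry a smooth tonotopic
    gradient and opposing rate/scale preference gradients, so preference
    maps and their negative rate-scale correlation are recoverable.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    cfg = SCENARIOS[scenario]
    cspec = cochlear_spec or CochlearFilterbankSpec()
    mspec = modulation_spec or ModulationFilterbankSpec()
    rng = np.random.default_rng(seed)

    n_points = 2 * n_voxels_per_cell
    mrc = rng.normal(1.0, 0.2, n_points)
    order = np.argsort(np.argsort(-mrc, kind="stable"), kind="stable")
    pac_mask = order < n_points // 2  # top half of MRC

    span = cspec.octave_span
    pref_oct = np.linspace(0.1 * span, 0.9 * span, n_points)
    rates = np.asarray(mspec.rates, float)
    scales = np.asarray(mspec.scales, float)
    # opposing gradients: rate rises, scale falls along the grid
    pref_rate_pos = np.linspace(0, len(rates) - 1, n_points)
    pref_scale_pos = np.linspace(len(scales) - 1, 0, n_points)

    snr_lo, snr_hi = cfg["snr"]
    snr_by_depth = np.linspace(snr_lo, snr_hi, len(DEPTHS))

    n_vox = n_points * len(DEPTHS)
    n_feat = cspec.n_channels
    grid_index = np.empty(n_vox, dtype=int)
    depth_index = np.empty(n_vox, dtype=int)
    region = np.empty(n_vox, dtype=object)
    tuning = np.empty(n_vox, dtype=object)
    weights = np.zeros((n_vox, n_feat))
    snr = np.empty(n_vox)
    voxel_index = np.empty((n_points, len(DEPTHS)), dtype=int)

    v = 0
    for g in range(n_points):
        reg = "PAC" if pac_mask[g] else "nonPAC"
        for d in range(len(DEPTHS)):
            if cfg["tuning"] == "laminar":
                if reg == "PAC" and DEPTHS[d] <= 0.6:
                    tun = "frequency"
                else:
                    tun = "modulation"
            elif cfg["tuning"] == "all_frequency":
                tun = "frequency"
            else:  # mixture: alternate within each (region, depth) cell
                tun = "frequency" if g % 2 == 0 else "modulation"

            if tun == "frequency":
                center = pref_oct[g] / span * (cspec.n_channels - 1)
                center += rng.normal(0, 2.0)
                w = _gaussian_profile(cspec.n_channels, center, 6.0)
            else:
                nb = mspec.n_freq_bins
                bin_center = pref_oct[g] / span * (nb - 1) + rng.normal(0, 0.3)
                wb = _gaussian_profile(nb, bin_center, 0.8)
                wr = _gaussian_profile(
                    len(rates), pref_rate_pos[g] + rng.normal(0, 0.3), 0.6
                )
                ws = _gaussian_profile(
                    len(scales), pref_scale_pos[g] + rng.normal(0, 0.3), 0.6
                )
                w = (wb[:, None, None] * wr[None, :, None] * ws[None, None, :]).reshape(-1)
            weights[v] = w / np.linalg.norm(w)
            grid_index[v] = g
            depth_index[v] = d + 1
            region[v] = reg
            tuning[v] = tun
            snr[v] = snr_by_depth[d]
            voxel_index[g, d] = v
            v += 1

    pop = GroundTruthPopulation(
        grid_index=grid_index,
        depth_index=depth_index,
        depth=DEPTHS[depth_index - 1],
        region=region.astype(str),
        tuning_model=tuning.astype(str),
        true_weights=weights,
        snr=snr,
        hrf_peak_s=hrf_peak_s + rng.uniform(-hrf_peak_jitter_s, hrf_peak_jitter_s, n_vox),
        hrf_undershoot=np.full(n_vox, 0.35),
        scenario=scenario,
    )
    grid = DepthGrid(
        mrc=mrc,
        pac_mask=pac_mask,
        depths=DEPTHS.copy(),
        voxel_index=voxel_index,
        pref_octave=pref_oct,
    )
    return pop, grid


# ---------------------------------------------------------------------------
# forward model


def double_gamma_hrf(
    t: np.ndarray, peak_s: float = 5.0, undershoot_s: float = 15.0,
    ratio: float = 0.35, dispersion: float = 0.9,
) -> np.ndarray:
    """Canonical-family double-gamma HRF evaluated at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    a1 = peak_s / dispersion + 1.0
    a2 = undershoot_s / dispersion + 1.0
    h = stats.gamma.pdf(t, a1, scale=dispersion) - ratio * stats.gamma.pdf(
        t, a2, scale=dispersion
    )
    return h


def simulate_bold(
    population: GroundTruthPopulation,
    designs: list[EventDesign],
    features_truth,
    seed: int | None = None,
    ar_coef: float = 0.4,
    drift_order: int = 3,
    drift_amp: float = 1.0,
    noise_amp: float = 1.0,
    hrf_length_s: float = 30.0,
) -> BoldTimeseries:
    """Simulate laminar BOLD runs from the linear forward model.

    ``features_truth`` is a FeatureMatrix or a mapping from tuning-model
    tag to FeatureMatrix; each voxel's per-sound amplitude is
    ``true_weights . features`` in its own tuning space.  Silent trials
    contribute baseline only; repeat trials evoke the same amplitude as
    their sound (they are excluded later, at estimation).  Noise is AR(1)
    plus Legendre drift, both scaled by the voxel's 1/SNR.
    """
    if isinstance(features_truth, FeatureMatrix):
        features_truth = {features_truth.model_tag: features_truth}
    rng = np.random.default_rng(seed)
    n_vox = population.n_voxels
    tr = designs[0].tr_s if designs else 2.4

    # per-sound amplitude per voxel
    any_fm = next(iter(features_truth.values()))
    n_sounds = any_fm.values.shape[0]
    amplitude = np.zeros((n_sounds, n_vox))
    for tag, fm in features_truth.items():
        sel = population.tuning_model == tag
        if not np.any(sel):
            continue
        if fm.values.shape[1] != population.true_weights.shape[1]:
            raise ValueError(
                f"feature dimension {fm.values.shape[1]} does not match "
                f"true_weights ({population.true_weights.shape[1]})"
            )
        amplitude[:, sel] = fm.values @ population.true_weights[sel].T
    missing = set(np.unique(population.tuning_model)) - set(features_truth)
    if missing:
        raise ValueError(f"no truth features supplied for tuning model(s) {missing}")

    n_taps = int(np.ceil(hrf_length_s / tr))
    t = np.arange(n_taps) * tr
    kernels = np.stack(
        [
            double_gamma_hrf(t, p, ratio=u)
            for p, u in zip(population.hrf_peak_s, population.hrf_undershoot)
        ],
        axis=1,
    )  # (n_taps, n_vox)

    # noiseless signal per run
    clean_runs = []
    for d in designs:
        u = np.zeros((d.n_volumes, n_vox))
        for onset, sid, silent in zip(d.onsets, d.sound_id, d.is_silent):
            if silent:
                continue
            u[onset] += amplitude[sid]
        conv = sps.fftconvolve(u, kernels, mode="full", axes=0)[: d.n_volumes]
        clean_runs.append(conv)

    clean_all = np.concatenate(clean_runs, axis=0) if clean_runs else np.zeros((0, n_vox))
    sig_sd = clean_all.std(axis=0)
    sig_sd[sig_sd == 0] = np.median(sig_sd[sig_sd > 0]) if np.any(sig_sd > 0) else 1.0
    noise_sd = noise_amp * sig_sd / population.snr

    runs = []
    for conv in clean_runs:
        n_vol = conv.shape[0]
        white = rng.standard_normal((n_vol, n_vox)) * np.sqrt(1 - ar_coef**2)
        noise = sps.lfilter([1.0], [1.0, -ar_coef], white, axis=0)
        x = np.linspace(-1, 1, n_vol)
        basis = np.stack(
            [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(drift_order + 1)],
            axis=1,
        )
        coefs = rng.standard_normal((drift_order + 1, n_vox)) * (drift_amp * noise_sd)
        drift = basis @ coefs
        runs.append(conv + noise * noise_sd + drift)

    return BoldTimeseries(
        runs=runs,
        tr_s=tr,
        params={
            "ar_coef": ar_coef,
            "drift_order": drift_order,
            "drift_amp": drift_amp,
            "noise_amp": noise_amp,
            "seed": seed,
        },
    )
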