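"""Synthetic cohorts, patients and polygraphy with ground-truth bookkeeping.

The generator emulates the study conditions of a pediatric ASL-CBF normative
comparison:

* **Fixture atlases** — block parcellations on a small grid with the real
  atlases' topology: 7 striatal + 7 thalamic source subregions and 6
  cortical subdivisions per hemisphere (40 labels), mergeable to the 36
  analysis compartments.
* **Control cohorts** — cortical CBF follows a saturating age curve
  (maturational rise); striatal/thalamic CBF is the cortical value times an
  age-dependent ratio that plateaus near 1.5 through the first year and
  decays toward 1.0 with maturation. Between-subject variation is a
  mean-one log-normal factor (positivity of CBF) plus a smaller per-
  compartment log-normal jitter; within-image noise is Gaussian per voxel.
* **Patients** — a control draw of the requested age whose chosen
  compartments are scaled by multiplicative effect factors (ictal
  hyperperfusion > 1, hypoperfusion < 1), recorded as ground truth.
* **Polygraphy** — EEG background as band-limited (slow, depressed) colored
  noise plus periodic stereotyped complexes: a negative sharp wave with a
  fixed spatial topography followed by a slow wave, and a diamond-enveloped
  EMG burst starting a fixed latency after each complex peak.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import (
    COMPARTMENT_KEYS,
    CORTICAL_SUBREGIONS,
    STRIATAL_SUBREGIONS,
    THALAMIC_SUBREGIONS,
    AtlasLabelVolume,
    CompartmentKey,
    Hemisphere,
    RegionLabel,
    Structure,
    Subdivision,
    apply_merge_rules,
    default_merge_rules,
)
from .cbf import CbfTable, CbfVolume, ExamMetadata, build_cbf_table
from .eeg import PolygraphicRecording
from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# fixture atlases
# ---------------------------------------------------------------------------


def make_fixture_atlas(grid: int = 32, seed: int = 0) -> AtlasLabelVolume:
    """Block-parcellation fixture atlas with the connectivity atlases' topology.

    Hemispheres split the x axis (world x < 0 is left), structures occupy
    y slabs (cortex, striatum, thalamus) and source subregions occupy z
    chunks whose widths are jittered by ``seed`` so compartment sizes differ.
    Two y rows are left as background. Deterministic per (grid, seed).
    """
    if grid < 16:
        raise ValueError("grid must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    n = int(grid)
    data = np.zeros((n, n, n), dtype=np.int32)
    affine = np.eye(4)
    affine[:3, 3] = -(n - 1) / 2.0  # center the grid; x=0 falls between hemispheres

    slab = (n - 2) // 3
    structure_rows = {
        Structure.CORTEX: (0, slab),
        Structure.STRIATUM: (slab, 2 * slab),
        Structure.THALAMUS: (2 * slab, 3 * slab),
    }
    sources = {
        Structure.CORTEX: CORTICAL_SUBREGIONS,
        Structure.STRIATUM: STRIATAL_SUBREGIONS,
        Structure.THALAMUS: THALAMIC_SUBREGIONS,
    }
    half = n // 2
    hemi_cols = {Hemisphere.LEFT: (0, half), Hemisphere.RIGHT: (half, n)}

    labels: dict[int, RegionLabel] = {}
    next_id = 1
    for structure, (j0, j1) in structure_rows.items():
        names = sources[structure]
        cuts = np.linspace(0, n, len(names) + 1).astype(int)
        jitter = rng.integers(-1, 2, size=len(cuts) - 2)
        cuts[1:-1] = np.maximum.accumulate(np.clip(cuts[1:-1] + jitter, 2, n - 2))
        for name, k0, k1 in zip(names, cuts[:-1], cuts[1:]):
            if k1 <= k0:
                raise ValueError("grid too small to host all subregions")
            for hemi, (i0, i1) in hemi_cols.items():
                data[i0:i1, j0:j1, k0:k1] = next_id
                labels[next_id] = RegionLabel(structure, name, hemi)
                next_id += 1
    return AtlasLabelVolume(data, affine, labels, space="fixture")


def fixture_compartment_atlas(grid: int = 32, seed: int = 0) -> AtlasLabelVolume:
    """Fixture atlas already merged to the 36 analysis compartments."""
    return apply_merge_rules(make_fixture_atlas(grid, seed), default_merge_rules())


# ---------------------------------------------------------------------------
# CBF cohorts and patients
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Parameters of the synthetic control population.

    The defaults describe a 232-child control pool (ages spanning infancy to
    adolescence, two scanners, sedation for the youngest) with a cortical
    CBF maturation curve and a subcortical/cortical ratio near 1.5 in the
    first year that decays toward 1.0 afterwards.
    """

    n_controls: int = 232
    age_range_months: tuple[float, float] = (3.0, 186.0)
    scanners: tuple[str, ...] = ("scanner_A", "scanner_B")
    sedation_age_cutoff_months: float = 48.0
    cortical_cbf_at_birth: float = 28.0       # ml/100 g/min
    cortical_cbf_asymptote: float = 58.0      # ml/100 g/min
    cortical_tau_months: float = 30.0
    ratio_at_birth: float = 1.5               # subcortical / cortical
    ratio_asymptote: float = 1.0
    ratio_plateau_months: float = 12.0
    ratio_tau_months: float = 48.0
    between_subject_cv: float = 0.15
    compartment_cv: float = 0.05
    voxel_noise_sd: float = 5.0               # ml/100 g/min
    background_fraction: float = 0.5          # non-compartment tissue level
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("between_subject_cv", "compartment_cv", "voxel_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def cortical_cbf(age_months: float, spec: CohortSpec) -> float:
    """Mean cortical CBF at a given age: saturating maturational rise."""
    a0, a1, tau = (
        spec.cortical_cbf_at_birth,
        spec.cortical_cbf_asymptote,
        spec.cortical_tau_months,
    )
    return a1 - (a1 - a0) * float(np.exp(-age_months / tau))


def subcortical_ratio(age_months: float, spec: CohortSpec) -> float:
    """Striatal/thalamic over cortical CBF ratio at a given age.

    Holds at ``ratio_at_birth`` through the plateau (first year by default),
    then decays exponentially toward ``ratio_asymptote``.
    """
    excess = spec.ratio_at_birth - spec.ratio_asymptote
    lag = max(0.0, age_months - spec.ratio_plateau_months)
    return spec.ratio_asymptote + excess * float(np.exp(-lag / spec.ratio_tau_months))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one log-normal multiplicative factor(s) with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def compartment_means(
    age_months: float, spec: CohortSpec, rng: np.random.Generator
) -> dict[CompartmentKey, float]:
    """Draw one subject's true per-compartment mean CBF values."""
    base = cortical_cbf(age_months, spec)
    ratio = subcortical_ratio(age_months, spec)
    subject = _lognormal_factor(rng, spec.between_subject_cv)
    jitter = _lognormal_factor(rng, spec.compartment_cv, size=len(COMPARTMENT_KEYS))
    means = {}
    for key, j in zip(COMPARTMENT_KEYS, jitter):
        level = base if key.structure == Structure.CORTEX else base * ratio
        means[key] = float(level * subject * j)
    return means


def volume_from_means(
    means: Mapping[CompartmentKey, float],
    atlas: AtlasLabelVolume,
    meta: ExamMetadata,
    *,
    voxel_noise_sd: float,
    background_level: float,
    rng: np.random.Generator,
) -> CbfVolume:
    key_to_label = atlas.compartment_labels()
    lut = np.full(max(atlas.labels) + 1, background_level, dtype=float)
    for key, mean in means.items():
        lut[key_to_label[key]] = mean
    data = lut[atlas.data]
    if voxel_noise_sd > 0:
        data = data + rng.normal(0.0, voxel_noise_sd, size=data.shape)
    return CbfVolume(data, atlas.affine.copy(), meta)


@dataclass
class Cohort:
    """Generated control cohort: volumes, metadata, and ground truth."""

    volumes: list[CbfVolume]
    metadata: pd.DataFrame
    ground_truth: pd.DataFrame  # subject_id, structure, subdivision, hemisphere, true_mean

    def tables(self, atlas: AtlasLabelVolume) -> list[CbfTable]:
        return [build_cbf_table(vol, atlas) for vol in self.volumes]


def generate_control_cohort(spec: CohortSpec, atlas: AtlasLabelVolume) -> Cohort:
    """Generate the control pool: one CBF volume + metadata row per subject."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range_months
    volumes, meta_rows, truth_rows = [], [], []
    for i in range(spec.n_controls):
        age = float(rng.integers(int(lo), int(hi) + 1))
        scanner = str(rng.choice(list(spec.scanners)))
        sedation = age < spec.sedation_age_cutoff_months
        subject = f"ctrl-{i:03d}"
        meta = ExamMetadata(
            subject_id=subject, exam_id=f"{subject}-e1", age_months=age,
            scanner=scanner, sedation=sedation, state="control", group="controls",
        )
        means = compartment_means(age, spec, rng)
        background = spec.background_fraction * cortical_cbf(age, spec)
        volumes.append(
            volume_from_means(
                means, atlas, meta,
                voxel_noise_sd=spec.voxel_noise_sd,
                background_level=background, rng=rng,
            )
        )
        meta_rows.append(meta.to_dict())
        truth_rows.extend(
            {
                "subject_id": subject,
                "structure": key.structure.value,
                "subdivision": key.subdivision.value,
                "hemisphere": key.hemisphere.value,
                "true_mean": mean,
            }
            for key, mean in means.items()
        )
    return Cohort(volumes, pd.DataFrame(meta_rows), pd.DataFrame(truth_rows))


#: Default multiplicative effect for ictal hyperperfusion in injected
#: circuits: about twice baseline perfusion, the magnitude of stroke-like
#: ictal CBF increases, and ~6 control SD at the default cohort dispersion.
DEFAULT_ICTAL_EFFECT = 2.0


@dataclass
class EffectSpec:
    """A synthetic patient: demographics plus injected compartment effects."""

    age_months: float
    scanner: str = "scanner_A"
    sedation: bool = True
    state: str = "ictal"
    effects: Mapping[CompartmentKey, float] = field(default_factory=dict)
    subject_id: str = "patient"
    seed: int = 0

    def __post_init__(self) -> None:
        for key, factor in self.effects.items():
            if factor <= 0:
                raise ConfigurationError(f"effect for {key} must be > 0, got {factor}")


def circuit_effect(
    subdivision: Subdivision,
    hemisphere: Hemisphere,
    factor: float = DEFAULT_ICTAL_EFFECT,
    structures: Sequence[Structure] = tuple(Structure),
) -> dict[CompartmentKey, float]:
    """Effect map for a topographically aligned circuit (same subdivision and
    hemisphere across the chosen structures)."""
    return {
        CompartmentKey(Structure(st), subdivision, hemisphere): factor
        for st in structures
    }


def generate_patient(
    effect: EffectSpec, cohort_spec: CohortSpec, atlas: AtlasLabelVolume
) -> tuple[CbfVolume, dict]:
    """Draw a patient volume from the control model and apply the effects.

    The volume is first generated exactly like a control of the same age,
    then every affected compartment's voxels are scaled by its factor.
    Returns the volume and a ground-truth record.
    """
    key_to_label = atlas.compartment_labels()
    unknown = [k for k in effect.effects if k not in key_to_label]
    if unknown:
        raise KeyError(f"effect compartments not in atlas: {unknown}")

    rng = np.random.default_rng(effect.seed)
    meta = ExamMetadata(
        subject_id=effect.subject_id, exam_id=f"{effect.subject_id}-{effect.state}",
        age_months=effect.age_months, scanner=effect.scanner,
        sedation=effect.sedation, state=effect.state, group="patients",
    )
    means = compartment_means(effect.age_months, cohort_spec, rng)
    background = cohort_spec.background_fraction * cortical_cbf(
        effect.age_months, cohort_spec
    )
    volume = volume_from_means(
        means, atlas, meta,
        voxel_noise_sd=cohort_spec.voxel_noise_sd,
        background_level=background, rng=rng,
    )
    for key, factor in effect.effects.items():
        volume.data[atlas.data == key_to_label[key]] *= factor
    truth = {
        "effects": {key: float(f) for key, f in effect.effects.items()},
        "base_means": means,
        "age_months": effect.age_months,
        "state": effect.state,
        "seed": effect.seed,
    }
    return volume, truth


# ---------------------------------------------------------------------------
# polygraphy
# ---------------------------------------------------------------------------

EEG_CHANNELS = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]
CENTRAL_PARIETAL_CHANNELS = ["C3", "C4", "Cz", "P3", "P4", "Pz"]
EMG_CHANNELS = ["EMG_deltoid_left", "EMG_deltoid_right"]


def _sspe_topography() -> dict[str, float]:
    """Zero-sum spatial profile of the SSPE complex: negative central-parietal
    sharp wave, left predominant (max at P3), phase reversal over frontal
    leads. Zero channel sum keeps the profile invariant under common-average
    re-referencing."""
    weights = {
        "P3": -1.0, "C3": -0.9, "Pz": -0.85, "Cz": -0.8, "P4": -0.8, "C4": -0.75,
        "O1": -0.1, "O2": -0.1, "T3": -0.1, "T4": -0.1, "T5": -0.1, "T6": -0.1,
    }
    frontal = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz")
    balance = -sum(weights.values()) / len(frontal)
    weights.update({name: balance for name in frontal})
    return weights


@dataclass
class EegPreset:
    """Waveform/timing parameters for one periodic-discharge scenario."""

    name: str
    topography: Mapping[str, float] = field(default_factory=dict)
    amplitude_uv: float = 90.0            # sharp-wave peak at the max-weight channel
    sharp_duration_ms: float = 120.0
    slow_amplitude_uv: float = 40.0
    slow_duration_ms: float = 500.0
    slow_onset_ms: float = 60.0           # after the sharp-wave peak
    fast_rhythm_uv: float = 0.0           # superimposed rapid rhythms on the slow wave
    fast_rhythm_hz: float = 20.0
    interval_range_s: tuple[float, float] | None = (5.0, 7.0)
    latency_ms: float = 40.0              # EEG complex peak -> EMG onset
    emg_peak_uv: float = 100.0
    emg_rise_ms: float = 40.0
    emg_fall_ms: float = 110.0
    emg_sides: Mapping[str, float] = field(
        default_factory=lambda: {"EMG_deltoid_right": 1.0, "EMG_deltoid_left": 0.6}
    )
    emg_noise_sd_uv: float = 10.0         # envelope-peak / noise-sd = amplitude SNR 10
    eeg_noise_sd_uv: float = 20.0
    noise_band_hz: tuple[float, float] = (0.5, 4.0)
    sfreq: float = 1024.0

    def __post_init__(self) -> None:
        for name in self.topography:
            if name not in EEG_CHANNELS:
                raise ConfigurationError(f"unknown EEG channel {name!r}")
        for name in self.emg_sides:
            if name not in EMG_CHANNELS:
                raise ConfigurationError(f"unknown EMG channel {name!r}")
        if self.name.startswith("SSPE") and self.interval_range_s is not None:
            if not 20.0 <= self.latency_ms <= 60.0:
                raise ConfigurationError("SSPE presets require latency in [20, 60] ms")


def sspe_early(**overrides) -> EegPreset:
    """SSPE at presentation: 5-7 s periodicity, 90 µV sharp wave, 20-60 ms latency."""
    params = dict(
        name="SSPE_early",
        topography=_sspe_topography(),
        amplitude_uv=90.0,
        fast_rhythm_uv=8.0,
        interval_range_s=(5.0, 7.0),
        latency_ms=40.0,
    )
    params.update(overrides)
    return EegPreset(**params)


def sspe_late(**overrides) -> EegPreset:
    """Advanced SSPE: shorter 2-3 s complex-to-complex intervals."""
    params = dict(
        name="SSPE_late",
        topography=_sspe_topography(),
        amplitude_uv=90.0,
        interval_range_s=(2.0, 3.0),
        latency_ms=40.0,
    )
    params.update(overrides)
    return EegPreset(**params)


def lpd_focal(**overrides) -> EegPreset:
    """Lateralized periodic discharges confined to left-hemisphere leads."""
    params = dict(
        name="LPD_focal",
        topography={"F3": -0.8, "C3": -1.0, "P3": -0.9, "F7": -0.6, "T3": -0.7, "T5": -0.6},
        amplitude_uv=120.0,
        interval_range_s=(1.5, 3.0),
        latency_ms=40.0,
        emg_sides={"EMG_deltoid_right": 1.0},
    )
    params.update(overrides)
    return EegPreset(**params)


def es_cluster(**overrides) -> EegPreset:
    """Clustered epileptic spasms: diffuse slow-wave complex with superimposed
    fast rhythms and bilateral (asymmetric) deltoid bursts."""
    params = dict(
        name="ES_cluster",
        topography={name: -0.7 for name in EEG_CHANNELS} | {"Cz": -1.0, "Pz": -0.9},
        amplitude_uv=150.0,
        slow_amplitude_uv=100.0,
        fast_rhythm_uv=15.0,
        interval_range_s=(5.0, 10.0),
        latency_ms=60.0,
        emg_rise_ms=150.0,
        emg_fall_ms=250.0,
        emg_sides={"EMG_deltoid_right": 1.0, "EMG_deltoid_left": 0.8},
    )
    params.update(overrides)
    return EegPreset(**params)


def null_background(**overrides) -> EegPreset:
    """Background activity only: no complexes, no EMG bursts."""
    params = dict(name="null_background", topography={}, interval_range_s=None)
    params.update(overrides)
    return EegPreset(**params)


def _colored_noise(
    rng: np.random.Generator, n: int, sfreq: float, band: tuple[float, float], sd: float
) -> np.ndarray:
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    lo, hi = band
    hi = min(hi, 0.45 * sfreq)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    colored = signal.sosfiltfilt(sos, white)
    scale = colored.std()
    return colored * (sd / scale) if scale > 0 else colored


def _emg_carrier(
    rng: np.random.Generator, n: int, sfreq: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-amplitude EMG interference carrier.

    Band-limited noise normalized by its Hilbert envelope, so the burst's
    instantaneous amplitude follows the diamond envelope exactly and the
    burst onset is identifiable (a plain noise carrier leaves the first
    milliseconds of the ramp without any signal whenever it dips near zero).
    """
    x = _colored_noise(rng, n, sfreq, band, 1.0)
    analytic = signal.hilbert(x)
    return np.real(analytic) / np.maximum(np.abs(analytic), 1e-9)


def _hann(n: int) -> np.ndarray:
    return np.hanning(n) if n > 1 else np.ones(max(n, 1))


def _add_waveform(trace: np.ndarray, start: int, waveform: np.ndarray) -> None:
    stop = start + waveform.size
    lo, hi = max(start, 0), min(stop, trace.size)
    if lo < hi:
        trace[lo:hi] += waveform[lo - start : hi - start]


def generate_polygraphy(
    preset: EegPreset, duration_s: float, seed: int = 0
) -> tuple[PolygraphicRecording, dict]:
    """Generate a polygraphic recording and its ground-truth event record.

    Complex peaks are placed at sample-grid times separated by intervals
    drawn uniformly from the preset's range; each EMG burst starts exactly
    ``latency_ms`` (snapped to the sample grid) after the complex peak.
    """
    if preset.interval_range_s is not None:
        if duration_s < 10 * preset.interval_range_s[1]:
            raise ValueError(
                "duration must be at least 10x the maximum complex interval"
            )
    rng = np.random.default_rng(seed)
    fs = preset.sfreq
    n = int(round(duration_s * fs))

    data = np.zeros((len(EEG_CHANNELS) + len(EMG_CHANNELS), n))
    for i in range(len(EEG_CHANNELS)):
        data[i] = _colored_noise(rng, n, fs, preset.noise_band_hz, preset.eeg_noise_sd_uv)
    emg_offset = len(EEG_CHANNELS)
    emg_band = (20.0, min(400.0, 0.45 * fs))
    for j in range(len(EMG_CHANNELS)):
        data[emg_offset + j] = _colored_noise(
            rng, n, fs, emg_band, preset.emg_noise_sd_uv
        )

    peaks: list[int] = []
    if preset.interval_range_s is not None:
        t = 5.0
        guard = (preset.slow_onset_ms + preset.slow_duration_ms) / 1000.0 + 1.0
        while t + guard < duration_s:
            peaks.append(int(round(t * fs)))
            t += rng.uniform(*preset.interval_range_s)

    latency_samples = int(round(preset.latency_ms / 1000.0 * fs))

    n_sharp = max(3, int(round(preset.sharp_duration_ms / 1000.0 * fs)) | 1)
    sharp = _hann(n_sharp)
    n_slow = max(3, int(round(preset.slow_duration_ms / 1000.0 * fs)))
    slow = _hann(n_slow) * (preset.slow_amplitude_uv / max(preset.amplitude_uv, 1e-12))
    if preset.fast_rhythm_uv > 0:
        tt = np.arange(n_slow) / fs
        slow = slow + (
            preset.fast_rhythm_uv / max(preset.amplitude_uv, 1e-12)
        ) * _hann(n_slow) * np.sin(2 * np.pi * preset.fast_rhythm_hz * tt)
    slow_offset = int(round(preset.slow_onset_ms / 1000.0 * fs))

    n_rise = max(1, int(round(preset.emg_rise_ms / 1000.0 * fs)))
    n_fall = max(1, int(round(preset.emg_fall_ms / 1000.0 * fs)))
    envelope = np.concatenate(
        [np.linspace(0.0, 1.0, n_rise, endpoint=False), np.linspace(1.0, 0.0, n_fall)]
    )

    for peak in peaks:
        for name, weight in preset.topography.items():
            trace = data[EEG_CHANNELS.index(name)]
            scale = weight * preset.amplitude_uv
            _add_waveform(trace, peak - n_sharp // 2, scale * sharp)
            _add_waveform(trace, peak + slow_offset, scale * slow)
        onset = peak + latency_samples
        for name, side in preset.emg_sides.items():
            carrier = _emg_carrier(rng, envelope.size, fs, emg_band)
            burst = preset.emg_peak_uv * side * envelope * carrier
            _add_waveform(data[emg_offset + EMG_CHANNELS.index(name)], onset, burst)

    rec = PolygraphicRecording(
        data=data,
        sfreq=fs,
        ch_names=EEG_CHANNELS + EMG_CHANNELS,
        eeg_channels=list(EEG_CHANNELS),
        emg_channels=list(EMG_CHANNELS),
        montage="referential",
    )
    peaks_s = np.asarray(peaks, dtype=float) / fs
    truth = {
        "preset": preset.name,
        "seed": seed,
        "complex_peaks_s": peaks_s,
        "emg_onsets_s": peaks_s + latency_samples / fs,
        "latency_samples": latency_samples,
        "latency_ms": latency_samples / fs * 1000.0,
        "amplitude_uv": preset.amplitude_uv,
        "intervals_s": np.diff(peaks_s),
    }
    return rec, truth
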