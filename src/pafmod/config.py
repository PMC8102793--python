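"""Configuration objects for simulation and pipeline runs.

Every numeric default that the analysis protocol fixes (sampling rate, trial
counts, filter cutoffs, artifact thresholds, spectral grid, alpha band,
analysis-window spans) lives here so that a run is fully determined by one
config object plus a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

#: The four working-memory task types: 2/3-sample x Precise/Relative.
TASK_TYPES = ("2P", "2R", "3P", "3R")

#: Channel role labels.
ROLE_SCALP = "scalp"
ROLE_POSTERIOR = "posterior"
ROLE_EOG = "EOG"


@dataclass(frozen=True)
class TrialTimeline:
    """Timing of one trial, in seconds relative to cue+sample onset (t = 0).

    The epoch spans 7.5 s: 2 s of pre-trial buffer, 500 ms baseline fixation,
    500 ms cue+sample, 2,000 ms memory delay, then test/response/feedback.
    Consecutive trial onsets are 5.5 s apart, so adjacent 7.5 s epochs overlap
    by 2 s.
    """

    baseline_onset: float = -0.5
    cue_sample_onset: float = 0.0
    sample_duration: float = 0.5
    delay_duration: float = 2.0
    test_onset: float = 2.5
    segment_span: tuple[float, float] = (-2.0, 5.5)
    trial_spacing: float = 5.5

    def __post_init__(self) -> None:
        lo, hi = self.segment_span
        if abs((hi - lo) - 7.5) > 1e-12:
            raise ValueError("segment span must be exactly 7.5 s")
        if not (lo <= self.baseline_onset and 0.0 <= hi):
            raise ValueError("baseline window must lie inside the segment")
        if abs(self.test_onset - (self.sample_duration + self.delay_duration)) > 1e-12:
            raise ValueError("test onset must equal sample + delay duration")


def default_channel_labels(n_channels: int) -> list[str]:
    return [f"ch{i + 1:02d}" for i in range(n_channels)]


def default_posterior_labels(n_channels: int, n_posterior: int = 14) -> list[str]:
    labels = default_channel_labels(n_channels)
    return labels[-n_posterior:]


def _default_accuracy_means() -> dict[str, float]:
    # Cross-group central tendencies of proportion correct per task type.
    return {"2P": 0.915, "2R": 0.925, "3P": 0.71, "3R": 0.86}


def _default_rt_means() -> dict[str, float]:
    # Mean response times (ms) per task type.
    return {"2P": 654.0, "2R": 698.0, "3P": 736.0, "3R": 833.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic working-memory EEG cohort.

    The cohort emulates a 110-participant study (77 females, 33 males), each
    performing 8 blocks of 64 trials of a 4-condition visuospatial working
    memory task while 47 scalp channels plus 2 EOG channels are recorded at
    512 Hz. Each subject carries a baseline peak alpha frequency and a
    sex-dependent baseline-to-delay frequency shift (the quantity the analysis
    is built to recover).
    """

    n_females: int = 77
    n_males: int = 33
    sampling_rate: float = 512.0
    n_blocks: int = 8
    trials_per_block: int = 64
    n_channels: int = 47
    posterior_channels: list[str] = field(default_factory=lambda: default_posterior_labels(47))
    baseline_paf_mean: float = 10.4
    baseline_paf_sd: float = 1.2
    modulation_mean_f: float = 0.30
    modulation_sd_f: float = 1.1
    modulation_mean_m: float = 0.0
    modulation_sd_m: float = 0.7
    #: within-subject trial-to-trial SD of the injected frequencies (Hz)
    paf_trial_sd: float = 0.0
    aperiodic_exponent: float = 1.0
    alpha_amplitude: float = 10.0      # uV
    noise_amplitude: float = 2.0       # uV RMS of the 1/f background
    eog_noise_amplitude: float = 1.0   # uV RMS on the EOG channels
    blink_rate: float = 0.1            # per-trial blink probability
    blink_amplitude: float = 100.0     # uV
    paf_accuracy_r_male_relative: float = 0.4
    accuracy_means: dict[str, float] = field(default_factory=_default_accuracy_means)
    rt_means: dict[str, float] = field(default_factory=_default_rt_means)
    accuracy_logit_sd: float = 0.5     # between-subject ability SD, logit scale
    rt_subject_sigma: float = 0.15     # between-subject lognormal sigma
    rt_trial_sigma: float = 0.25       # within-subject lognormal sigma
    seed: int = 0
    timeline: TrialTimeline = field(default_factory=TrialTimeline)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.n_females + self.n_males

    @property
    def trials_per_subject(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def channel_labels(self) -> list[str]:
        return default_channel_labels(self.n_channels)

    @property
    def eog_labels(self) -> list[str]:
        return ["eog1", "eog2"]

    @property
    def all_labels(self) -> list[str]:
        return self.channel_labels + self.eog_labels

    @property
    def channel_roles(self) -> dict[str, str]:
        roles = {}
        posterior = set(self.posterior_channels)
        for lab in self.channel_labels:
            roles[lab] = ROLE_POSTERIOR if lab in posterior else ROLE_SCALP
        for lab in self.eog_labels:
            roles[lab] = ROLE_EOG
        return roles

    def validate(self) -> None:
        for name in ("n_females", "n_males", "n_blocks", "trials_per_block", "n_channels"):
            if getattr(self, name) <= 0 or int(getattr(self, name)) != getattr(self, name):
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.blink_rate <= 1.0:
            raise ValueError("blink_rate must be a probability in [0, 1]")
        for name in ("baseline_paf_sd", "modulation_sd_f", "modulation_sd_m",
                     "paf_trial_sd", "noise_amplitude", "eog_noise_amplitude",
                     "accuracy_logit_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        labels = self.channel_labels
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels")
        if not self.posterior_channels:
            raise ValueError("at least one posterior channel is required")
        missing = set(self.posterior_channels) - set(labels)
        if missing:
            raise ValueError(f"posterior channels not in montage: {sorted(missing)}")
        # highest generated frequency is the alpha band ceiling (14 Hz) plus
        # jitter; require a generous margin below Nyquist
        if self.sampling_rate <= 2 * 20.0:
            raise ValueError("sampling_rate must exceed twice the highest generated frequency")
        for m in (self.accuracy_means, self.rt_means):
            if set(m) != set(TASK_TYPES):
                raise ValueError(f"task-type maps must have keys {TASK_TYPES}")
        for p in self.accuracy_means.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("accuracy means must be proportions in [0, 1]")


@dataclass
class PreprocConfig:
    """Filtering, segmentation and artifact-screening parameters."""

    hp_hz: float = 0.5
    lp_hz: float = 30.0
    eog_threshold_uv: float = 18.75
    spike_factor: float = 10.0
    use_ica_hook: bool = False

    def validate(self) -> None:
        if not 0 < self.hp_hz < self.lp_hz:
            raise ValueError("need 0 < hp < lp")
        if self.spike_factor <= 1:
            raise ValueError("spike_factor must exceed 1")


@dataclass
class SpectralConfig:
    """Time-frequency decomposition parameters (Hann-tapered sliding window)."""

    window_s: float = 2.0
    stride_s: float = 0.05
    fmin: float = 2.0
    fmax: float = 20.0
    fstep: float = 0.5


@dataclass
class StatsConfig:
    n_boot: int = 2000
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Full pipeline configuration: simulate -> preprocess -> tfr -> paf -> stats."""

    sim: SimConfig = field(default_factory=SimConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    alpha_band: tuple[float, float] = (8.0, 14.0)
    seed: int = 0
    out_dir: str = "pafmod_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_band"] = list(self.alpha_band)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, Mapping):
            sim = dict(sim)
            tl = sim.pop("timeline", None)
            if isinstance(tl, Mapping):
                tl = dict(tl)
                if "segment_span" in tl:
                    tl["segment_span"] = tuple(tl["segment_span"])
                sim["timeline"] = TrialTimeline(**tl)
            sim = SimConfig(**sim)
        preproc = d.pop("preproc", {})
        if isinstance(preproc, Mapping):
            preproc = PreprocConfig(**preproc)
        spectral = d.pop("spectral", {})
        if isinstance(spectral, Mapping):
            spectral = SpectralConfig(**spectral)
        stats = d.pop("stats", {})
        if isinstance(stats, Mapping):
            stats = StatsConfig(**stats)
        band = tuple(d.pop("alpha_band", (8.0, 14.0)))
        return cls(sim=sim, preproc=preproc, spectral=spectral, stats=stats,
                   alpha_band=band, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable hash of the analysis configuration, stamped on every output.

        The output directory is excluded: it does not affect the results.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
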