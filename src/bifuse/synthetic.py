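"""Synthetic bimodal motor-imagery data with lateralized effects.

The generator emulates the two signatures the downstream pipeline is built
to detect:

* EEG: event-related desynchronization (ERD) of the mu rhythm (10 Hz) on
  sensorimotor channels contralateral to the imagined hand, on top of a
  1/f broadband background;
* fNIRS: a canonical double-gamma hemodynamic response adding to HbO (and,
  scaled by a negative factor, to HbR) on contralateral channels, on top of
  cardiac / respiratory / Mayer-wave oscillations and white noise.

Hemisphere membership is encoded in the channel names following the 10-05
convention: odd position digits = left hemisphere, even = right.  Left-hand
imagery activates the right hemisphere and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import LABELS, RawRecording

#: EEG montage around the sensorimotor cortex (left then right hemisphere).
EEG_CHANNELS = ["FCC5h", "FCC3h", "CCP5h", "CCP3h", "FCC4h", "FCC6h", "CCP4h", "CCP6h"]

#: fNIRS source-detector pairs co-located with the EEG montage.
FNIRS_CHANNELS = ["FC3-FC5", "FC3-FC1", "C5-C3", "C1-C3", "FC4-FC2", "FC4-FC6", "C2-C4", "C6-C4"]

#: HbR response amplitude relative to HbO (typical empirical ratio).
HBR_RATIO = -0.4

MU_FREQ_HZ = 10.0
MU_AMPLITUDE = 1.0

# physiological confounds added to the chromophore traces: (freq Hz, amplitude)
FNIRS_CONFOUNDS = ((1.0, 0.2), (0.3, 0.15), (0.1, 0.1))
FNIRS_WHITE_NOISE_SCALE = 0.1  # white-noise sd as a fraction of noise_sd


def hemisphere_of(channel_name: str) -> str:
    """Infer the hemisphere of a channel from its position digits.

    Odd digits lie over the left hemisphere, even digits over the right
    (10-05 electrode naming).  Compound optode names such as ``"FC3-FC5"``
    carry digits of a single hemisphere.
    """
    digits = [int(c) for c in channel_name if c.isdigit()]
    if not digits:
        raise ValueError(f"channel name {channel_name!r} carries no position digit")
    sides = {"left" if d % 2 else "right" for d in digits}
    if len(sides) != 1:
        raise ValueError(f"channel name {channel_name!r} mixes hemispheres")
    return sides.pop()


def contralateral_hemisphere(label: str) -> str:
    """The hemisphere activated by imagery of the given hand."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    return "right" if label == "left" else "left"


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic participant.

    The defaults mirror the experimental protocol of the emulated open
    dataset: 30 trials per class, 10-s trials, EEG at 200 Hz and fNIRS at
    10 Hz, eight channels per modality over the sensorimotor cortex.
    ``erd_depth`` is the fractional mu-power suppression on contralateral
    channels; ``hemo_amplitude`` the contralateral HbO peak in relative
    concentration units; ``noise_sd`` the broadband EEG noise level (the
    fNIRS white-noise level is scaled from it).
    """

    n_trials_per_class: int = 30
    trial_length_s: float = 10.0
    eeg_rate_hz: float = 200.0
    fnirs_rate_hz: float = 10.0
    n_eeg_channels: int = 8
    n_fnirs_channels: int = 8
    erd_depth: float = 0.5
    hemo_amplitude: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    eeg_channel_names: list[str] = field(default_factory=lambda: list(EEG_CHANNELS))
    fnirs_channel_names: list[str] = field(default_factory=lambda: list(FNIRS_CHANNELS))

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.eeg_channel_names) != self.n_eeg_channels:
            raise ValueError("eeg_channel_names length must equal n_eeg_channels")
        if len(self.fnirs_channel_names) != self.n_fnirs_channels:
            raise ValueError("fnirs_channel_names length must equal n_fnirs_channels")
        # every channel must carry a hemisphere tag
        for name in list(self.eeg_channel_names) + list(self.fnirs_channel_names):
            hemisphere_of(name)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def pink_noise(n_samples: int, n_channels: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise: white noise shaped in the frequency domain."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return sd * shaped


def double_gamma_hrf(t_s: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak.

    Peak near 6 s, undershoot near 16 s with amplitude ratio 1/6.
    """
    from scipy.stats import gamma

    t = np.asarray(t_s, dtype=float)
    h = gamma.pdf(t, a=6) - gamma.pdf(t, a=16) / 6.0
    peak = gamma.pdf(np.linspace(0, 32, 3201), a=6).max()
    return np.where(t >= 0, h / peak, 0.0)


def _mu_wave(n: int, rate: float, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / rate
    phases = rng.uniform(0, 2 * np.pi, size=n_channels)
    return MU_AMPLITUDE * np.sin(2 * np.pi * MU_FREQ_HZ * t[None, :] + phases[:, None])


def generate_eeg_trial(label: str, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """One 10-s EEG trial: 1/f background plus a mu oscillation whose
    amplitude is suppressed by ``erd_depth`` on contralateral channels.

    Returns channels x samples at ``spec.eeg_rate_hz``.
    """
    active = contralateral_hemisphere(label)
    n = int(round(spec.trial_length_s * spec.eeg_rate_hz))
    mu = _mu_wave(n, spec.eeg_rate_hz, spec.n_eeg_channels, rng)
    gain = np.array(
        [
            1.0 - spec.erd_depth if hemisphere_of(name) == active else 1.0
            for name in spec.eeg_channel_names
        ]
    )
    return gain[:, None] * mu + pink_noise(n, spec.n_eeg_channels, spec.noise_sd, rng)


def _fnirs_confounds(
    n: int, rate: float, n_channels: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / rate
    out = np.zeros((n_channels, n))
    for freq, amp in FNIRS_CONFOUNDS:
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        out += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    out += FNIRS_WHITE_NOISE_SCALE * sd * rng.standard_normal((n_channels, n))
    return out


def generate_fnirs_trial(label: str, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """One cue-locked fNIRS trial as two planes (HbO, HbR) x channels x samples.

    A double-gamma response scaled by ``hemo_amplitude`` adds to HbO (and
    ``HBR_RATIO`` times that to HbR) on contralateral channels; every channel
    receives physiological oscillations and white noise.
    """
    active = contralateral_hemisphere(label)
    n = int(round(spec.trial_length_s * spec.fnirs_rate_hz))
    t = np.arange(n) / spec.fnirs_rate_hz
    hrf = double_gamma_hrf(t)
    mask = np.array(
        [1.0 if hemisphere_of(name) == active else 0.0 for name in spec.fnirs_channel_names]
    )
    response = spec.hemo_amplitude * mask[:, None] * hrf[None, :]
    hbo = response + _fnirs_confounds(n, spec.fnirs_rate_hz, spec.n_fnirs_channels, spec.noise_sd, rng)
    hbr = HBR_RATIO * response + abs(HBR_RATIO) * _fnirs_confounds(
        n, spec.fnirs_rate_hz, spec.n_fnirs_channels, spec.noise_sd, rng
    )
    return np.stack([hbo, hbr])


# layout constants for the continuous recordings (seconds)
_PAD_START_S = 15.0
_PAD_END_S = 15.0
_REST_RANGE_S = (10.0, 12.0)
_TIME_GRID_S = 0.1  # event times land on a grid exact in both sample rates


def generate_dataset(spec: SyntheticSpec) -> tuple[RawRecording, RawRecording]:
    """Paired continuous EEG and chromophore recordings with aligned events.

    Trials (``n_trials_per_class`` per label, order shuffled) are separated
    by rest gaps of 10-12 s.  Event onsets are identical across modalities
    after converting samples to seconds.  The chromophore recording stacks
    HbO rows before HbR rows, with suffixed channel names.
    """
    rng = spec.rng()
    labels = [lab for lab in LABELS for _ in range(spec.n_trials_per_class)]
    rng.shuffle(labels)

    onsets_s = []
    t = _PAD_START_S
    for k in range(len(labels)):
        onsets_s.append(round(t / _TIME_GRID_S) * _TIME_GRID_S)
        gap = rng.uniform(*_REST_RANGE_S)
        t += spec.trial_length_s + round(gap / _TIME_GRID_S) * _TIME_GRID_S
    total_s = onsets_s[-1] + spec.trial_length_s + _PAD_END_S

    n_eeg = int(round(total_s * spec.eeg_rate_hz))
    n_fn = int(round(total_s * spec.fnirs_rate_hz))

    # rest background: 1/f noise + baseline mu for EEG, confounds for fNIRS
    eeg = pink_noise(n_eeg, spec.n_eeg_channels, spec.noise_sd, rng)
    eeg += _mu_wave(n_eeg, spec.eeg_rate_hz, spec.n_eeg_channels, rng)
    fnirs = np.stack(
        [
            _fnirs_confounds(n_fn, spec.fnirs_rate_hz, spec.n_fnirs_channels, spec.noise_sd, rng),
            abs(HBR_RATIO)
            * _fnirs_confounds(n_fn, spec.fnirs_rate_hz, spec.n_fnirs_channels, spec.noise_sd, rng),
        ]
    )

    events_eeg, events_fn = [], []
    for onset_s, label in zip(onsets_s, labels):
        i_eeg = int(round(onset_s * spec.eeg_rate_hz))
        i_fn = int(round(onset_s * spec.fnirs_rate_hz))
        span_eeg = int(round(spec.trial_length_s * spec.eeg_rate_hz))
        span_fn = int(round(spec.trial_length_s * spec.fnirs_rate_hz))
        eeg[:, i_eeg : i_eeg + span_eeg] = generate_eeg_trial(label, spec, rng)
        fnirs[:, :, i_fn : i_fn + span_fn] = generate_fnirs_trial(label, spec, rng)
        events_eeg.append((i_eeg, label))
        events_fn.append((i_fn, label))

    eeg_rec = RawRecording(
        participant_id=f"synthetic-{spec.seed:04d}",
        modality="eeg",
        channel_names=list(spec.eeg_channel_names),
        sample_rate_hz=spec.eeg_rate_hz,
        data=eeg,
        events=events_eeg,
        pre_cue_s=10.0,
        post_cue_s=20.0,
    )
    chromo_names = [f"{c}_HbO" for c in spec.fnirs_channel_names] + [
        f"{c}_HbR" for c in spec.fnirs_channel_names
    ]
    fnirs_rec = RawRecording(
        participant_id=eeg_rec.participant_id,
        modality="nirs-chromophore",
        channel_names=chromo_names,
        sample_rate_hz=spec.fnirs_rate_hz,
        data=fnirs.reshape(2 * spec.n_fnirs_channels, n_fn),
        events=events_fn,
        pre_cue_s=10.0,
        post_cue_s=20.0,
    )
    return eeg_rec, fnirs_rec
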