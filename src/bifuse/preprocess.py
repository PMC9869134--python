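"""Preprocessing chains for EEG and fNIRS recordings.

EEG chain: downsample 200 -> 128 Hz, drop EOG channels, common average
reference, zero-phase band-pass 8-25 Hz, select the eight sensorimotor
electrodes, cut 0-10 s cue-locked epochs, normalize each channel to
[-1, 1].

fNIRS chain: (modified Beer-Lambert conversion when the input is raw light
intensity), zero-phase band-pass 0.01-0.1 Hz at the native 10 Hz, upsample
to 128 Hz, select the eight sensorimotor optical channels, cut epochs with
a [-5, -2] s pre-cue baseline correction, crop to 0-10 s, normalize.

All filters are 4th-order Butterworth applied forward-backward
(zero phase); resampling is polyphase with anti-aliasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ChromophoreEpoch, Epoch, RawRecording
from .synthetic import EEG_CHANNELS, FNIRS_CHANNELS

TARGET_RATE_HZ = 128.0
EEG_BAND_HZ = (8.0, 25.0)
FNIRS_BAND_HZ = (0.01, 0.1)
BASELINE_WINDOW_S = (-5.0, -2.0)
EPOCH_SPAN_S = (0.0, 10.0)
FILTER_ORDER = 4


# ---------------------------------------------------------------------------
# array-level primitives


def _resample_array(data: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    if rate_out <= 0:
        raise ValueError(f"target rate must be positive, got {rate_out}")
    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def _bandpass_sos(low_hz: float, high_hz: float, rate_hz: float, order: int):
    nyq = rate_hz / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")


def _bandpass_array(
    data: np.ndarray, low_hz: float, high_hz: float, rate_hz: float, order: int
) -> np.ndarray:
    sos = _bandpass_sos(low_hz, high_hz, rate_hz, order)
    return signal.sosfiltfilt(sos, data, axis=-1)


# ---------------------------------------------------------------------------
# epoch-level operations (accept Epoch or RawRecording where sensible)


def resample(epoch: Epoch, target_rate_hz: float) -> Epoch:
    """Anti-aliased rate conversion; sample count becomes
    round(old_count * target / old)."""
    out = _resample_array(epoch.data, epoch.sample_rate_hz, target_rate_hz)
    expected = int(round(epoch.data.shape[-1] * target_rate_hz / epoch.sample_rate_hz))
    if out.shape[-1] != expected:  # polyphase edge case: trim/pad to contract
        out = out[..., :expected]
    return epoch.replace(data=out, sample_rate_hz=target_rate_hz)


def common_average_reference(epoch: Epoch) -> Epoch:
    """Subtract the across-channel mean from every channel, per sample."""
    if getattr(epoch, "modality", "eeg") != "eeg":
        raise ValueError("common average reference applies to EEG only")
    if epoch.data.shape[0] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return epoch.replace(data=epoch.data - epoch.data.mean(axis=0, keepdims=True))


def bandpass(epoch: Epoch, low_hz: float, high_hz: float, order: int = FILTER_ORDER) -> Epoch:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    return epoch.replace(
        data=_bandpass_array(epoch.data, low_hz, high_hz, epoch.sample_rate_hz, order)
    )


def baseline_correct(epoch: Epoch, window_s: tuple[float, float] = BASELINE_WINDOW_S) -> Epoch:
    """Subtract the per-channel mean over ``window_s`` (relative to cue)."""
    lo, hi = window_s
    if lo < epoch.t_start_s or hi > epoch.t_start_s + epoch.duration_s:
        raise ValueError(
            f"baseline window {window_s} s outside epoch context "
            f"[{epoch.t_start_s}, {epoch.t_start_s + epoch.duration_s}) s"
        )
    i0 = int(round((lo - epoch.t_start_s) * epoch.sample_rate_hz))
    i1 = int(round((hi - epoch.t_start_s) * epoch.sample_rate_hz))
    mean = epoch.data[:, i0:i1].mean(axis=1, keepdims=True)
    return epoch.replace(data=epoch.data - mean)


def normalize_amplitude(epoch: Epoch, scope: str = "channel") -> Epoch:
    """Scale to max |x| = 1, per channel (default) or over the whole trial."""
    data = epoch.data.astype(float)
    if scope == "channel":
        denom = np.abs(data).max(axis=1, keepdims=True)
    elif scope == "trial":
        denom = np.full((data.shape[0], 1), np.abs(data).max())
    else:
        raise ValueError(f"scope must be 'channel' or 'trial', got {scope!r}")
    zero = denom.ravel() == 0
    if zero.any():
        warnings.warn("all-zero channel(s) left unchanged by normalization", stacklevel=2)
        denom = np.where(denom == 0, 1.0, denom)
    return epoch.replace(data=data / denom)


def compute_coe(ce: ChromophoreEpoch) -> Epoch:
    """Cerebral oxygen exchange: COE = HbO - HbR, element-wise."""
    if ce.hbo.data.shape != ce.hbr.data.shape:
        raise ValueError("HbO/HbR shape mismatch")
    return ce.hbo.replace(data=ce.hbo.data - ce.hbr.data, modality="coe")


# ---------------------------------------------------------------------------
# Beer-Lambert conversion


@dataclass
class BeerLambertParams:
    """Constants of the modified Beer-Lambert law.

    ``extinction_matrix`` rows are wavelengths, columns (HbO, HbR), in
    1/(mM*cm).  ``dpf`` is the differential pathlength factor per
    wavelength; ``separation_cm`` the source-detector distance.
    Defaults use standard extinction coefficients at 760/850 nm and
    DPF = 6.0 at a 3-cm optode separation.
    """

    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    extinction_matrix: np.ndarray = field(
        default_factory=lambda: np.array([[0.586, 1.548], [1.058, 0.691]])
    )
    dpf: tuple[float, float] = (6.0, 6.0)
    separation_cm: float = 3.0

    def system_matrix(self) -> np.ndarray:
        """The 2x2 matrix A with ΔOD = A @ (ΔHbO, ΔHbR)."""
        E = np.asarray(self.extinction_matrix, dtype=float)
        L = self.separation_cm * np.asarray(self.dpf, dtype=float)
        A = E * L[:, None]
        if not np.isfinite(np.linalg.cond(A)) or np.linalg.cond(A) > 1e12:
            raise ValueError("extinction system is singular or near-singular")
        return A


def optical_density(intensity: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """ΔOD(t) = -log10(I(t) / I_baseline)."""
    if np.any(intensity <= 0) or np.any(baseline <= 0):
        raise ValueError("light intensities must be strictly positive")
    return -np.log10(intensity / baseline)


def beer_lambert(
    intensity_epoch: Epoch,
    params: BeerLambertParams | None = None,
    baseline_window: tuple[int, int] | None = None,
) -> ChromophoreEpoch:
    """Convert a two-wavelength intensity epoch to HbO/HbR concentration
    changes.

    The epoch's rows must hold all first-wavelength channels followed by all
    second-wavelength channels (equal counts, matching order).
    ``baseline_window`` selects the samples averaged into I_baseline
    (default: the whole epoch).
    """
    params = params or BeerLambertParams()
    data = np.asarray(intensity_epoch.data, dtype=float)
    if data.shape[0] % 2:
        raise ValueError("intensity epoch needs two wavelength planes per optical channel")
    n = data.shape[0] // 2
    planes = data.reshape(2, n, -1)
    sl = slice(*baseline_window) if baseline_window else slice(None)
    baseline = planes[:, :, sl].mean(axis=2, keepdims=True)
    dod = optical_density(planes, baseline)  # (2, n, t)
    A = params.system_matrix()
    conc = np.linalg.solve(A, dod.reshape(2, -1)).reshape(2, n, -1)
    names = [c.split("_")[0] for c in intensity_epoch.channel_names[:n]] or [
        f"ch{i}" for i in range(n)
    ]
    hbo = intensity_epoch.replace(
        data=conc[0], modality="hbo", channel_names=[f"{c}_HbO" for c in names]
    )
    hbr = intensity_epoch.replace(
        data=conc[1], modality="hbr", channel_names=[f"{c}_HbR" for c in names]
    )
    return ChromophoreEpoch(hbo=hbo, hbr=hbr)


def beer_lambert_forward(
    ce: ChromophoreEpoch, params: BeerLambertParams | None = None
) -> np.ndarray:
    """Forward model: concentration changes back to ΔOD planes (2, n, t)."""
    params = params or BeerLambertParams()
    A = params.system_matrix()
    conc = np.stack([ce.hbo.data, ce.hbr.data])
    return (A @ conc.reshape(2, -1)).reshape(conc.shape)


# ---------------------------------------------------------------------------
# recording-level chains


def select_channels(rec: RawRecording, names: list[str]) -> RawRecording:
    """Keep the named channels, in the requested order."""
    index = {c: i for i, c in enumerate(rec.channel_names)}
    missing = [c for c in names if c not in index]
    if missing:
        raise KeyError(f"channels absent from recording: {missing}")
    rows = [index[c] for c in names]
    return RawRecording(
        participant_id=rec.participant_id,
        modality=rec.modality,
        channel_names=list(names),
        sample_rate_hz=rec.sample_rate_hz,
        data=rec.data[rows],
        events=list(rec.events),
        pre_cue_s=rec.pre_cue_s,
        post_cue_s=rec.post_cue_s,
    )


def drop_eog(rec: RawRecording) -> RawRecording:
    keep = [c for c in rec.channel_names if "eog" not in c.lower()]
    return select_channels(rec, keep)


def _resample_recording(rec: RawRecording, target_rate_hz: float) -> RawRecording:
    data = _resample_array(rec.data, rec.sample_rate_hz, target_rate_hz)
    scale = target_rate_hz / rec.sample_rate_hz
    events = [(int(round(onset * scale)), label) for onset, label in rec.events]
    return RawRecording(
        participant_id=rec.participant_id,
        modality=rec.modality,
        channel_names=list(rec.channel_names),
        sample_rate_hz=target_rate_hz,
        data=data,
        events=events,
        pre_cue_s=rec.pre_cue_s,
        post_cue_s=rec.post_cue_s,
    )


def epoch_recording(
    rec: RawRecording,
    t_start_s: float,
    duration_s: float,
    modality: str,
) -> list[Epoch]:
    """Cut one epoch per event, ``[t_start, t_start + duration)`` around cue."""
    n = int(round(duration_s * rec.sample_rate_hz))
    epochs = []
    for k, (onset, label) in enumerate(rec.events):
        i0 = onset + int(round(t_start_s * rec.sample_rate_hz))
        if i0 < 0 or i0 + n > rec.data.shape[1]:
            raise ValueError(f"event {k} at sample {onset} lacks requested context")
        epochs.append(
            Epoch(
                modality=modality,
                data=rec.data[:, i0 : i0 + n].copy(),
                sample_rate_hz=rec.sample_rate_hz,
                t_start_s=t_start_s,
                label=label,
                parent_trial_id=f"{rec.participant_id}/trial{k:03d}",
                participant_id=rec.participant_id,
                channel_names=list(rec.channel_names),
            )
        )
    return epochs


def preprocess_eeg(
    raw: RawRecording,
    montage: list[str] | None = None,
    band_hz: tuple[float, float] = EEG_BAND_HZ,
    normalize_scope: str = "channel",
) -> list[Epoch]:
    """Full EEG chain; returns one 0-10 s epoch at 128 Hz per event."""
    montage = montage or EEG_CHANNELS
    rec = _resample_recording(raw, TARGET_RATE_HZ)
    rec = drop_eog(rec)
    if rec.n_channels < 2:
        raise ValueError("EEG chain needs at least 2 channels for the common average")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)  # CAR before selection
    data = _bandpass_array(data, band_hz[0], band_hz[1], rec.sample_rate_hz, FILTER_ORDER)
    rec = RawRecording(
        participant_id=rec.participant_id,
        modality="eeg",
        channel_names=rec.channel_names,
        sample_rate_hz=rec.sample_rate_hz,
        data=data,
        events=rec.events,
        pre_cue_s=rec.pre_cue_s,
        post_cue_s=rec.post_cue_s,
    )
    rec = select_channels(rec, montage)
    epochs = epoch_recording(rec, EPOCH_SPAN_S[0], EPOCH_SPAN_S[1] - EPOCH_SPAN_S[0], "eeg")
    return [normalize_amplitude(e, scope=normalize_scope) for e in epochs]


def _split_chromophore(rec: RawRecording) -> tuple[RawRecording, RawRecording, list[str]]:
    """Split a stacked chromophore recording into HbO and HbR halves."""
    hbo_rows = [i for i, c in enumerate(rec.channel_names) if c.endswith("_HbO")]
    hbr_rows = [i for i, c in enumerate(rec.channel_names) if c.endswith("_HbR")]
    if not hbo_rows or len(hbo_rows) != len(hbr_rows):
        raise ValueError("chromophore recording must carry matching _HbO/_HbR rows")
    base = [rec.channel_names[i][: -len("_HbO")] for i in hbo_rows]
    hbo = select_channels(rec, [rec.channel_names[i] for i in hbo_rows])
    hbr = select_channels(rec, [rec.channel_names[i] for i in hbr_rows])
    return hbo, hbr, base


def preprocess_fnirs(
    raw: RawRecording,
    montage: list[str] | None = None,
    params: BeerLambertParams | None = None,
    band_hz: tuple[float, float] = FNIRS_BAND_HZ,
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
    normalize_scope: str = "channel",
    filter_first: bool = True,
) -> list[ChromophoreEpoch]:
    """Full fNIRS chain; returns one chromophore epoch pair per event.

    ``filter_first`` band-passes at the native 10 Hz before upsampling
    (numerically preferable for the 0.01 Hz corner); set False to follow
    the upsample-then-filter ordering instead.
    """
    montage = montage or FNIRS_CHANNELS
    if raw.modality == "nirs-intensity":
        as_epoch = Epoch(
            modality="hbo",  # placeholder; replaced below
            data=raw.data,
            sample_rate_hz=raw.sample_rate_hz,
            t_start_s=0.0,
            label="left",
            parent_trial_id="raw",
            channel_names=list(raw.channel_names),
        )
        ce = beer_lambert(as_epoch, params)
        data = np.vstack([ce.hbo.data, ce.hbr.data])
        names = list(ce.hbo.channel_names) + list(ce.hbr.channel_names)
        raw = RawRecording(
            participant_id=raw.participant_id,
            modality="nirs-chromophore",
            channel_names=names,
            sample_rate_hz=raw.sample_rate_hz,
            data=data,
            events=list(raw.events),
            pre_cue_s=raw.pre_cue_s,
            post_cue_s=raw.post_cue_s,
        )
    elif raw.modality != "nirs-chromophore":
        raise ValueError(f"expected an fNIRS recording, got modality {raw.modality!r}")

    def _filter(rec: RawRecording) -> RawRecording:
        filtered = _bandpass_array(
            rec.data, band_hz[0], band_hz[1], rec.sample_rate_hz, FILTER_ORDER
        )
        return RawRecording(
            participant_id=rec.participant_id,
            modality=rec.modality,
            channel_names=rec.channel_names,
            sample_rate_hz=rec.sample_rate_hz,
            data=filtered,
            events=rec.events,
            pre_cue_s=rec.pre_cue_s,
            post_cue_s=rec.post_cue_s,
        )

    if filter_first:
        rec = _resample_recording(_filter(raw), TARGET_RATE_HZ)
    else:
        rec = _filter(_resample_recording(raw, TARGET_RATE_HZ))

    hbo_rec, hbr_rec, base = _split_chromophore(rec)
    missing = [c for c in montage if c not in base]
    if missing:
        raise KeyError(f"optical channels absent from recording: {missing}")
    hbo_rec = select_channels(hbo_rec, [f"{c}_HbO" for c in montage])
    hbr_rec = select_channels(hbr_rec, [f"{c}_HbR" for c in montage])

    t0 = baseline_window_s[0]
    span = EPOCH_SPAN_S[1] - t0
    out = []
    for eh, er in zip(
        epoch_recording(hbo_rec, t0, span, "hbo"), epoch_recording(hbr_rec, t0, span, "hbr")
    ):
        pair = []
        for ep in (eh, er):
            ep = baseline_correct(ep, baseline_window_s)
            i0 = int(round((EPOCH_SPAN_S[0] - t0) * ep.sample_rate_hz))
            n = int(round((EPOCH_SPAN_S[1] - EPOCH_SPAN_S[0]) * ep.sample_rate_hz))
            ep = ep.replace(data=ep.data[:, i0 : i0 + n], t_start_s=EPOCH_SPAN_S[0])
            pair.append(normalize_amplitude(ep, scope=normalize_scope))
        out.append(ChromophoreEpoch(hbo=pair[0], hbr=pair[1]))
    return out
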