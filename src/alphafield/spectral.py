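"""EEG spectral estimation and alpha-band readouts.

Implements the scalp-EEG side of the analysis: multitaper power spectra on
10-s epochs, individual alpha frequency (IAF) detection in 8-12 Hz with an
explicit identifiability rule, the Hilbert-envelope alpha amplitude
(band-pass +/- 2 Hz around the IAF, zero-phase 4th-order Butterworth), the
stimulation-frequency MISMATCH predictor, and the post-pre / tACS-sham
difference helpers.

Amplitudes are in microvolt (uV) throughout; frequencies in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import AnalysisError, InputError, SubjectExclusion

DEFAULT_CHANNELS = ("Oz", "POz")
ALPHA_BAND = (8.0, 12.0)


@dataclass
class EEGRun:
    """One run of multi-channel EEG.

    Parameters
    ----------
    sampling_rate
        Sampling rate in Hz.
    channel_labels
        One label per row of ``samples``.
    samples
        Array of shape ``(n_channels, n_samples)`` in uV.
    artifact_segments
        Half-open sample intervals ``[start, stop)`` to exclude from
        averaging; must be sorted, non-overlapping and in range.
    """

    sampling_rate: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    artifact_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        if self.samples.ndim != 2:
            raise InputError("samples must be (n_channels, n_samples)")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InputError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        segs = tuple((int(a), int(b)) for a, b in self.artifact_segments)
        n = self.samples.shape[1]
        prev_stop = 0
        for a, b in segs:
            if not (0 <= a < b <= n):
                raise InputError(f"artifact segment [{a}, {b}) out of range [0, {n})")
            if a < prev_stop:
                raise InputError("artifact segments overlap or are unsorted")
            prev_stop = b
        self.artifact_segments = segs

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Run length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InputError(
                f"channel {label!r} not found; available: {list(self.channel_labels)}"
            ) from None

    def clean_segments(self) -> list[tuple[int, int]]:
        """Half-open sample intervals not covered by an artifact segment."""
        out = []
        pos = 0
        for a, b in self.artifact_segments:
            if a > pos:
                out.append((pos, a))
            pos = b
        if pos < self.n_samples:
            out.append((pos, self.n_samples))
        return out


@dataclass
class Spectrum:
    """Epoch- and channel-averaged power spectrum.

    ``power`` is a one-sided PSD on the ``frequencies`` grid; absolute
    scaling is immaterial for peak picking.
    """

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float
    smoothing_halfwidth: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise InputError("frequencies and power must have the same shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise InputError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise InputError("power must be nonnegative")


@dataclass
class IafResult:
    """Outcome of IAF detection.

    ``iaf`` is ``None`` when no identifiable peak exists in ``band``.
    """

    iaf: float | None
    peak_power: float
    band: tuple[float, float] = field(default=ALPHA_BAND)

    @property
    def identifiable(self) -> bool:
        return self.iaf is not None


def power_spectrum(
    run: EEGRun,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    epoch_length: float = 10.0,
    resolution: float = 0.1,
    smoothing: float = 0.5,
) -> Spectrum:
    """Multitaper power spectrum averaged over epochs and channels.

    The run is split into consecutive non-overlapping epochs of
    ``epoch_length`` seconds; any epoch overlapping an artifact segment is
    dropped whole. Each surviving epoch is mean-detrended and tapered with
    DPSS windows of half-bandwidth ``smoothing`` Hz (time-halfbandwidth
    product ``NW = epoch_length * smoothing``, ``2 NW - 1`` tapers); tapered
    periodograms are averaged over tapers, epochs, and finally channels.
    ``resolution`` sets the output frequency grid via zero padding; it may
    be equal to or finer than the natural ``1 / epoch_length`` grid, but a
    coarser grid would truncate epochs and is rejected.
    """
    fs = run.sampling_rate
    n_ep = round(epoch_length * fs)
    if n_ep < 2:
        raise InputError("epoch_length too short for the sampling rate")
    nfft = round(fs / resolution)
    if nfft < n_ep:
        raise InputError(
            f"resolution {resolution} Hz is coarser than the {epoch_length} s "
            "epoch supports; decrease epoch_length or refine resolution"
        )
    ch_idx = [run.channel_index(c) for c in channels]

    # epochs fully inside a clean segment
    starts = []
    for a, b in run.clean_segments():
        # align epoch grid to run start: epoch i covers [i*n_ep, (i+1)*n_ep)
        first = math.ceil(a / n_ep)
        last = b // n_ep
        starts.extend(i * n_ep for i in range(first, last))
    if not starts:
        raise AnalysisError("no artifact-free epoch of the requested length")

    nw = epoch_length * smoothing
    n_tapers = max(1, int(2 * nw - 1))
    tapers = signal.windows.dpss(n_ep, nw, Kmax=n_tapers)  # (K, n_ep), unit energy

    acc = None
    for s in starts:
        seg = run.samples[ch_idx, s : s + n_ep]
        seg = seg - seg.mean(axis=1, keepdims=True)
        # (K, C, nfft//2+1)
        spec = np.fft.rfft(tapers[:, None, :] * seg[None, :, :], n=nfft, axis=-1)
        psd = (np.abs(spec) ** 2).mean(axis=0) * (2.0 / fs)
        acc = psd if acc is None else acc + psd
    power = acc.mean(axis=0) / len(starts)  # channel then epoch average
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return Spectrum(freqs, power, resolution=fs / nfft, smoothing_halfwidth=smoothing)


def detect_iaf(
    spectrum: Spectrum,
    band: tuple[float, float] = ALPHA_BAND,
    prominence_fraction: float = 0.2,
) -> IafResult:
    """Detect the individual alpha frequency as the highest in-band peak.

    The candidate must be a local maximum of the spectrum whose prominence
    is at least ``prominence_fraction`` of the median in-band power; this is
    the reproducible surrogate for a visual "identifiable peak" call.
    Returns a non-identifiable result (``iaf is None``) otherwise.
    """
    f, p = spectrum.frequencies, spectrum.power
    lo, hi = band
    if lo < f[0] or hi > f[-1]:
        raise InputError(f"band {band} outside spectrum support [{f[0]}, {f[-1]}]")
    in_band = (f >= lo) & (f <= hi)
    if not np.any(in_band):
        raise InputError(f"band {band} contains no spectral bins")
    threshold = prominence_fraction * float(np.median(p[in_band]))

    peaks, _ = signal.find_peaks(p)
    prominences = signal.peak_prominences(p, peaks)[0] if peaks.size else np.array([])
    keep = peaks[(in_band[peaks]) & (prominences >= threshold)] if peaks.size else peaks
    if keep.size == 0:
        return IafResult(iaf=None, peak_power=float("nan"), band=band)
    best = keep[np.argmax(p[keep])]
    return IafResult(iaf=float(f[best]), peak_power=float(p[best]), band=band)


def session_mean_iaf(
    runs: list[EEGRun],
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    band: tuple[float, float] = ALPHA_BAND,
    **spectrum_kwargs,
) -> float:
    """Arithmetic mean of per-run IAFs over the supplied runs.

    Runs without an identifiable peak are skipped; if no run has one the
    subject cannot be analysed and :class:`SubjectExclusion` is raised.
    The caller chooses the run set: all four pre/post video runs for the
    analysis IAF, or the tACS session's pre+post for the MISMATCH predictor.
    """
    iafs = []
    for run in runs:
        spec = power_spectrum(run, channels=channels, **spectrum_kwargs)
        res = detect_iaf(spec, band=band)
        if res.identifiable:
            iafs.append(res.iaf)
    if not iafs:
        raise SubjectExclusion("non-identifiable alpha peak in all supplied runs")
    return float(np.mean(iafs))


def band_envelope(
    run: EEGRun,
    iaf: float,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    halfwidth: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Hilbert envelope of the band-passed signal, per channel.

    Zero-phase (forward-backward) Butterworth band-pass of the given order
    around ``iaf +/- halfwidth``, then the magnitude of the analytic signal.
    Returns shape ``(len(channels), n_samples)`` in uV.
    """
    if iaf - halfwidth <= 0:
        raise InputError(f"iaf - halfwidth = {iaf - halfwidth} must be positive")
    nyq = run.sampling_rate / 2
    if iaf + halfwidth >= nyq:
        raise InputError("band edge exceeds the Nyquist frequency")
    ch_idx = [run.channel_index(c) for c in channels]
    sos = signal.butter(
        order, [iaf - halfwidth, iaf + halfwidth], btype="bandpass",
        fs=run.sampling_rate, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, run.samples[ch_idx], axis=1)
    return np.abs(signal.hilbert(filtered, axis=1))


def alpha_amplitude(
    run: EEGRun,
    iaf: float,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    halfwidth: float = 2.0,
    edge_trim: float = 1.0,
) -> float:
    """Mean alpha-band Hilbert envelope, in uV.

    Each contiguous artifact-free segment is filtered and
    Hilbert-transformed on its own, so even extreme artifact amplitudes
    cannot ring into the average; ``edge_trim`` seconds are then discarded
    at each end of every segment to suppress the remaining filter and
    Hilbert edge transients. The envelope is averaged over the kept samples
    per channel and the channel means are then averaged (the two averaging
    orders coincide because the channels share the artifact mask).
    """
    trim = round(edge_trim * run.sampling_rate)
    total = None
    count = 0
    for a, b in run.clean_segments():
        if b - a <= 2 * trim:
            continue
        segment = EEGRun(run.sampling_rate, run.channel_labels, run.samples[:, a:b])
        env = band_envelope(segment, iaf, channels=channels, halfwidth=halfwidth)
        kept = env[:, trim : env.shape[1] - trim]
        total = kept.sum(axis=1) if total is None else total + kept.sum(axis=1)
        count += kept.shape[1]
    if count == 0:
        raise AnalysisError("no artifact-free samples left after edge trimming")
    return float((total / count).mean())


def mismatch(tacs_frequency: float, tacs_session_mean_iaf: float) -> float:
    """Absolute difference between the applied tACS frequency and the
    session-mean IAF, in Hz."""
    for name, v in (("tacs_frequency", tacs_frequency),
                    ("tacs_session_mean_iaf", tacs_session_mean_iaf)):
        if not np.isfinite(v) or v <= 0:
            raise InputError(f"{name} must be finite and positive, got {v}")
    return abs(tacs_frequency - tacs_session_mean_iaf)


def delta(post_value: float, pre_value: float) -> float:
    """Post-minus-pre change within one session."""
    if not (np.isfinite(post_value) and np.isfinite(pre_value)):
        raise InputError("delta requires finite inputs")
    return post_value - pre_value


def double_delta(delta_tacs: float, delta_sham: float) -> float:
    """Session contrast of the within-session changes (tACS minus sham)."""
    if not (np.isfinite(delta_tacs) and np.isfinite(delta_sham)):
        raise InputError("double_delta requires finite inputs")
    return delta_tacs - delta_sham
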