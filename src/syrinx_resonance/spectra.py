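"""Power spectra, spectral smoothing and harmonic profiles of duck calls.

Everything here is relative-amplitude analysis: each spectrum is
self-normalised so its maximum sits at 0 dB, because field recordings carry
no absolute SPL calibration and all downstream comparisons (harmonic
emphasis, resonance-peak matching) are about the *shape* of the spectrum.

Two smoothing routes are provided, mirroring common practice in
bioacoustics software: cepstral liftering of the log-spectrum, and an
all-pole (LPC) envelope of the waveform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import fft as sfft
from scipy import signal as ssig
from scipy.linalg import solve_toeplitz

__all__ = [
    "CallRecording",
    "PowerSpectrum",
    "HarmonicProfile",
    "power_spectrum",
    "cepstral_smooth",
    "lpc_envelope",
    "central_segment",
    "estimate_fundamental",
    "harmonic_amplitudes",
    "average_spectra",
    "detect_peaks",
]

_MIN_SAMPLES = 1024
_MIN_RATE = 8000


@dataclass
class CallRecording:
    """A mono call recording with samples in [-1, 1].

    ``metadata`` carries species/sex/call-type/age annotations; stereo
    input should be down-mixed before construction (see
    :func:`from_samples`).
    """

    samples: np.ndarray
    sample_rate_hz: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 2:
            warnings.warn(
                "stereo input down-mixed to mono by channel mean",
                stacklevel=3,
            )
            self.samples = self.samples.mean(axis=1)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D (or 2-D stereo) array")
        if self.samples.size < _MIN_SAMPLES:
            raise ValueError(
                f"recording too short: {self.samples.size} < {_MIN_SAMPLES} samples"
            )
        if self.sample_rate_hz < _MIN_RATE:
            raise ValueError(
                f"sample_rate_hz must be >= {_MIN_RATE}, got {self.sample_rate_hz}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate_hz / 2.0


@dataclass
class PowerSpectrum:
    """Frequency bins and dB levels, peak-normalised to 0 dB.

    ``smoothing`` records provenance: ``"none"``, ``"cepstral"`` or
    ``"lpc"``, with the controlling parameter in ``smoothing_parameter``.
    """

    frequencies_hz: np.ndarray
    level_db: np.ndarray
    smoothing: str = "none"
    smoothing_parameter: float = float("nan")

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.level_db = np.asarray(self.level_db, dtype=float)
        if self.frequencies_hz.shape != self.level_db.shape:
            raise ValueError("frequency and level arrays must share a shape")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequencies_hz must be strictly increasing")

    def normalised(self) -> "PowerSpectrum":
        return replace(self, level_db=self.level_db - self.level_db.max())

    @property
    def peak_hz(self) -> float:
        return float(self.frequencies_hz[int(np.argmax(self.level_db))])

    def level_at(self, hz: float) -> float:
        return float(np.interp(hz, self.frequencies_hz, self.level_db))


@dataclass(frozen=True)
class HarmonicProfile:
    """Fundamental frequency and relative amplitudes of FF, F2, F3.

    Amplitudes are in dB relative to the segment's spectral maximum, so
    they are always <= 0 and the loudest harmonic sits at 0 dB.
    """

    fundamental_hz: float
    rel_amp_db: dict
    segment: tuple[float, float] = (float("nan"), float("nan"))


def power_spectrum(
    recording: CallRecording,
    window_s: float = 0.03,
    overlap: float = 0.5,
) -> PowerSpectrum:
    """Welch-averaged periodogram of a recording, in dB re max.

    30 ms Hann windows with 50% overlap give ~33 Hz resolution at
    44.1 kHz — fine enough to separate call harmonics while averaging
    away frame-to-frame variation.
    """
    nperseg = int(round(window_s * recording.sample_rate_hz))
    if nperseg > recording.samples.size:
        raise ValueError(
            f"recording ({recording.samples.size} samples) shorter than one "
            f"window ({nperseg} samples)"
        )
    freqs, pxx = ssig.welch(
        recording.samples,
        fs=recording.sample_rate_hz,
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        window="hann",
        detrend="constant",
    )
    level = 10.0 * np.log10(np.maximum(pxx, 1e-300))
    return PowerSpectrum(freqs, level - level.max())


def cepstral_smooth(
    spectrum: PowerSpectrum, bandwidth_hz: float = 50.0
) -> PowerSpectrum:
    """Smooth a log-spectrum by low-pass liftering its cepstrum.

    The dB spectrum is transformed to the cepstral (quefrency) domain with
    a DCT and components above the cutoff quefrency ``1 / bandwidth_hz``
    are zeroed: spectral ripple with period finer than ``bandwidth_hz`` is
    removed, leaving the envelope.  The result is re-normalised to 0 dB.
    """
    if not bandwidth_hz > 0:
        raise ValueError(f"bandwidth_hz must be > 0, got {bandwidth_hz}")
    df = np.diff(spectrum.frequencies_hz)
    if not np.allclose(df, df[0], rtol=1e-6):
        raise ValueError("cepstral smoothing requires a uniform frequency grid")
    level = spectrum.level_db
    n = level.size
    span_hz = df[0] * n
    # DCT-II coefficient k oscillates with spectral period 2*span/k, i.e.
    # quefrency k / (2*span); keep k <= 2*span / bandwidth.
    cep = sfft.dct(level, type=2, norm="ortho")
    k_max = int(math.floor(2.0 * span_hz / bandwidth_hz))
    cep[k_max + 1 :] = 0.0
    smoothed = sfft.idct(cep, type=2, norm="ortho")
    return PowerSpectrum(
        spectrum.frequencies_hz.copy(),
        smoothed - smoothed.max(),
        smoothing="cepstral",
        smoothing_parameter=bandwidth_hz,
    )


def lpc_envelope(
    recording: CallRecording,
    n_peaks: int = 30,
    preemphasis_hz: float = 50.0,
    n_bins: int = 2049,
) -> PowerSpectrum:
    """All-pole (LPC) spectral envelope of a recording.

    A first-difference pre-emphasis filter ``x[n] - a*x[n-1]`` with
    ``a = exp(-2*pi*preemphasis_hz / fs)`` flattens the spectral tilt
    above ``preemphasis_hz``; an autoregressive model of order
    ``2 * n_peaks`` (one conjugate pole pair per resonance peak) is then
    fitted by the autocorrelation (Levinson) method, evaluated on a
    uniform grid up to Nyquist, and divided by the pre-emphasis response
    so the envelope describes the original signal.

    Below a few hundred Hz the de-tilted envelope carries a boundary
    artifact of up to ~15 dB (the all-pole fit cannot follow the
    pre-emphasis null at DC); the call energy analysed here lies well
    above that region.
    """
    order = 2 * int(n_peaks)
    x = recording.samples
    if order >= x.size:
        raise ValueError(
            f"model order {order} must be below the sample count {x.size}"
        )
    a_pre = math.exp(-2.0 * math.pi * preemphasis_hz / recording.sample_rate_hz)
    x = x.astype(float) - a_pre * np.concatenate([[0.0], x[:-1]])
    # biased autocorrelation via FFT
    nfft = sfft.next_fast_len(2 * x.size)
    spec = np.abs(sfft.rfft(x, nfft)) ** 2
    r = sfft.irfft(spec)[: order + 1] / x.size
    if r[0] <= 0:
        raise ValueError("silent recording: cannot fit an all-pole model")
    r = r / r[0]
    r[0] += 1e-9  # Tikhonov-style guard against a singular Toeplitz system
    ar = solve_toeplitz((r[:order], r[:order]), -r[1 : order + 1])
    freqs = np.linspace(0.0, recording.nyquist_hz, n_bins)
    _, h = ssig.freqz(
        [1.0], np.concatenate([[1.0], ar]), worN=freqs, fs=recording.sample_rate_hz
    )
    # undo the pre-emphasis tilt so the envelope describes the original
    # signal, not the high-passed one
    _, h_pre = ssig.freqz(
        [1.0, -a_pre], [1.0], worN=freqs, fs=recording.sample_rate_hz
    )
    level = 20.0 * np.log10(np.maximum(np.abs(h), 1e-300)) - 20.0 * np.log10(
        np.maximum(np.abs(h_pre), 1e-300)
    )
    return PowerSpectrum(
        freqs,
        level - level.max(),
        smoothing="lpc",
        smoothing_parameter=float(n_peaks),
    )


def central_segment(
    call_start_s: float, call_end_s: float, fraction: float = 0.5
) -> tuple[float, float]:
    """The window of length ``fraction * duration`` centred at the call
    midpoint — used to sample the steady portion of a call, away from the
    frequency-modulated onset and offset."""
    if not call_end_s > call_start_s:
        raise ValueError("call_end_s must exceed call_start_s")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    mid = 0.5 * (call_start_s + call_end_s)
    half = 0.5 * fraction * (call_end_s - call_start_s)
    return (mid - half, mid + half)


def estimate_fundamental(
    recording: CallRecording,
    segment: tuple[float, float] | None = None,
    search_hz: tuple[float, float] = (500.0, 6000.0),
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.45,
) -> float | None:
    """Mean fundamental frequency over a segment, or None if unvoiced.

    Frame-wise normalised autocorrelation: each 25 ms frame votes with the
    lag of its strongest autocorrelation peak inside the search band
    (parabolic interpolation refines the lag); frames whose peak falls
    below the voicing threshold abstain.  Voted frequencies further than
    20% from their median are discarded as octave/noise errors, and the
    mean of the rest is returned.  Returns ``None`` — never 0 — when no
    frame is voiced.
    """
    fs = recording.sample_rate_hz
    lo_hz, hi_hz = search_hz
    if not 0 < lo_hz < hi_hz <= recording.nyquist_hz:
        raise ValueError("search band must satisfy 0 < lo < hi <= Nyquist")
    if segment is None:
        x = recording.samples
    else:
        i0 = max(0, int(round(segment[0] * fs)))
        i1 = min(recording.samples.size, int(round(segment[1] * fs)))
        if i1 <= i0:
            raise ValueError("segment lies outside the recording")
        x = recording.samples[i0:i1]
    frame_n = int(round(frame_s * fs))
    hop_n = max(1, int(round(hop_s * fs)))
    lag_min = max(2, int(math.floor(fs / hi_hz)))
    lag_max = int(math.ceil(fs / lo_hz))
    if frame_n <= lag_max:
        frame_n = lag_max + 1
    estimates: list[float] = []
    for start in range(0, max(1, x.size - frame_n + 1), hop_n):
        frame = x[start : start + frame_n]
        if frame.size < frame_n:
            break
        frame = frame - frame.mean()
        e0 = float(np.dot(frame, frame))
        if e0 <= 0:
            continue
        nfft = sfft.next_fast_len(2 * frame_n)
        ac = sfft.irfft(np.abs(sfft.rfft(frame, nfft)) ** 2)[: lag_max + 2]
        ac = ac / ac[0]
        window = ac[lag_min : lag_max + 1]
        best = float(window.max())
        if best < voicing_threshold:
            continue
        # a periodic signal peaks equally at every multiple of its period;
        # take the *shortest* near-maximal local-maximum lag to avoid
        # subharmonic (half-frequency) errors
        interior = np.nonzero(
            (ac[lag_min : lag_max + 1] >= ac[lag_min - 1 : lag_max])
            & (ac[lag_min : lag_max + 1] >= ac[lag_min + 1 : lag_max + 2])
            & (window >= 0.9 * best)
        )[0]
        k = (int(interior[0]) if interior.size else int(np.argmax(window))) + lag_min
        # parabolic interpolation around the peak lag
        if 0 < k < ac.size - 1:
            denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
            delta = 0.5 * (ac[k - 1] - ac[k + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        estimates.append(fs / (k + delta))
    if not estimates:
        return None
    arr = np.asarray(estimates)
    med = float(np.median(arr))
    kept = arr[np.abs(arr - med) <= 0.2 * med]
    return float(kept.mean())


def harmonic_amplitudes(
    spectrum: PowerSpectrum,
    fundamental_hz: float,
    band_halfwidth_frac: float = 0.15,
    segment: tuple[float, float] = (float("nan"), float("nan")),
) -> HarmonicProfile:
    """Relative amplitudes of the first three harmonics.

    For k = 1..3 the level is the spectrum maximum inside
    ``k*FF ± band_halfwidth_frac*FF`` — the fractional band tolerates the
    frequency modulation real calls show — referenced to the spectrum's
    global maximum (0 dB).
    """
    if not fundamental_hz > 0:
        raise ValueError("fundamental_hz must be > 0")
    if 3.0 * fundamental_hz >= spectrum.frequencies_hz[-1]:
        raise ValueError(
            "third harmonic exceeds the spectrum range; "
            f"3*{fundamental_hz:.0f} Hz > {spectrum.frequencies_hz[-1]:.0f} Hz"
        )
    ref = spectrum.level_db.max()
    half = band_halfwidth_frac * fundamental_hz
    amps: dict[str, float] = {}
    for k, name in ((1, "FF"), (2, "F2"), (3, "F3")):
        centre = k * fundamental_hz
        mask = np.abs(spectrum.frequencies_hz - centre) <= half
        if not mask.any():
            raise ValueError(f"no spectrum bins in the {name} band at {centre} Hz")
        amps[name] = float(spectrum.level_db[mask].max() - ref)
    return HarmonicProfile(
        fundamental_hz=fundamental_hz, rel_amp_db=amps, segment=segment
    )


def average_spectra(
    spectra: Sequence[PowerSpectrum], domain: str = "db"
) -> PowerSpectrum:
    """Per-bin average of spectra sharing one frequency grid, 0 dB re max.

    ``domain="db"`` averages dB levels (matching how combined call-type
    spectra are usually plotted); ``domain="power"`` averages linear power
    before converting back.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].frequencies_hz
    for s in spectra[1:]:
        if s.frequencies_hz.shape != grid.shape or not np.allclose(
            s.frequencies_hz, grid
        ):
            raise ValueError(
                "spectra must share one frequency grid; resample first"
            )
    levels = np.stack([s.level_db for s in spectra])
    if domain == "db":
        mean = levels.mean(axis=0)
    elif domain == "power":
        mean = 10.0 * np.log10(np.mean(10.0 ** (levels / 10.0), axis=0))
    else:
        raise ValueError(f"domain must be 'db' or 'power', got {domain!r}")
    return PowerSpectrum(grid.copy(), mean - mean.max())


def detect_peaks(
    spectrum: PowerSpectrum,
    min_prominence_db: float = 6.0,
    min_separation_hz: float = 200.0,
) -> list[float]:
    """Spectral peak frequencies, ascending.

    Local maxima with at least ``min_prominence_db`` of prominence,
    greedily pruned (loudest first) so no two returned peaks are closer
    than ``min_separation_hz``.
    """
    idx, props = ssig.find_peaks(
        spectrum.level_db, prominence=min_prominence_db
    )
    if idx.size == 0:
        return []
    order = np.argsort(spectrum.level_db[idx])[::-1]
    kept: list[float] = []
    for i in order:
        f = float(spectrum.frequencies_hz[idx[i]])
        if all(abs(f - g) >= min_separation_hz for g in kept):
            kept.append(f)
    return sorted(kept)
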