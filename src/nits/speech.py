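"""Voice feature extraction for the reading-aloud task.

Pipeline: silence removal by energy thresholding, per-frame fundamental
frequency by five estimators (normalized correlation, pitch estimation
filter, cepstrum, log-harmonic summation, summation of residual
harmonics), mel and gammatone cepstral coefficients, ten spectral-shape
descriptors, a wavelet scattering transform, and assembly of the
per-frame sequence fed to the sequence classifiers.

All extractors are deterministic and operate at the clip's native sample
rate (48 kHz nominal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.fft import dct, fft, ifft, rfft
from scipy.signal import get_window, lfilter

from nits.session_io import AudioClip

_EPS_LOG = 1e-30  # floor before log, never added (keeps gain separation exact)


@dataclass(frozen=True)
class FrameSpec:
    """Short-time analysis framing: 30 ms window, 10 ms hop by default."""

    frame_ms: float = 30.0
    hop_ms: float = 10.0
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not 0 < self.hop_ms <= self.frame_ms:
            raise ValueError("need 0 < hop_ms <= frame_ms")
        if self.window not in ("hamming", "hann"):
            raise ValueError("window must be hamming or hann")

    def sizes(self, rate_hz: int) -> tuple[int, int]:
        return (
            int(round(self.frame_ms * rate_hz / 1000.0)),
            int(round(self.hop_ms * rate_hz / 1000.0)),
        )


def frame_signal(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """(n_frames, frame) view-copy; n_frames = floor((len-frame)/hop)+1."""
    if len(x) < frame:
        raise ValueError("frame longer than clip")
    n = (len(x) - frame) // hop + 1
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _frames(clip: AudioClip, spec: FrameSpec) -> tuple[np.ndarray, np.ndarray, int]:
    frame, hop = spec.sizes(clip.rate_hz)
    fr = frame_signal(clip.samples, frame, hop)
    win = get_window(spec.window, frame, fftbins=True)
    return fr, fr * win, hop


# ---------------------------------------------------------------------------
# Silence removal


def remove_silence(
    clip: AudioClip, threshold_db: float = 40.0, min_segment_ms: float = 100.0, hop_ms: float = 10.0
) -> AudioClip:
    """Keep blocks whose short-time energy is within threshold_db of the peak.

    The clip is cut into non-overlapping hops; a hop survives when its RMS
    energy is less than ``threshold_db`` below the loudest hop.  Runs of
    surviving hops shorter than ``min_segment_ms`` are discarded, and the
    survivors are concatenated.  An entirely silent clip yields an empty
    clip (downstream extractors reject it).
    """
    if len(clip.samples) == 0:
        return AudioClip(samples=np.empty(0), rate_hz=clip.rate_hz)
    hop = max(1, int(round(hop_ms * clip.rate_hz / 1000.0)))
    n = len(clip.samples) // hop
    if n == 0:
        blocks = clip.samples[None, :]
        n = 1
    else:
        blocks = clip.samples[: n * hop].reshape(n, hop)
    rms = np.sqrt((blocks ** 2).mean(axis=1))
    peak = rms.max()
    if peak <= 0:
        return AudioClip(samples=np.empty(0), rate_hz=clip.rate_hz)
    keep = 20.0 * np.log10(np.maximum(rms, _EPS_LOG) / peak) > -threshold_db
    min_blocks = max(1, int(round(min_segment_ms / hop_ms)))
    # zero out runs shorter than the minimum segment
    out = []
    i = 0
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j]:
            j += 1
        if j - i >= min_blocks:
            out.append(clip.samples[i * hop : j * hop])
        i = j
    tail = clip.samples[n * hop :]
    if out and len(tail) and keep[n - 1]:
        out.append(tail)
    samples = np.concatenate(out) if out else np.empty(0)
    return AudioClip(samples=samples, rate_hz=clip.rate_hz)


# ---------------------------------------------------------------------------
# Pitch estimation

PITCH_METHODS = ("ncf", "pef", "cep", "lhs", "srh")


def _parabolic(y: np.ndarray, i: int) -> float:
    """Sub-sample peak refinement by parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def _ncf_frame(x: np.ndarray, rate: int, fmin: float, fmax: float) -> tuple[float, float]:
    lag_min = int(rate / fmax)
    lag_max = min(int(rate / fmin), len(x) - 1)
    if lag_max <= lag_min:
        return 0.0, 0.0
    n = len(x)
    # normalized cross-correlation via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = fft(x, nfft)
    r = np.real(ifft(X * np.conj(X)))[: lag_max + 1]
    e0 = r[0]
    if e0 <= 0:
        return 0.0, 0.0
    cum = np.concatenate([[0.0], np.cumsum(x ** 2)])
    e_lag = cum[n] - cum[: lag_max + 1]  # energy of x[k:] at lag k
    ncf = r / np.sqrt(np.maximum(e0 * e_lag, 1e-20))
    seg = ncf[lag_min : lag_max + 1]
    i = int(np.argmax(seg)) + lag_min
    lag = _parabolic(ncf, i)
    return rate / lag, float(ncf[i])


def _cep_frame(mag: np.ndarray, rate: int, nfft: int, fmin: float, fmax: float) -> float:
    # 60 dB dynamic-range floor suppresses spurious quefrency ripple from
    # the near-zero noise floor between harmonics
    logmag = np.log(np.maximum(mag, mag.max() * 1e-3 + _EPS_LOG))
    ceps = np.real(ifft(np.concatenate([logmag, logmag[-2:0:-1]])))
    q_min = int(rate / fmax)
    q_max = min(int(rate / fmin), len(ceps) // 2 - 1)
    if q_max <= q_min:
        return 0.0
    i = int(np.argmax(ceps[q_min : q_max + 1])) + q_min
    return rate / _parabolic(ceps, i)


def _harmonic_sum(mag: np.ndarray, freqs: np.ndarray, f0_grid: np.ndarray,
                  n_harm: int, log_domain: bool) -> np.ndarray:
    """Harmonic summation with decaying weights (suppresses subharmonics)."""
    if log_domain:
        spec = np.log(np.maximum(mag, mag.max() * 1e-3 + _EPS_LOG))
    else:
        spec = mag
    out = np.zeros(len(f0_grid))
    fmax_bin = freqs[-1]
    for k in range(1, n_harm + 1):
        w = 0.85 ** (k - 1) if log_domain else 1.0 / k
        fk = f0_grid * k
        ok = fk <= fmax_bin
        out[ok] += w * np.interp(fk[ok], freqs, spec)
    return out


def _srh_frame(x: np.ndarray, rate: int, freqs: np.ndarray, f0_grid: np.ndarray,
               nfft: int, order: int = 12) -> np.ndarray:
    # LPC residual amplitude spectrum, then summation of residual harmonics
    r = np.correlate(x, x, mode="full")[len(x) - 1 : len(x) + order]
    try:
        from scipy.linalg import solve_toeplitz

        col = r[:order].copy()
        col[0] *= 1.0 + 1e-9  # ridge for near-singular autocorrelation
        a = solve_toeplitz(col, r[1 : order + 1])
        coeffs = np.concatenate([[1.0], -a])
    except Exception:
        coeffs = np.array([1.0])
    resid = lfilter(coeffs, [1.0], x)
    e = np.abs(rfft(resid, nfft))
    e = e / max(e.max(), _EPS_LOG)
    out = np.zeros(len(f0_grid))
    for k in range(1, 6):
        fk = f0_grid * k
        ok = fk <= freqs[-1]
        out[ok] += np.interp(fk[ok], freqs, e)
        if k >= 2:
            fh = f0_grid * (k - 0.5)
            okh = fh <= freqs[-1]
            out[okh] -= np.interp(fh[okh], freqs, e)
    return out


def pitch(
    clip: AudioClip,
    method: str = "ncf",
    spec: Optional[FrameSpec] = None,
    fmin: float = 50.0,
    fmax: float = 400.0,
    voicing_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame fundamental frequency and voicing flag.

    Voicing is decided by the normalized-autocorrelation peak for every
    method (a frame with no periodicity is unvoiced regardless of the f0
    estimator); f0 itself comes from the selected method.  The default
    pitch frame is 60 ms (several cycles at the 50 Hz floor); spectra are
    zero-padded 4x for harmonic-grid resolution.
    Returns ``(f0_hz, voiced)`` with f0 = nan on unvoiced frames.
    """
    if method not in PITCH_METHODS:
        raise ValueError(f"unknown pitch method {method!r}")
    if len(clip.samples) == 0:
        raise ValueError("empty clip")
    spec = spec or FrameSpec(frame_ms=60.0, hop_ms=10.0)
    raw, windowed, _ = _frames(clip, spec)
    rate = clip.rate_hz
    n_frames, frame = raw.shape
    nfft = int(2 ** np.ceil(np.log2(4 * frame)))
    freqs = np.arange(nfft // 2 + 1) * rate / nfft
    f0_grid = np.arange(fmin, fmax + 1.0, 1.0)
    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    for t in range(n_frames):
        x = raw[t] - raw[t].mean()
        f_ncf, conf = _ncf_frame(x, rate, fmin, fmax)
        voiced[t] = conf > voicing_threshold and fmin <= f_ncf <= fmax * 1.05
        if not voiced[t]:
            continue
        if method == "ncf":
            f0[t] = f_ncf
        elif method == "cep":
            mag = np.abs(rfft(windowed[t], nfft))
            f0[t] = _cep_frame(mag, rate, nfft, fmin, fmax)
        elif method in ("pef", "lhs"):
            mag = np.abs(rfft(windowed[t], nfft))
            hs = _harmonic_sum(mag, freqs, f0_grid, n_harm=5, log_domain=(method == "lhs"))
            f0[t] = f0_grid[int(np.argmax(hs))]
        else:  # srh
            hs = _srh_frame(x, rate, freqs, f0_grid, nfft)
            f0[t] = f0_grid[int(np.argmax(hs))]
    return f0, voiced


# ---------------------------------------------------------------------------
# Cepstral coefficients


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, rate: int, fmin: float = 0.0,
                   fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank on the rfft bin grid, (n_filters, nfft//2+1)."""
    fmax = rate / 2.0 if fmax is None else fmax
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    edges = _mel_to_hz(mels)
    freqs = np.arange(nfft // 2 + 1) * rate / nfft
    fb = np.zeros((n_filters, len(freqs)))
    for i in range(n_filters):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _erb(f):
    return 24.7 * (4.37 * np.asarray(f) / 1000.0 + 1.0)


def gammatone_filterbank(n_filters: int, nfft: int, rate: int, fmin: float = 50.0,
                         fmax: float | None = None) -> np.ndarray:
    """4th-order gammatone magnitude responses at ERB-spaced centers."""
    fmax = rate / 2.0 if fmax is None else fmax
    # ERB-rate scale spacing
    def hz_to_erbrate(f):
        return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f))

    def erbrate_to_hz(e):
        return (10.0 ** (np.asarray(e) / 21.4) - 1.0) / 0.00437

    centers = erbrate_to_hz(np.linspace(hz_to_erbrate(fmin), hz_to_erbrate(fmax), n_filters))
    freqs = np.arange(nfft // 2 + 1) * rate / nfft
    fb = np.zeros((n_filters, len(freqs)))
    for i, fc in enumerate(centers):
        b = 1.019 * _erb(fc)
        fb[i] = (1.0 + ((freqs - fc) / b) ** 2) ** (-2.0)  # |H|^... 4th-order envelope
    return fb


def _cepstra(clip: AudioClip, fb: np.ndarray, n_coeffs: int, spec: FrameSpec,
             nfft: int) -> np.ndarray:
    _, windowed, _ = _frames(clip, spec)
    mag = np.abs(rfft(windowed, nfft, axis=1))
    energies = mag @ fb.T
    logen = np.log(np.maximum(energies, _EPS_LOG))
    cc = dct(logen, type=2, norm="ortho", axis=1)
    return cc[:, :n_coeffs].T  # (n_coeffs, n_frames)


def mfcc(clip: AudioClip, n_coeffs: int = 13, spec: FrameSpec = FrameSpec(),
         n_filters: int = 26) -> np.ndarray:
    """Mel cepstral coefficients, (n_coeffs, n_frames); coefficient 0 kept."""
    if n_coeffs > n_filters:
        raise ValueError("n_coeffs must be <= filter count")
    frame, _ = spec.sizes(clip.rate_hz)
    nfft = int(2 ** np.ceil(np.log2(frame)))
    fb = mel_filterbank(n_filters, nfft, clip.rate_hz)
    return _cepstra(clip, fb, n_coeffs, spec, nfft)


def gtcc(clip: AudioClip, n_coeffs: int = 13, spec: FrameSpec = FrameSpec(),
         n_filters: int = 32) -> np.ndarray:
    """Gammatone cepstral coefficients, (n_coeffs, n_frames)."""
    if n_coeffs > n_filters:
        raise ValueError("n_coeffs must be <= filter count")
    frame, _ = spec.sizes(clip.rate_hz)
    nfft = int(2 ** np.ceil(np.log2(frame)))
    fb = gammatone_filterbank(n_filters, nfft, clip.rate_hz)
    return _cepstra(clip, fb, n_coeffs, spec, nfft)


# ---------------------------------------------------------------------------
# Spectral descriptors

DESCRIPTOR_NAMES = (
    "slope", "skewness", "centroid", "spread", "decrease",
    "kurtosis", "flux", "rolloff", "flatness", "entropy",
)


def _descriptors_of_spectrum(mag: np.ndarray, freqs: np.ndarray,
                             rolloff_pct: float) -> np.ndarray:
    total = mag.sum()
    if total <= 0:
        return np.full(9, np.nan)  # all but flux
    # power weighting for the moments: sidelobe/noise-floor mass is
    # negligible in power, so a pure tone's centroid sits on the tone
    p = mag ** 2 / (mag ** 2).sum()
    centroid = float((freqs * p).sum())
    spread = float(np.sqrt(((freqs - centroid) ** 2 * p).sum()))
    if spread > 0:
        skew = float((((freqs - centroid) / spread) ** 3 * p).sum())
        kurt = float((((freqs - centroid) / spread) ** 4 * p).sum())
    else:
        skew, kurt = 0.0, 0.0
    # least-squares slope of magnitude vs frequency
    fc = freqs - freqs.mean()
    slope = float((fc * (mag - mag.mean())).sum() / (fc ** 2).sum())
    k = np.arange(1, len(mag))
    denom = mag[1:].sum()
    decrease = float(((mag[1:] - mag[0]) / k).sum() / denom) if denom > 0 else 0.0
    cum = np.cumsum(mag)
    ro_idx = int(np.searchsorted(cum, rolloff_pct * cum[-1]))
    rolloff = float(freqs[min(ro_idx, len(freqs) - 1)])
    power = mag ** 2
    am = power.mean()
    gm = float(np.exp(np.mean(np.log(np.maximum(power, _EPS_LOG)))))
    flatness = gm / am if am > 0 else 0.0
    pp = power / power.sum()
    entropy = float(-(pp * np.log(np.maximum(pp, _EPS_LOG))).sum() / np.log(len(pp)))
    return np.array([slope, skew, centroid, spread, decrease, kurt, rolloff, flatness, entropy])


def spectral_descriptors(clip: AudioClip, spec: FrameSpec = FrameSpec(),
                         rolloff_pct: float = 0.85) -> np.ndarray:
    """Per-frame 10-vector of spectral-shape descriptors, (n_frames, 10).

    Column order follows ``DESCRIPTOR_NAMES``.  Flux is the L2 change of
    the normalized magnitude spectrum between consecutive frames (0 for
    the first frame); an all-zero frame yields NaNs.
    """
    _, windowed, _ = _frames(clip, spec)
    nfft = int(2 ** np.ceil(np.log2(windowed.shape[1])))
    mag = np.abs(rfft(windowed, nfft, axis=1))
    freqs = np.arange(nfft // 2 + 1) * clip.rate_hz / nfft
    n = len(mag)
    out = np.empty((n, 10))
    prev = None
    for t in range(n):
        d9 = _descriptors_of_spectrum(mag[t], freqs, rolloff_pct)
        tot = mag[t].sum()
        norm = mag[t] / tot if tot > 0 else mag[t]
        flux = float(np.linalg.norm(norm - prev)) if prev is not None else 0.0
        prev = norm
        out[t] = [d9[0], d9[1], d9[2], d9[3], d9[4], d9[5], flux, d9[6], d9[7], d9[8]]
    return out


def mean_spectrum_descriptors(clip: AudioClip, spec: FrameSpec = FrameSpec(),
                              rolloff_pct: float = 0.85) -> dict[str, float]:
    """Descriptors of the frame-averaged power spectrum (flux excluded).

    Averaging the periodogram across frames before taking the descriptor
    stabilizes flatness/entropy for noise-like signals (a single frame of
    white noise has chi-square bin scatter that biases the geometric mean
    well below 1).
    """
    _, windowed, _ = _frames(clip, spec)
    nfft = int(2 ** np.ceil(np.log2(windowed.shape[1])))
    power = (np.abs(rfft(windowed, nfft, axis=1)) ** 2).mean(axis=0)
    freqs = np.arange(nfft // 2 + 1) * clip.rate_hz / nfft
    d9 = _descriptors_of_spectrum(np.sqrt(power), freqs, rolloff_pct)
    names = [n for n in DESCRIPTOR_NAMES if n != "flux"]
    vals = dict(zip(names, d9))
    # flatness/entropy of the averaged *power* spectrum itself
    am = power.mean()
    gm = float(np.exp(np.mean(np.log(np.maximum(power, _EPS_LOG)))))
    vals["flatness"] = gm / am if am > 0 else 0.0
    pp = power / power.sum()
    vals["entropy"] = float(-(pp * np.log(np.maximum(pp, _EPS_LOG))).sum() / np.log(len(pp)))
    return vals


# ---------------------------------------------------------------------------
# Wavelet scattering transform


@dataclass(frozen=True)
class WstConfig:
    """Scattering configuration: 0.5 s invariance, Q1=8, Q2=1, 8 windows."""

    invariance_s: float = 0.5
    q1: int = 8
    q2: int = 1
    n_windows: int = 8
    log_transform: bool = True
    log_eps: float = 1e-10
    fmin_hz: float = 50.0
    fmax_frac: float = 0.35  # top center frequency as fraction of the rate

    def __post_init__(self) -> None:
        if min(self.invariance_s, self.q1, self.q2, self.n_windows) <= 0:
            raise ValueError("WST parameters must be positive")


def _morlet_bank(n: int, rate: int, q: int, fmin: float, fmax: float) -> np.ndarray:
    """Analytic Gaussian (Morlet-envelope) filters on the length-n FFT grid."""
    freqs = np.fft.fftfreq(n, d=1.0 / rate)
    centers = []
    f = fmax
    while f >= fmin:
        centers.append(f)
        f /= 2.0 ** (1.0 / q)
    bank = np.zeros((len(centers), n))
    r = 1.0 - 2.0 ** (-1.0 / q)  # relative bandwidth per filter
    for i, fc in enumerate(centers):
        sigma = max(fc * r, 1e-6)
        bank[i] = np.exp(-((freqs - fc) ** 2) / (2.0 * sigma ** 2)) * (freqs > 0) * 2.0
    return bank


def _lowpass(n: int, rate: int, invariance_s: float) -> np.ndarray:
    freqs = np.fft.fftfreq(n, d=1.0 / rate)
    sigma = 1.0 / (2.0 * np.pi * invariance_s / 4.0)  # ~T/4 time support
    return np.exp(-(freqs ** 2) / (2.0 * sigma ** 2))


def wst_features(clip: AudioClip, config: WstConfig = WstConfig()) -> np.ndarray:
    """Order-0/1/2 scattering coefficients, (n_channels, n_windows).

    First-order filters: ``q1`` wavelets per octave from ``fmax_frac`` of
    the rate down to ``fmin_hz``; second-order: ``q2`` per octave applied
    to each first-order envelope for center frequencies below half the
    parent's.  Envelopes are lowpass-averaged at the invariance scale and
    pooled into ``n_windows`` equal time windows, then log-transformed.
    """
    n = len(clip.samples)
    rate = clip.rate_hz
    if n < int(config.invariance_s * rate):
        raise ValueError("clip shorter than the invariance window")
    X = fft(clip.samples)
    phi = _lowpass(n, rate, config.invariance_s)
    fmax = config.fmax_frac * rate
    bank1 = _morlet_bank(n, rate, config.q1, config.fmin_hz, fmax)
    c1 = fmax * 2.0 ** (-np.arange(bank1.shape[0]) / config.q1)
    # second-order filters act on first-order envelopes, whose modulation
    # content lives well below the carrier; envelopes are decimated to a
    # ~8 kHz rate (by spectral cropping) before the second filter bank
    decim = max(1, n // max(1, int(n * 8000 / rate)))
    n2 = n // decim
    rate2 = rate // decim
    fmax2 = min(2000.0, fmax / 2.0)
    bank2 = _morlet_bank(n2, rate2, config.q2, config.fmin_hz, fmax2)
    c2 = fmax2 * 2.0 ** (-np.arange(bank2.shape[0]) / config.q2)
    phi2 = _lowpass(n2, rate2, config.invariance_s)

    def pool(env_fft: np.ndarray, m: int, lowpass: np.ndarray) -> np.ndarray:
        sm = np.real(ifft(env_fft * lowpass))
        edges = np.linspace(0, m, config.n_windows + 1).astype(int)
        return np.array([sm[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])

    rows = [pool(X, n, phi)]  # order 0
    half2 = n2 // 2
    for i in range(bank1.shape[0]):
        u1 = np.abs(ifft(X * bank1[i]))
        U1 = fft(u1)
        rows.append(pool(U1, n, phi))
        # decimate the envelope: keep the low-frequency spectrum block
        U1d = np.concatenate([U1[: half2], U1[n - (n2 - half2):]]) / decim
        for j in range(bank2.shape[0]):
            if c2[j] < c1[i] / 2.0:
                u2 = np.abs(ifft(U1d * bank2[j]))
                rows.append(pool(fft(u2), n2, phi2))
    S = np.vstack(rows)
    if config.log_transform:
        S = np.log(np.abs(S) + config.log_eps)
    return S


# ---------------------------------------------------------------------------
# Sequence assembly


def assemble_speech_sequence(
    clip: AudioClip,
    spec: FrameSpec = FrameSpec(),
    pitch_method: str = "ncf",
    n_mfcc: int = 13,
    n_gtcc: int = 13,
    zscore: bool = True,
) -> np.ndarray:
    """Per-frame feature matrix for the sequence classifier, (n_frames, 28).

    Default preset: pitch (1) + MFCC (13) + GTCC (13) + spectral skewness
    (1).  Unvoiced pitch frames carry 0 before normalization.  Columns are
    z-scored over the sequence; constant columns become zeros.
    """
    if len(clip.samples) == 0:
        raise ValueError("empty voiced content")
    f0, voiced = pitch(clip, method=pitch_method, spec=spec)
    f0 = np.where(voiced, np.nan_to_num(f0), 0.0)
    m = mfcc(clip, n_coeffs=n_mfcc, spec=spec).T
    g = gtcc(clip, n_coeffs=n_gtcc, spec=spec).T
    skew = spectral_descriptors(clip, spec)[:, DESCRIPTOR_NAMES.index("skewness")]
    skew = np.nan_to_num(skew)
    n = min(len(f0), len(m), len(g), len(skew))
    M = np.column_stack([f0[:n], m[:n], g[:n], skew[:n]])
    if zscore:
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        M = (M - mu) / sd
    return M
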