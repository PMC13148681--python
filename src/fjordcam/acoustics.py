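"""Long-term mean spectrogram for multi-day audio.

Short Welch spectra (Hann window, 50% overlap) are averaged within coarse
time bins (10 s by default) and restricted to a frequency band, producing a
time–frequency matrix compact enough to display days of 96-kHz audio at
once. Power is in dB referenced to digital full scale (no hydrophone
calibration is applied).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = ["SpectrogramMatrix", "long_term_spectrogram", "read_wav", "write_wav"]

logger = logging.getLogger(__name__)


@dataclass
class SpectrogramMatrix:
    """Long-term spectrogram: power[t_bin, f_bin] in dB re full scale."""

    time_bins_s: np.ndarray      # bin start times
    frequencies_hz: np.ndarray
    power_db: np.ndarray         # (n_time, n_freq)
    fft_size: int
    band_hz: tuple
    time_resolution_s: float

    def peak_frequency(self, t_bin: int = 0) -> float:
        """Frequency of maximum power in one time bin."""
        return float(self.frequencies_hz[int(np.argmax(self.power_db[t_bin]))])

    def save(self, path: str | Path) -> None:
        """CSV matrix plus a JSON header."""
        path = Path(path)
        header = {
            "fft_size": self.fft_size,
            "band_hz": list(self.band_hz),
            "time_resolution_s": self.time_resolution_s,
        }
        path.with_suffix(".json").write_text(json.dumps(header))
        import pandas as pd

        df = pd.DataFrame(
            self.power_db, index=self.time_bins_s, columns=self.frequencies_hz
        )
        df.to_csv(path, index_label="time_s")


def long_term_spectrogram(
    audio: np.ndarray,
    fs: float,
    fft_size: int = 1024,
    time_resolution_s: float = 10.0,
    band_hz: tuple = (20.0, 43000.0),
) -> SpectrogramMatrix:
    """Mean Welch spectrum per coarse time bin, restricted to a band.

    Within each ``time_resolution_s`` bin the magnitude-squared FFTs of
    Hann-windowed, 50%-overlapping segments of ``fft_size`` samples are
    averaged; rows are restricted to ``band_hz`` (clipped to Nyquist with a
    warning if needed) and converted to dB.
    """
    audio = np.asarray(audio, dtype=np.float64)
    lo, hi = band_hz
    if fs <= 2 * lo:
        raise ValueError("sampling rate too low for the requested band")
    if hi > fs / 2:
        logger.warning("band upper edge %.0f Hz above Nyquist %.0f Hz; clipping", hi, fs / 2)
        hi = fs / 2
    samples_per_bin = int(round(time_resolution_s * fs))
    if audio.size < samples_per_bin:
        raise ValueError("audio shorter than one time bin")
    n_bins = audio.size // samples_per_bin

    freqs = np.fft.rfftfreq(fft_size, d=1.0 / fs)
    keep = (freqs >= lo) & (freqs <= hi)
    power = np.empty((n_bins, int(keep.sum())))
    for k in range(n_bins):
        chunk = audio[k * samples_per_bin:(k + 1) * samples_per_bin]
        f, pxx = signal.welch(
            chunk,
            fs=fs,
            window="hann",
            nperseg=fft_size,
            noverlap=fft_size // 2,
            detrend=False,
            scaling="density",
        )
        power[k] = pxx[keep]
    power_db = 10.0 * np.log10(np.maximum(power, 1e-20))
    return SpectrogramMatrix(
        time_bins_s=np.arange(n_bins) * time_resolution_s,
        frequencies_hz=freqs[keep],
        power_db=power_db,
        fft_size=fft_size,
        band_hz=(lo, hi),
        time_resolution_s=time_resolution_s,
    )


def write_wav(path: str | Path, audio: np.ndarray, fs: float) -> None:
    """Write a waveform in [−1, 1] as PCM 16-bit WAV."""
    x = np.clip(np.asarray(audio, dtype=np.float64), -1.0, 1.0)
    wavfile.write(str(path), int(fs), (x * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file; integer PCM is rescaled to [−1, 1] floats."""
    fs, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    return np.asarray(data, dtype=np.float64), float(fs)
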