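"""Raw multichannel EEG clip container, windowing, and EDF ingestion.

An :class:`EEGClip` is the unit of analysis: a fixed-duration block of
scalp EEG held as a ``channels x samples`` matrix (microvolts) together
with its sampling rate and montage labels.  One clip becomes one graph
instance downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGClip", "window_clip", "read_edf"]

DEFAULT_WINDOW_SECONDS = 12.0


@dataclass(frozen=True)
class EEGClip:
    """A channels x samples block of EEG signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Per-channel voltage traces in microvolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_labels : tuple of str
        Unique montage names, one per row of ``signal``.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple = field(default=())

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if sig.shape[0] < 2 or sig.shape[1] < 2:
            raise ValueError("clip needs at least 2 channels and 2 samples")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        labels = tuple(self.channel_labels) or tuple(
            f"CH{i}" for i in range(sig.shape[0])
        )
        if len(labels) != sig.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {sig.shape[0]} channels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.n_samples / self.fs


def window_clip(clip: EEGClip, duration: float = DEFAULT_WINDOW_SECONDS) -> list:
    """Split a recording into consecutive non-overlapping clips.

    Windows are ``duration`` seconds long; a trailing remainder shorter
    than one window is dropped.
    """
    if duration <= 0:
        raise ValueError("window duration must be positive")
    step = int(round(duration * clip.fs))
    if step < 2:
        raise ValueError("window shorter than 2 samples")
    n_windows = clip.n_samples // step
    return [
        EEGClip(clip.signal[:, i * step : (i + 1) * step], clip.fs, clip.channel_labels)
        for i in range(n_windows)
    ]


def read_edf(path, channels=None) -> EEGClip:
    """Read a European Data Format recording into an :class:`EEGClip`.

    Thin hook over :func:`mne.io.read_raw_edf`; volts are rescaled to
    microvolts.  ``channels`` optionally restricts and orders the montage.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw = raw.pick(list(channels))
    data = raw.get_data() * 1e6
    return EEGClip(data, float(raw.info["sfreq"]), tuple(raw.ch_names))
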