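"""Record container and signal preprocessing.

Raw clinical records arrive at 500 Hz with lengths from 6 s to 60 s.  Before
batching, each record is downsampled (anti-aliased) to the training rate —
250 Hz in the reference protocol — and cropped or zero-padded to a fixed
duration so a convolutional network sees a uniform input shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = ["EcgRecord", "resample", "fix_length", "preprocess"]


@dataclass
class EcgRecord:
    """One multichannel ECG: (leads, samples) in millivolts at ``rate`` Hz."""

    record_id: str
    signal: np.ndarray
    rate: float
    main_labels: set[str] = field(default_factory=set)
    aux_labels: set[str] = field(default_factory=set)
    fold: int | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (leads, samples) matrix")
        if self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise ValueError("signal needs at least one lead and one sample")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


def resample(r: EcgRecord, target_rate: float) -> EcgRecord:
    """Downsample with anti-alias filtering; duration preserved to one sample.

    Only downsampling (or the identity) is supported: the training protocol
    never upsamples, and silently interpolating would hide a configuration
    mistake.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate > r.rate:
        raise ValueError(
            f"upsampling {r.rate} Hz -> {target_rate} Hz is not supported")
    if target_rate == r.rate:
        return replace(r, signal=r.signal.copy())
    # polyphase resampling with the rate ratio in lowest terms
    from math import gcd
    num, den = int(round(target_rate * 1000)), int(round(r.rate * 1000))
    g = gcd(num, den)
    up, down = num // g, den // g
    out = sps.resample_poly(r.signal, up, down, axis=1)
    n_expected = int(round(r.n_samples * target_rate / r.rate))
    out = out[:, :n_expected]
    if out.shape[1] < n_expected:
        out = np.pad(out, ((0, 0), (0, n_expected - out.shape[1])))
    if not np.isfinite(out).all():
        raise ValueError("non-finite values after resampling")
    return replace(r, signal=out, rate=target_rate)


def fix_length(r: EcgRecord, target_seconds: float) -> EcgRecord:
    """Crop to, or zero-pad up to, exactly ``target_seconds * rate`` samples.

    Long records keep their first ``target_seconds``; short ones are padded
    with trailing zeros. Labels and rate are unchanged.
    """
    if target_seconds <= 0:
        raise ValueError("target duration must be positive")
    n_target = int(round(target_seconds * r.rate))
    if r.n_samples >= n_target:
        out = r.signal[:, :n_target].copy()
    else:
        out = np.pad(r.signal, ((0, 0), (0, n_target - r.n_samples)))
    return replace(r, signal=out)


def preprocess(r: EcgRecord, target_rate: float = 250.0,
               target_seconds: float = 60.0) -> EcgRecord:
    """The standard pipeline: resample then length-normalize."""
    return fix_length(resample(r, target_rate), target_seconds)
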