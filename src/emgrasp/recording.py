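"""The labelled multichannel surface-EMG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAMPLE_RATE_HZ = 1000

EXTRINSIC = "extrinsic"
INTRINSIC = "intrinsic"

MAX_CHANNELS = 12  # 8 extrinsic forearm + 4 intrinsic hand electrode pairs


def default_roles(n_extrinsic: int = 8, n_intrinsic: int = 4) -> tuple[str, ...]:
    return (EXTRINSIC,) * n_extrinsic + (INTRINSIC,) * n_intrinsic


@dataclass
class EmgRecording:
    """A surface-EMG recording sampled at 1000 Hz with per-sample labels.

    Attributes
    ----------
    samples
        ``(n_samples, n_channels)`` signed amplitudes (arbitrary units).
        One row per millisecond.
    channel_roles
        Per-channel ``"extrinsic"`` (forearm) or ``"intrinsic"`` (hand) tag.
    labels
        Per-sample motion-class identifier.
    wrist_condition
        Per-recording wrist tag, e.g. ``"static:neutral"``,
        ``"dynamic:flexion-extension:forward"`` or
        ``"hybrid:pronation-supination:reverse"``.
    meta
        Free-form provenance (repetition index, protocol kind, seed, ...).
    """

    samples: np.ndarray
    channel_roles: tuple[str, ...]
    labels: np.ndarray
    wrist_condition: str
    sample_rate_hz: int = SAMPLE_RATE_HZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.labels = np.asarray(self.labels)
        self.channel_roles = tuple(self.channel_roles)
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise ValueError(f"sample_rate_hz must be {SAMPLE_RATE_HZ}, got {self.sample_rate_hz}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x channels) array")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} != number of samples {self.samples.shape[0]}"
            )
        if len(self.channel_roles) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for {self.samples.shape[1]} channels"
            )
        if self.samples.shape[1] > MAX_CHANNELS:
            raise ValueError(f"at most {MAX_CHANNELS} channels supported")
        bad = set(self.channel_roles) - {EXTRINSIC, INTRINSIC}
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> int:
        return self.n_samples  # one sample per millisecond at 1000 Hz

    def channel_indices(self, placement: str) -> np.ndarray:
        """Channel indices for ``"extrinsic_only"``, ``"intrinsic_only"`` or ``"both"``."""
        roles = np.asarray(self.channel_roles)
        if placement == "both":
            return np.arange(self.n_channels)
        if placement == "extrinsic_only":
            return np.flatnonzero(roles == EXTRINSIC)
        if placement == "intrinsic_only":
            return np.flatnonzero(roles == INTRINSIC)
        raise ValueError(
            f"unknown placement {placement!r}; expected 'extrinsic_only', 'intrinsic_only' or 'both'"
        )
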