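"""Shared domain types and error classes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Electrode labels of the Emotiv EPOC X headset, in device order.
EPOC_X_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Ad topics whose shock-style versions use graphic imagery (road-safety ads);
#: the alpha-suppression (discomfort) effect is planted only for these.
GRAPHIC_TOPICS: tuple[str, ...] = ("seatbelt", "helmet")

VALID_TOPICS: tuple[str, ...] = ("seatbelt", "helmet", "water", "electricity")
VALID_STYLES: tuple[str, ...] = ("shock", "comic")


class ParameterError(ValueError):
    """An argument or configuration value is outside its valid range."""


class StructuralError(ValueError):
    """Input data violates a structural contract (e.g. malformed marker track)."""


@dataclass(frozen=True)
class AdSpec:
    """One advertisement stimulus: identity, topic, storytelling style, duration."""

    ad_id: str
    topic: str
    style: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.topic not in VALID_TOPICS:
            raise ParameterError(f"unknown topic {self.topic!r}; expected one of {VALID_TOPICS}")
        if self.style not in VALID_STYLES:
            raise ParameterError(f"unknown style {self.style!r}; expected one of {VALID_STYLES}")
        if not self.duration_s > 0:
            raise ParameterError(f"ad {self.ad_id!r}: duration must be positive, got {self.duration_s}")


@dataclass
class Recording:
    """One subject's continuous multi-channel EEG session.

    ``data`` is a (channels, samples) float array in microvolt scale and
    ``marker`` a per-sample integer track that is 0 everywhere except for a 1
    at each stimulus onset and offset (the Emotiv/PsychoPy marker convention).
    ``stimulus_order`` lists ad ids in the order they were shown; marker pairs
    are matched to it positionally.
    """

    subject_id: str
    sampling_rate: float
    data: np.ndarray
    marker: np.ndarray
    channel_labels: tuple[str, ...] = EPOC_X_CHANNELS
    stimulus_order: Optional[tuple[str, ...]] = None
    clean_data: Optional[np.ndarray] = None  # artifact-free copy, if kept
    blink_source: Optional[np.ndarray] = None  # ocular artifact time course, if kept

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.marker = np.asarray(self.marker)
        if self.data.ndim != 2:
            raise StructuralError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise StructuralError(
                f"data has {self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if self.marker.shape != (self.data.shape[1],):
            raise StructuralError("marker length must equal the number of samples")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class StimulusEpoch:
    """The EEG segment recorded while one subject watched one ad."""

    subject_id: str
    ad_id: str
    topic: str
    style: str
    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = EPOC_X_CHANNELS
    rating: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise StructuralError("epoch data must be (channels x samples)")
        if self.rating is not None and not 1 <= int(self.rating) <= 10:
            raise ParameterError(f"rating must be in [1, 10], got {self.rating}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class CleanEpoch(StimulusEpoch):
    """A preprocessed epoch plus a record of what was done to it."""

    provenance: list = field(default_factory=list)
    removed_components: tuple[int, ...] = ()
    repaired_fraction: float = 0.0
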