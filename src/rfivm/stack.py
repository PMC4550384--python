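"""Core in-memory containers for multichannel time-lapse data.

``ImageStack`` holds a ``(time, channel, row, column)`` intensity array
with named channel roles (e.g. ``tumor`` for the constitutive
fluorophore, ``dextran`` / ``albumin`` for circulating tracers) and frame
timestamps.  ``BinaryMask`` is a boolean region together with the
provenance of the thresholding / morphology steps that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ChannelError(KeyError):
    """Raised when a requested channel role is absent from a stack."""


class ShapeError(ValueError):
    """Raised when masks or frames with incompatible shapes are combined."""


DEFAULT_CHANNEL_ROLES = ("tumor", "dextran", "albumin")


@dataclass
class ImageStack:
    """Time-lapse stack of shape ``(n_frames, n_channels, rows, cols)``."""

    frames: np.ndarray
    channel_roles: tuple[str, ...] = DEFAULT_CHANNEL_ROLES
    timestamps_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 4:
            raise ShapeError(
                f"frames must be 4-D (time, channel, row, col), got {frames.shape}"
            )
        if np.any(frames < 0):
            raise ValueError("intensities must be nonnegative")
        self.frames = frames
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != frames.shape[1]:
            raise ShapeError(
                f"{len(self.channel_roles)} channel roles for "
                f"{frames.shape[1]} channels"
            )
        if self.timestamps_s is None:
            self.timestamps_s = np.arange(frames.shape[0], dtype=float)
        else:
            self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.timestamps_s.shape != (frames.shape[0],):
            raise ShapeError("one timestamp per frame required")
        if frames.shape[0] > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise ChannelError(
                f"channel role {role!r} not in {self.channel_roles}"
            ) from None

    def channel(self, role: str) -> np.ndarray:
        """All frames of one channel, shape ``(n_frames, rows, cols)``."""
        return self.frames[:, self.channel_index(role)]

    def frame(self, idx: int, role: str) -> np.ndarray:
        return self.frames[idx, self.channel_index(role)]


@dataclass
class BinaryMask:
    """Boolean pixel region with provenance of how it was produced."""

    pixels: np.ndarray
    source_channel: str = ""
    threshold_value: float | None = None
    morphology_trace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got shape {self.pixels.shape}")

    @property
    def area(self) -> int:
        """Number of set pixels."""
        return int(np.count_nonzero(self.pixels))

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.pixels & other.pixels)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.pixels | other.pixels)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.pixels)

    def _check(self, other: "BinaryMask") -> None:
        if self.pixels.shape != other.pixels.shape:
            raise ShapeError(
                f"mask shapes differ: {self.pixels.shape} vs {other.pixels.shape}"
            )
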