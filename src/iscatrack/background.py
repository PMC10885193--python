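"""Ratiometric background removal for interferometric movies.

In iSCAT the static scattering of the substrate (here an hBN flake and
its bright edges) dwarfs the signal of a single binding molecule.  The
standard remedy is temporal: estimate a per-pixel background from a
running window of preceding frames and express each frame as the
dimensionless ratiometric contrast ``(I - B) / B``, which is signed and
fluctuates around zero on empty surface.

The background of frame ``t`` is computed from the ``window`` frames
*strictly before* ``t`` so that a short-lived particle never contributes
to the background it is measured against — important because single-frame
binding events are a real signal class here.  The first ``window`` frames
have no defined background and are dropped; downstream frame indices are
offset by :attr:`ContrastStack.valid_frame_offset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateBackgroundError,
    InvalidParameterError,
    InvalidWindowError,
)

__all__ = [
    "MovieStack",
    "ContrastStack",
    "running_background",
    "ratiometric_contrast",
    "contrast_stack",
]


@dataclass
class MovieStack:
    """A time-ordered stack of raw intensity frames.

    Attributes
    ----------
    frames:
        ``(T, H, W)`` array of non-negative intensities.
    pixel_nm:
        Pixel pitch in nm.
    frame_rate_hz:
        Acquisition rate in Hz.
    """

    frames: np.ndarray
    pixel_nm: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidParameterError(
                f"frames must be a (T, H, W) stack with T >= 1, got shape "
                f"{self.frames.shape}"
            )
        if np.any(self.frames < 0) or not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("intensities must be finite and >= 0")
        if self.pixel_nm <= 0:
            raise InvalidParameterError(f"pixel_nm must be > 0, got {self.pixel_nm}")
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError(
                f"frame_rate_hz must be > 0, got {self.frame_rate_hz}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz


@dataclass
class ContrastStack:
    """Signed ratiometric contrast frames ``(I - B) / B``.

    ``frames[i]`` is the contrast of raw frame ``i + valid_frame_offset``.
    Pixels where the background was zero are invalid: their contrast is
    stored as 0 and flagged in :attr:`invalid`, and detection excludes
    them.
    """

    frames: np.ndarray
    valid_frame_offset: int
    pixel_nm: float
    frame_rate_hz: float
    invalid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(np.float64)
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("contrast must be finite everywhere")
        if self.valid_frame_offset < 0:
            raise InvalidParameterError("valid_frame_offset must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz


def running_background(
    stack: MovieStack, window: int, mode: str = "median", stride: int = 1
) -> np.ndarray:
    """Per-pixel running background over the preceding ``window`` frames.

    Returns a ``(T - window, H, W)`` array whose slice ``i`` is the
    background of raw frame ``i + window``, i.e. the per-pixel mean or
    median of raw frames ``[i, i + window)``.

    Parameters
    ----------
    stack:
        Input movie.
    window:
        Number of strictly-preceding frames averaged; ``1 <= window < T``.
        The window must comfortably exceed the longest particle dwell:
        a molecule occupying more than half the window contaminates the
        median, leaving an inverted "ghost" blob after it departs.
    mode:
        ``"mean"`` (running average) or ``"median"`` (robust to transient
        particles; a blob present in fewer than half the window frames
        leaves the median untouched).
    stride:
        Recompute the median only every ``stride`` frames and reuse it
        in between (1 = exact per-frame background).  The scattering
        background is static up to slow drift, so a small stride loses
        nothing while cutting the dominant cost of long-window medians.
    """
    T = stack.n_frames
    if not 1 <= window < T:
        raise InvalidWindowError(
            f"window must satisfy 1 <= window < n_frames ({T}), got {window}"
        )
    if stride < 1:
        raise InvalidParameterError(f"stride must be >= 1, got {stride}")
    frames = stack.frames
    if mode == "mean":
        # cumulative-sum sliding mean: O(T*H*W)
        csum = np.cumsum(frames, axis=0, dtype=np.float64)
        upper = csum[window - 1 : T - 1]
        lower = np.concatenate(
            [np.zeros((1,) + frames.shape[1:]), csum[: T - window - 1]], axis=0
        )
        return (upper - lower) / window
    if mode == "median":
        H, W = frames.shape[1:]
        # pixel-major layout: each row is one pixel's time series, so the
        # window slice handed to the median is (nearly) contiguous
        series = np.ascontiguousarray(frames.reshape(T, H * W).T)
        out = np.empty((T - window, H, W), dtype=frames.dtype)
        for t in range(window, T, stride):
            bg = np.median(series[:, t - window : t], axis=1).reshape(H, W)
            out[t - window : min(t - window + stride, T - window)] = bg
        return out
    raise InvalidParameterError(f"mode must be 'mean' or 'median', got {mode!r}")


def ratiometric_contrast(stack: MovieStack, background: np.ndarray) -> ContrastStack:
    """Contrast ``(I - B) / B`` of the last ``len(background)`` frames.

    ``background[i]`` is paired with raw frame ``i + (T - len(background))``,
    matching the alignment produced by :func:`running_background`.
    Zero-background pixels are flagged invalid rather than propagated as
    infinities.
    """
    background = np.asarray(background)
    if not np.issubdtype(background.dtype, np.floating):
        background = background.astype(np.float64)
    if background.ndim != 3 or background.shape[1:] != stack.frames.shape[1:]:
        raise InvalidParameterError(
            f"background shape {background.shape} does not match movie frames "
            f"{stack.frames.shape}"
        )
    if background.shape[0] > stack.n_frames:
        raise InvalidParameterError("background has more frames than the movie")
    if not np.any(background > 0):
        raise DegenerateBackgroundError("background is zero everywhere")
    offset = stack.n_frames - background.shape[0]
    raw = stack.frames[offset:]
    invalid = background <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = (raw - background) / background
    contrast[invalid] = 0.0
    return ContrastStack(
        frames=contrast,
        valid_frame_offset=offset,
        pixel_nm=stack.pixel_nm,
        frame_rate_hz=stack.frame_rate_hz,
        invalid=invalid if invalid.any() else None,
    )


def contrast_stack(
    stack: MovieStack, window: int = 75, mode: str = "median", stride: int = 1
) -> ContrastStack:
    """Convenience: running background followed by ratiometric contrast."""
    return ratiometric_contrast(stack, running_background(stack, window, mode, stride))
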