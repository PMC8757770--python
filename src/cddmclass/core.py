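"""Core data model for current density distribution maps (CDDMs).

A CDDM is a pair of same-shape real grids sampled over the myocardium:

* ``magnitude`` — current density per node, normalized so that the maximum
  over the grid is exactly 1 (the "brightness" of the rendered map);
* ``angle`` — direction of the current density vector per node, stored in
  radians wrapped into the half-open interval (−π, π].

The computational grid defaults to 10×10, so the stage-1 correlation vectors
have length n = 100.  Both dimensions must be even because the stage-2
features are computed on the four equal quadrants of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import HeartStateLabel

TWO_PI = 2.0 * np.pi


class DegenerateMapError(ValueError):
    """Raised for an all-zero magnitude grid, which cannot be normalized."""


class MapValidationError(ValueError):
    """Raised for non-finite or negative magnitudes, or bad grid shapes."""


@dataclass(frozen=True)
class GridConfig:
    """Grid geometry; ``stage1_vector_length`` is the flattened length n."""

    height: int = 10
    width: int = 10

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise MapValidationError("grid must be at least 2x2")
        if self.height % 2 or self.width % 2:
            raise MapValidationError(
                f"grid dimensions must be even for quadrant splitting, "
                f"got {self.height}x{self.width}"
            )

    @property
    def stage1_vector_length(self) -> int:
        return self.height * self.width

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


DEFAULT_GRID = GridConfig()


def wrap_angle(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (radians) into (−π, π].

    The upper endpoint is closed: π maps to π, −π maps to π, 2π maps to 0.
    """
    a = np.asarray(angle, dtype=float)
    wrapped = a - TWO_PI * np.ceil((a - np.pi) / TWO_PI)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def normalize_map(raw_magnitude: np.ndarray) -> np.ndarray:
    """Divide a non-negative magnitude grid elementwise by its maximum.

    The result has maximum exactly 1 and the same shape as the input.

    Raises
    ------
    DegenerateMapError
        If every element is zero (no scale to normalize by).
    MapValidationError
        If any element is negative or non-finite.
    """
    mag = np.asarray(raw_magnitude, dtype=float)
    if not np.all(np.isfinite(mag)):
        raise MapValidationError("magnitude grid contains non-finite values")
    if np.any(mag < 0):
        raise MapValidationError("magnitude grid contains negative values")
    peak = mag.max() if mag.size else 0.0
    if peak == 0.0:
        raise DegenerateMapError("all-zero magnitude grid cannot be normalized")
    return mag / peak


@dataclass
class CDDM:
    """One current density distribution map (magnitude grid + angle grid).

    Parameters
    ----------
    magnitude
        H×W non-negative grid; divided by its maximum on construction, so
        stored magnitudes always peak at exactly 1.
    angle
        H×W grid of directions in radians; wrapped into (−π, π] on
        construction.
    label
        Optional heart-state class of the subject.
    map_id
        Identifier used in manifests and prediction tables.
    """

    magnitude: np.ndarray
    angle: np.ndarray
    label: HeartStateLabel | None = None
    map_id: str = ""

    def __post_init__(self) -> None:
        self.magnitude = normalize_map(self.magnitude)
        self.angle = np.asarray(self.angle, dtype=float)
        if not np.all(np.isfinite(self.angle)):
            raise MapValidationError("angle grid contains non-finite values")
        if self.magnitude.shape != self.angle.shape:
            raise MapValidationError(
                f"magnitude shape {self.magnitude.shape} != "
                f"angle shape {self.angle.shape}"
            )
        h, w = self.magnitude.shape
        if h < 2 or w < 2 or h % 2 or w % 2:
            raise MapValidationError(
                f"map grid must be even-sized and at least 2x2, got {h}x{w}"
            )
        self.angle = wrap_angle(self.angle)

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def split_quadrants(cddm: CDDM) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a map into four equal quarters.

    Returns ``[(mag, ang), ...]`` in fixed row-major order with row 0 at the
    top: Q1 = top-left, Q2 = top-right, Q3 = bottom-left, Q4 = bottom-right.
    Each sub-grid is (H/2)×(W/2); the stage-2 feature layout depends on this
    order, which is frozen.
    """
    h, w = cddm.shape
    hh, hw = h // 2, w // 2
    slices = [
        (slice(0, hh), slice(0, hw)),
        (slice(0, hh), slice(hw, w)),
        (slice(hh, h), slice(0, hw)),
        (slice(hh, h), slice(hw, w)),
    ]
    return [(cddm.magnitude[r, c], cddm.angle[r, c]) for r, c in slices]


def flatten_for_stage1(
    cddm: CDDM, grid: GridConfig = DEFAULT_GRID
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a map row-major into the stage-1 (magnitude, angle) vectors.

    The vectors have length ``grid.stage1_vector_length`` (100 on the default
    10×10 grid); flatten-then-reshape is the identity.
    """
    if cddm.shape != grid.shape:
        raise MapValidationError(
            f"map shape {cddm.shape} does not match grid config {grid.shape}"
        )
    return cddm.magnitude.ravel(), cddm.angle.ravel()
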