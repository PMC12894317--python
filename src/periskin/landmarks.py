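"""Named facial landmarks around the periorbital region.

A :class:`LandmarkSet` holds single named points (the four canthi, cheek and
temple anchors) and named polylines (eyebrow line, eyelid line, facial
outline per side), all in pixel coordinates with the origin at the top-left
corner, x to the right, y down, 0-based. Heights used by the morphology
module are measured image-up, i.e. ``height = image_height - y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SIDES = ("left", "right")

#: single points a full periorbital landmark set provides per side
POINT_NAMES = ("medial_canthus", "lateral_canthus", "cheek", "temple")
#: polylines per side (ordered point sequences)
LINE_NAMES = ("eyebrow", "eyelid", "outline")


class LandmarkError(KeyError):
    """A required landmark is missing or invalid; the message names it."""


@dataclass
class LandmarkSet:
    """Named 2-D points and polylines for one face image.

    Parameters
    ----------
    points : dict
        Maps names like ``"left_lateral_canthus"`` to ``(x, y)`` arrays.
    lines : dict
        Maps names like ``"right_eyebrow"`` to ``(n, 2)`` polyline arrays.
    image_size : tuple
        ``(height, width)`` of the source image in pixels.
    """

    points: dict[str, np.ndarray] = field(default_factory=dict)
    lines: dict[str, np.ndarray] = field(default_factory=dict)
    image_size: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        self.lines = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in self.lines.items()}

    # -- access ---------------------------------------------------------
    def point(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkError(f"missing landmark point {name!r}") from None

    def line(self, name: str) -> np.ndarray:
        try:
            return self.lines[name]
        except KeyError:
            raise LandmarkError(f"missing landmark line {name!r}") from None

    @property
    def image_height(self) -> int:
        return int(self.image_size[0])

    def validate(self) -> None:
        """Check every coordinate is finite and inside the image canvas."""
        h, w = self.image_size
        for name, xy in self.points.items():
            self._check(name, xy[None, :], h, w)
        for name, line in self.lines.items():
            self._check(name, line, h, w)

    @staticmethod
    def _check(name: str, arr: np.ndarray, h: int, w: int) -> None:
        if not np.all(np.isfinite(arr)):
            raise LandmarkError(f"landmark {name!r} has non-finite coordinates")
        if np.any(arr[:, 0] < 0) or np.any(arr[:, 0] > w - 1) or np.any(arr[:, 1] < 0) or np.any(arr[:, 1] > h - 1):
            raise LandmarkError(f"landmark {name!r} lies outside the image canvas")

    # -- geometric helpers ---------------------------------------------
    def interp_line_x(self, name: str, y: float) -> float:
        """x-coordinate of polyline `name` at height y (linear interpolation).

        The polyline is treated as a function x(y); points are sorted by y
        and extrapolation clamps to the nearest endpoint.
        """
        line = self.line(name)
        order = np.argsort(line[:, 1])
        ys, xs = line[order, 1], line[order, 0]
        return float(np.interp(y, ys, xs))

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        shift = np.array([dx, dy], dtype=float)
        return LandmarkSet(
            points={k: v + shift for k, v in self.points.items()},
            lines={k: v + shift for k, v in self.lines.items()},
            image_size=self.image_size,
        )

    def mirrored(self) -> "LandmarkSet":
        """Horizontal mirror: x -> (width-1) - x, left/right names swapped."""
        w = self.image_size[1]

        def flip(arr: np.ndarray) -> np.ndarray:
            out = arr.copy()
            out[..., 0] = (w - 1) - out[..., 0]
            return out

        def swap(name: str) -> str:
            if name.startswith("left_"):
                return "right_" + name[5:]
            if name.startswith("right_"):
                return "left_" + name[6:]
            return name

        return LandmarkSet(
            points={swap(k): flip(v) for k, v in self.points.items()},
            lines={swap(k): flip(v) for k, v in self.lines.items()},
            image_size=self.image_size,
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "image_size": list(self.image_size),
            "points": {k: [float(v[0]), float(v[1])] for k, v in self.points.items()},
            "lines": {k: [[float(x), float(y)] for x, y in v] for k, v in self.lines.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            points={k: np.asarray(v) for k, v in d["points"].items()},
            lines={k: np.asarray(v) for k, v in d["lines"].items()},
            image_size=tuple(d["image_size"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkSet":
        return cls.from_dict(json.loads(Path(path).read_text()))
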