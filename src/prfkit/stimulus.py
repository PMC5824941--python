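"""Bar-aperture stimulus movies for pRF mapping.

The mapping stimulus is a bar of checkerboard contrast swept across a
circular field; only the binarized aperture matters to the pRF model, so
frames are stored as 0/1 masks over a square pixel grid in degrees of
visual angle (dva). Coordinates follow the visual-field convention:
x positive rightward, y positive upward, origin at fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


@dataclass
class ApertureMovie:
    """Binary stimulus frames plus the visual-field geometry.

    frames: (T, H, W) uint8 array, 1 where the bar is present.
    sweep_labels: per-frame sweep index; -1 marks blank frames.
    """

    frames: np.ndarray
    field_radius: float = 7.0
    tr: float = 2.0
    sweep_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("frames must be binary")
        if self.sweep_labels is None:
            self.sweep_labels = np.zeros(self.frames.shape[0], dtype=int)
        self.sweep_labels = np.asarray(self.sweep_labels, dtype=int)
        if self.sweep_labels.shape[0] != self.frames.shape[0]:
            raise ValueError("sweep_labels must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_sweeps(self) -> int:
        return int(self.sweep_labels.max()) + 1 if self.n_frames else 0

    @property
    def pixels_per_dva(self) -> float:
        return (self.frames.shape[2] - 1) / (2.0 * self.field_radius)

    def tiled(self, n_runs: int) -> "ApertureMovie":
        """Back-to-back repeats of the protocol: one continuous session of
        ``n_runs`` runs, as used for concatenated-session fitting."""
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        return ApertureMovie(frames=np.tile(self.frames, (n_runs, 1, 1)),
                             field_radius=self.field_radius, tr=self.tr,
                             sweep_labels=np.tile(self.sweep_labels, n_runs))

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of pixel-center coordinates in dva."""
        _, h, w = self.frames.shape
        xs = np.linspace(-self.field_radius, self.field_radius, w)
        ys = np.linspace(-self.field_radius, self.field_radius, h)
        return np.meshgrid(xs, ys)

    def save(self, path: str | Path) -> None:
        """Compressed array container + plain-text sidecar header."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), frames=self.frames,
                            sweep_labels=self.sweep_labels)
        sidecar = path.with_suffix(".meta.txt")
        sidecar.write_text(
            f"field_radius: {self.field_radius}\n"
            f"tr: {self.tr}\n"
            f"pixels_per_dva: {self.pixels_per_dva}\n"
            f"n_frames: {self.n_frames}\n"
            f"n_sweeps: {self.n_sweeps}\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ApertureMovie":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            frames = z["frames"]
            labels = z["sweep_labels"]
        meta = {}
        for line in path.with_suffix(".meta.txt").read_text().splitlines():
            k, _, v = line.partition(":")
            meta[k.strip()] = v.strip()
        return cls(frames=frames, field_radius=float(meta["field_radius"]),
                   tr=float(meta["tr"]), sweep_labels=labels)


def bar_frame(center_offset: float, orientation: float, *, field_radius: float,
              bar_width: float, bar_length: float, grid_px: int) -> np.ndarray:
    """Single binary bar frame.

    ``orientation`` is the sweep (motion) direction in degrees CCW from the
    +x axis; the bar's long axis is orthogonal to it. ``center_offset`` is
    the signed distance of the bar center from fixation along the motion
    direction. A pixel is on iff its center lies inside the bar rectangle
    AND inside the field disc.
    """
    xs = np.linspace(-field_radius, field_radius, grid_px)
    X, Y = np.meshgrid(xs, xs)
    th = np.deg2rad(orientation)
    d_motion = X * np.cos(th) + Y * np.sin(th)
    d_bar = -X * np.sin(th) + Y * np.cos(th)
    mask = ((np.abs(d_motion - center_offset) <= bar_width / 2.0)
            & (np.abs(d_bar) <= bar_length / 2.0)
            & (X**2 + Y**2 <= field_radius**2))
    return mask.astype(np.uint8)


def generate_bar_apertures(field_radius: float = 7.0, bar_width: float = 2.0,
                           bar_length: float = 14.0,
                           orientations=DEFAULT_ORIENTATIONS,
                           steps_per_sweep: int = 12, grid_px: int = 101,
                           tr: float = 2.0, n_blank_frames: int = 0,
                           strict: bool = True) -> ApertureMovie:
    """Bar-sweep protocol: each orientation swept in both directions.

    Defaults give the standard mapping protocol: a 2 dva wide, 14 dva long
    bar crossing a 7 dva radius field along 4 orientations x 2 directions
    = 8 sweeps, stepping edge-to-edge in equal increments.
    """
    orientations = tuple(orientations)
    if not orientations:
        raise ValueError("orientations must be nonempty")
    if bar_width <= 0:
        raise ValueError("bar_width must be positive")
    if grid_px < 32:
        raise ValueError("grid_px must be >= 32")
    if strict and bar_width > 2 * field_radius:
        raise ValueError("bar_width exceeds the stimulated field diameter")

    offsets = np.linspace(-field_radius, field_radius, steps_per_sweep)
    frames, labels = [], []
    sweep = 0
    for ori in orientations:
        for direction in (1, -1):
            for c in offsets[::direction]:
                frames.append(bar_frame(c, ori, field_radius=field_radius,
                                        bar_width=bar_width,
                                        bar_length=bar_length,
                                        grid_px=grid_px))
                labels.append(sweep)
            sweep += 1
    for _ in range(n_blank_frames):
        frames.append(np.zeros((grid_px, grid_px), dtype=np.uint8))
        labels.append(-1)
    return ApertureMovie(frames=np.stack(frames), field_radius=field_radius,
                         tr=tr, sweep_labels=np.array(labels))
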