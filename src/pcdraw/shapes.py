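"""Synthetic pen-trajectory dataset: six stylized drawing classes.

Emulates a small corpus of hand-drawn 2-D drawings. Each class (FACE, HOUSE,
CAR, FLOWER, HUMAN, ROCKET) is produced by a fixed stroke program — a sequence
of pen-down primitives (ellipses, arcs, polylines) joined by pen-up transit
segments — with Gaussian jitter on the control points so that variants of a
class differ but stay class-typical. Trajectories are resampled to a fixed
length T (default 90) by arc-length-uniform interpolation within each
pen-state segment, normalized to [-1, 1] around the bounding-box center.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: default number of samples per trajectory after resampling
DEFAULT_T = 90
#: std of Gaussian control-point jitter, in normalized coordinate units
JITTER_SIGMA = 0.03
#: dense sampling resolution of the raw stroke programs
RAW_POINTS = 200


class ShapeClass(enum.IntEnum):
    """The six drawing classes, with stable integer codes 0-5."""

    FACE = 0
    HOUSE = 1
    CAR = 2
    FLOWER = 3
    HUMAN = 4
    ROCKET = 5


@dataclass
class Trajectory:
    """One drawing: an ordered (T, 3) array of (x, y, pen) samples.

    ``points[:, 0:2]`` are normalized coordinates in [-1, 1]; ``points[:, 2]``
    is the binary pen state (1 = pen down on paper, 0 = pen up, moving).
    """

    points: np.ndarray
    shape_class: ShapeClass
    variant_id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("trajectory points must have shape (T, 3)")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    @property
    def pen(self) -> np.ndarray:
        return self.points[:, 2]

    def validate(self, T: int | None = None) -> None:
        """Check the container invariants, raising ValueError on violation."""
        if T is not None and len(self) != T:
            raise ValueError(f"expected length {T}, got {len(self)}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite sample in trajectory")
        if np.any(np.abs(self.xy) > 1.0 + 1e-12):
            raise ValueError("coordinate outside [-1, 1]")
        if not np.all(np.isin(self.pen, (0.0, 1.0))):
            raise ValueError("pen state outside {0, 1}")


# ---------------------------------------------------------------------------
# stroke primitives — all return dense (n, 2) coordinate arrays


def _ellipse(cx: float, cy: float, rx: float, ry: float, n: int,
             t0: float = 0.0, t1: float = 2 * math.pi) -> np.ndarray:
    t = np.linspace(t0, t1, n)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def _chaikin(pts: np.ndarray, iterations: int = 3) -> np.ndarray:
    """Round polyline corners by Chaikin subdivision.

    Hand-drawn strokes have no sharp vertices; each pass replaces every
    corner with two points at 1/4 and 3/4 of the adjoining segments.
    Closed polylines (first point == last) stay closed.
    """
    pts = np.asarray(pts, dtype=float)
    closed = np.allclose(pts[0], pts[-1])
    for _ in range(iterations):
        a, b = pts[:-1], pts[1:]
        q = np.empty((2 * len(a), 2))
        q[0::2] = 0.75 * a + 0.25 * b
        q[1::2] = 0.25 * a + 0.75 * b
        if closed:
            pts = np.vstack([q, q[:1]])
        else:
            pts = np.vstack([pts[:1], q, pts[-1:]])
    return pts


def _polyline(pts: np.ndarray, n: int, smooth: int = 0) -> np.ndarray:
    """Sample n points along a polyline, uniform in arc length.

    ``smooth`` > 0 first rounds the corners by that many Chaikin passes.
    """
    pts = np.asarray(pts, dtype=float)
    if smooth:
        pts = _chaikin(pts, smooth)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0:
        return np.repeat(pts[:1], n, axis=0)
    s = np.linspace(0.0, total, n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(s, cum, pts[:, 0])
    out[:, 1] = np.interp(s, cum, pts[:, 1])
    return out


# ---------------------------------------------------------------------------
# per-class stroke programs
#
# Each program maps a jitter function over its control points and returns a
# list of pen-down strokes (dense point arrays) in drawing order. Pen-up
# transit segments between consecutive strokes are added afterwards.


def _program_face(j) -> list[np.ndarray]:
    head = _ellipse(*j(0.0, 0.0), *j(0.8, 0.9), 80)
    eyes = _polyline([j(-0.45, 0.3), j(-0.15, 0.35)], 10)
    eyes2 = _polyline([j(0.15, 0.35), j(0.45, 0.3)], 10)
    mouth = _ellipse(*j(0.0, -0.15), *j(0.45, 0.45), 30,
                     t0=math.pi * 1.2, t1=math.pi * 1.8)
    return [head, eyes, eyes2, mouth]


def _program_house(j) -> list[np.ndarray]:
    # walls and roof drawn as one closed contour
    body = _polyline([j(-0.7, -0.9), j(0.7, -0.9), j(0.7, 0.2),
                      j(0.85, 0.2), j(0.0, 0.9), j(-0.85, 0.2),
                      j(-0.7, 0.2), (-0.7, -0.9)], 90, smooth=3)
    door = _polyline([j(-0.2, -0.9), j(-0.2, -0.25), j(0.25, -0.25),
                      (0.25, -0.9)], 36, smooth=3)
    return [body, door]


def _program_car(j) -> list[np.ndarray]:
    body = _polyline([j(-0.95, -0.3), j(-0.95, 0.05), j(-0.45, 0.1),
                      j(-0.25, 0.5), j(0.35, 0.5), j(0.55, 0.1),
                      j(0.95, 0.05), j(0.95, -0.3), (-0.95, -0.3)], 80, smooth=3)
    wheel1 = _ellipse(*j(-0.55, -0.4), 0.26, 0.26, 26)
    wheel2 = _ellipse(*j(0.55, -0.4), 0.26, 0.26, 26)
    return [body, wheel1, wheel2]


def _program_flower(j) -> list[np.ndarray]:
    # petals: a closed rose-like contour around the flower center
    cx, cy = j(0.0, 0.45)
    t = np.linspace(0.0, 2 * math.pi, 90)
    r = 0.24 + 0.14 * np.cos(4 * t)
    petals = np.column_stack([cx + (r + 0.2) * np.cos(t),
                              cy + (r + 0.2) * np.sin(t)])
    stem = _polyline([j(0.0, -0.1), j(0.08, -0.5), j(0.0, -0.95)], 24, smooth=3)
    leaf = _ellipse(*j(0.3, -0.55), *j(0.26, 0.12), 26)
    return [petals, stem, leaf]


def _program_human(j) -> list[np.ndarray]:
    head = _ellipse(*j(0.0, 0.7), *j(0.24, 0.26), 34)
    # trunk and both legs in a single stroke
    body = _polyline([j(0.0, 0.44), j(0.0, -0.15), j(-0.4, -0.9),
                      j(0.0, -0.15), j(0.4, -0.9)], 50, smooth=3)
    arms = _polyline([j(-0.5, 0.0), j(0.0, 0.3), j(0.5, 0.0)], 26, smooth=3)
    return [head, body, arms]


def _program_rocket(j) -> list[np.ndarray]:
    # hull and both fins drawn as one closed contour
    body = _polyline([j(-0.3, -0.55), j(-0.3, 0.35), j(0.0, 0.9),
                      j(0.3, 0.35), j(0.3, -0.55), j(0.6, -0.85),
                      j(0.3, -0.85), (-0.3, -0.55), j(-0.6, -0.85),
                      j(-0.3, -0.85), (-0.3, -0.55)], 90, smooth=3)
    window = _ellipse(*j(0.0, 0.2), 0.18, 0.18, 20)
    return [body, window]


_PROGRAMS = {
    ShapeClass.FACE: _program_face,
    ShapeClass.HOUSE: _program_house,
    ShapeClass.CAR: _program_car,
    ShapeClass.FLOWER: _program_flower,
    ShapeClass.HUMAN: _program_human,
    ShapeClass.ROCKET: _program_rocket,
}


def generate_shape(shape_class: ShapeClass, seed: int,
                   n_points: int = RAW_POINTS) -> Trajectory:
    """Generate one jittered instance of a drawing class.

    Deterministic in ``(shape_class, seed)``. The returned trajectory carries
    dense sampling (roughly ``n_points`` samples); call :func:`resample` to
    bring it to the model's fixed length.

    Parameters
    ----------
    shape_class
        One of the six :class:`ShapeClass` values.
    seed
        Jitter seed; different seeds give different class-typical variants.
    n_points
        Approximate number of samples in the dense output (>= 10).
    """
    try:
        shape_class = ShapeClass(shape_class)
    except ValueError:
        raise ValueError(f"unknown shape class: {shape_class!r}") from None
    if n_points < 10:
        raise ValueError("n_points must be >= 10")

    rng = np.random.default_rng([int(shape_class), seed & 0x7FFFFFFF])

    def j(*vals: float) -> tuple[float, ...]:
        return tuple(v + rng.normal(0.0, JITTER_SIGMA) for v in vals)

    strokes = _PROGRAMS[shape_class](j)

    # scale the dense stroke sampling to the requested resolution
    scale = n_points / sum(len(s) for s in strokes)
    if scale != 1.0:
        strokes = [_polyline(s, max(2, int(round(len(s) * scale))))
                   for s in strokes]

    segments = []   # (points, pen_state)
    for i, stroke in enumerate(strokes):
        if i > 0:
            transit = _polyline([segments[-1][0][-1], stroke[0]], 4)
            segments.append((transit, 0.0))
        segments.append((stroke, 1.0))

    xy = np.concatenate([p for p, _ in segments])
    pen = np.concatenate([np.full(len(p), s) for p, s in segments])

    # normalize to [-1, 1] around the bounding-box center
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    center = (lo + hi) / 2
    half = max((hi - lo).max() / 2, 1e-12)
    xy = (xy - center) / half * 0.95

    return Trajectory(np.column_stack([xy, pen]), shape_class, variant_id=seed)


# ---------------------------------------------------------------------------
# resampling


def _pen_segments(points: np.ndarray) -> list[tuple[int, int]]:
    """Split a trajectory into maximal runs of constant pen state."""
    pen = points[:, 2]
    breaks = np.flatnonzero(np.diff(pen) != 0) + 1
    bounds = np.concatenate([[0], breaks, [len(pen)]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def _resample_pass(points: np.ndarray, T: int) -> np.ndarray:
    """One arc-length-uniform resampling pass over all pen segments.

    Samples are apportioned to segments proportionally to chord arc length
    (largest remainder, >= 2 per segment so endpoints survive).
    """
    segments = _pen_segments(points)
    lengths = []
    for a, b in segments:
        xy = points[a:b, :2]
        d = np.diff(xy, axis=0)
        lengths.append(float(np.hypot(d[:, 0], d[:, 1]).sum()) if b - a > 1
                       else 0.0)
    total = sum(lengths) or 1.0
    counts = [2] * len(segments)
    remaining = T - 2 * len(segments)
    quotas = [length / total * remaining for length in lengths]
    floors = [int(q) for q in quotas]
    counts = [c + f for c, f in zip(counts, floors)]
    left = remaining - sum(floors)
    order = np.argsort([f - q for q, f in zip(quotas, floors)])
    for k in order[:left]:
        counts[k] += 1

    out = []
    for (a, b), n in zip(segments, counts):
        seg = points[a:b]
        pts = _polyline(seg[:, :2], n) if b - a > 1 else \
            np.repeat(seg[:1, :2], n, axis=0)
        out.append(np.column_stack([pts, np.full(n, seg[0, 2])]))
    return np.concatenate(out)


def resample(traj: Trajectory, T: int = DEFAULT_T) -> Trajectory:
    """Resample to exactly T samples, arc-length-uniform within segments.

    Pen-down strokes and pen-up transits are resampled separately so stroke
    boundaries and their endpoints are preserved; the number of pen-state
    transitions is unchanged. The pass is iterated to its fixed point
    (re-uniformizing changes segment chord lengths slightly, which would
    otherwise shift the sample apportionment), so resampling is idempotent:
    an already-uniform length-T trajectory passes through unchanged.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if T < 2:
        raise ValueError("T must be >= 2")
    n_segments = len(_pen_segments(traj.points))
    if T < 2 * n_segments:
        raise ValueError(
            f"T={T} too small to preserve {n_segments} pen segments")

    points = traj.points
    for _ in range(100):
        new = _resample_pass(points, T)
        if new.shape == points.shape and np.abs(new - points).max() < 1e-13:
            points = new
            break
        points = new
    assert points.shape[0] == T
    return Trajectory(points, traj.shape_class, traj.variant_id)


# ---------------------------------------------------------------------------
# dataset


@dataclass
class DrawingDataset:
    """Per-class trajectory variants with a train/test partition."""

    trajectories: dict[ShapeClass, list[Trajectory]]
    train_ids: dict[ShapeClass, list[int]]
    test_ids: dict[ShapeClass, list[int]]
    seed: int
    timesteps: int = DEFAULT_T

    @property
    def classes(self) -> list[ShapeClass]:
        return sorted(self.trajectories, key=int)

    def split(self, which: str) -> list[Trajectory]:
        """All trajectories of the 'train' or 'test' partition, ordered by
        (class code, variant id)."""
        ids = {"train": self.train_ids, "test": self.test_ids}[which]
        return [t for c in self.classes for t in self.trajectories[c]
                if t.variant_id in ids[c]]

    def validate(self) -> None:
        for c, variants in self.trajectories.items():
            for t in variants:
                t.validate(self.timesteps)
            tr, te = set(self.train_ids[c]), set(self.test_ids[c])
            if tr & te:
                raise ValueError(f"overlapping train/test split for {c.name}")
            if tr | te != {t.variant_id for t in variants}:
                raise ValueError(f"split does not cover all variants of {c.name}")


def build_dataset(seed: int = 0, n_per_class: int = 10,
                  timesteps: int = DEFAULT_T,
                  classes: list[ShapeClass] | None = None,
                  train_fraction: float = 0.7) -> DrawingDataset:
    """Generate the full dataset: ``n_per_class`` variants of each class,
    resampled to ``timesteps`` samples, split 70/30 into train/test.

    The split is deterministic: the first 70% of variant ids train, the rest
    test (variants 0-6 / 7-9 at the default size).
    """
    classes = list(ShapeClass) if classes is None else list(classes)
    n_train = int(round(train_fraction * n_per_class))
    trajectories: dict[ShapeClass, list[Trajectory]] = {}
    train_ids: dict[ShapeClass, list[int]] = {}
    test_ids: dict[ShapeClass, list[int]] = {}
    for c in classes:
        variants = []
        for v in range(n_per_class):
            raw = generate_shape(c, seed * 1000 + v)
            t = resample(raw, timesteps)
            t.variant_id = v
            variants.append(t)
        trajectories[c] = variants
        train_ids[c] = list(range(n_train))
        test_ids[c] = list(range(n_train, n_per_class))
    ds = DrawingDataset(trajectories, train_ids, test_ids, seed, timesteps)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# on-disk format: CSV of samples + JSON manifest


def write_trajectories(dataset: DrawingDataset, path: str | Path) -> None:
    """Write the dataset as ``trajectories.csv`` + ``manifest.json`` in
    directory ``path``. Round-trips losslessly to stored precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in dataset.classes:
        for traj in dataset.trajectories[c]:
            for t, (x, y, pen) in enumerate(traj.points):
                rows.append((f"{c.name}_{traj.variant_id}", int(c), t,
                             x, y, int(pen)))
    df = pd.DataFrame(rows, columns=["trajectory_id", "class", "t",
                                     "x", "y", "pen"])
    df.to_csv(path / "trajectories.csv", index=False, float_format="%.12g")
    manifest = {
        "seed": dataset.seed,
        "timesteps": dataset.timesteps,
        "class_codes": {c.name: int(c) for c in dataset.classes},
        "train_ids": {c.name: dataset.train_ids[c] for c in dataset.classes},
        "test_ids": {c.name: dataset.test_ids[c] for c in dataset.classes},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_trajectories(path: str | Path) -> DrawingDataset:
    """Read a dataset written by :func:`write_trajectories`."""
    path = Path(path)
    csv = path / "trajectories.csv"
    df = pd.read_csv(csv)
    if df.empty:
        raise ValueError(f"{csv}: no trajectories (zero classes)")
    bad = ~df["pen"].isin((0, 1))
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"{csv}: invalid pen value at row {row}")
    manifest = json.loads((path / "manifest.json").read_text())

    trajectories: dict[ShapeClass, list[Trajectory]] = {}
    for (tid, code), g in df.groupby(["trajectory_id", "class"], sort=False):
        c = ShapeClass(int(code))
        variant = int(str(tid).rsplit("_", 1)[1])
        g = g.sort_values("t")
        points = g[["x", "y", "pen"]].to_numpy(dtype=float)
        trajectories.setdefault(c, []).append(
            Trajectory(points, c, variant))
    for variants in trajectories.values():
        variants.sort(key=lambda t: t.variant_id)

    ds = DrawingDataset(
        trajectories,
        {ShapeClass[k]: v for k, v in manifest["train_ids"].items()},
        {ShapeClass[k]: v for k, v in manifest["test_ids"].items()},
        seed=manifest["seed"],
        timesteps=manifest["timesteps"],
    )
    ds.validate()
    return ds
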