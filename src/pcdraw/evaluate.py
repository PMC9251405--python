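"""Evaluation of produced drawings against the training set.

Two statistics summarize each precision cell of the sweep, separately for
the presented segment (steps 1-30, drawn under sensory guidance) and the
completed segment (steps 31-90, drawn closed-loop):

* mean squared error to the *closest* training trajectory — pointwise
  same-index distance on (x, y), averaged over the segment, minimized over
  all training trajectories;
* the misinterpretation percentage — how often that closest trajectory
  belongs to a class other than the intended one. Cells whose mean error
  reaches the scribble threshold (0.3) are masked: their output resembles
  no training shape, so class confusion is undefined there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .completion import CompletionResult
from .shapes import ShapeClass, Trajectory

#: mean-MSE level above which a drawing counts as random scribbling
SCRIBBLE_THRESHOLD = 0.3

SEGMENTS = ("presented", "completed")


@dataclass
class DistanceResult:
    """Distance of one drawing segment to its closest training trajectory."""

    error: float
    closest_class: ShapeClass
    closest_variant: int
    intended_class: ShapeClass
    segment: str
    cell: tuple[float, float]      # (h_sensor, h_prior)
    network_id: int = 0
    repetition: int = 0
    variant_id: int = 0

    @property
    def misinterpreted(self) -> bool:
        return self.closest_class != self.intended_class


def _segment_slice(T: int, segment: str) -> slice:
    split = int(round(T / 3))
    if segment == "presented":
        return slice(0, split)
    if segment == "completed":
        return slice(split, T)
    raise ValueError(f"unknown segment {segment!r}")


def distance_to_closest(drawing: Trajectory | np.ndarray,
                        training_set: list[Trajectory], segment: str,
                        include_pen: bool = False,
                        intended_class: ShapeClass | None = None,
                        **provenance) -> DistanceResult:
    """MSE of one drawn segment to the closest training trajectory.

    The distance is pointwise at matching time indices (all trajectories
    share T by construction), on (x, y) by default; ``include_pen`` adds the
    pen channel. Ties break toward the lowest class code, then lowest
    variant id.
    """
    if not training_set:
        raise ValueError("empty training set")
    pts = drawing.points if isinstance(drawing, Trajectory) else \
        np.asarray(drawing, dtype=float)
    if intended_class is None and isinstance(drawing, Trajectory):
        intended_class = drawing.shape_class
    sl = _segment_slice(pts.shape[0], segment)
    ndim = 3 if include_pen else 2
    seg = pts[sl, :ndim]

    ordered = sorted(training_set,
                     key=lambda t: (int(t.shape_class), t.variant_id))
    errors = np.array([np.mean(np.sum(
        (seg - t.points[sl, :ndim]) ** 2, axis=1)) for t in ordered])
    k = int(np.argmin(errors))   # first minimum = lowest (class, variant)
    return DistanceResult(
        error=float(errors[k]),
        closest_class=ordered[k].shape_class,
        closest_variant=ordered[k].variant_id,
        intended_class=intended_class,
        segment=segment,
        **provenance,
    )


def evaluate_completions(results: list[CompletionResult],
                         training_set: list[Trajectory],
                         include_pen: bool = False) -> list[DistanceResult]:
    """Distance results for every completion, on both segments."""
    out = []
    for r in results:
        for segment in SEGMENTS:
            out.append(distance_to_closest(
                r.drawn, training_set, segment, include_pen=include_pen,
                intended_class=r.intended_class, cell=r.cell,
                network_id=r.network_id, repetition=r.repetition,
                variant_id=r.variant_id))
    return out


# ---------------------------------------------------------------------------
# 3x3 sweep matrix


@dataclass
class SweepMatrix:
    """Per-cell summary statistics of the precision sweep.

    ``table`` has one row per (segment, h_sensor, h_prior) with columns
    ``mean_error``, ``misinterpretation_pct`` (NaN where masked or not
    computed), ``masked``, and ``n_results``. Grids are oriented with
    precision increasing upward/rightward: rows run over h_prior values in
    descending order (1000 at the bottom), columns over h_sensor likewise.
    """

    table: pd.DataFrame
    scribble_threshold: float = SCRIBBLE_THRESHOLD

    @property
    def h_sensor_values(self) -> list[float]:
        return sorted(self.table["h_sensor"].unique())

    @property
    def h_prior_values(self) -> list[float]:
        return sorted(self.table["h_prior"].unique())

    def cell(self, segment: str, h_sensor: float, h_prior: float) -> pd.Series:
        t = self.table
        m = (t["segment"] == segment) & (t["h_sensor"] == h_sensor) \
            & (t["h_prior"] == h_prior)
        if not m.any():
            raise KeyError((segment, h_sensor, h_prior))
        return t[m].iloc[0]

    def grid(self, segment: str, field: str = "mean_error") -> np.ndarray:
        """3x3 array, rows = h_prior descending (low precision at bottom row
        index 2... i.e. row 0 = highest variance 1000), columns = h_sensor
        descending likewise, matching the drawing-matrix orientation."""
        hs = sorted(self.h_sensor_values, reverse=True)
        hp = sorted(self.h_prior_values, reverse=True)
        out = np.full((len(hp), len(hs)), np.nan)
        for i, p in enumerate(hp):
            for j, s in enumerate(hs):
                try:
                    out[i, j] = self.cell(segment, s, p)[field]
                except KeyError:
                    pass    # cell absent from the results: leave NaN
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "axes": {
                "rows": "h_prior descending (1000, 1, 0.001): bottom-to-top "
                        "of the figure orientation",
                "cols": "h_sensor descending (1000, 1, 0.001)",
            },
            "scribble_threshold": self.scribble_threshold,
            "cells": self.table.replace({np.nan: None}).to_dict("records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SweepMatrix":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        table = pd.DataFrame(payload["cells"])
        return cls(table, payload["scribble_threshold"])


def _cell_frame(results: list[DistanceResult]) -> pd.DataFrame:
    if not results:
        raise ValueError("no distance results")
    return pd.DataFrame({
        "segment": [r.segment for r in results],
        "h_sensor": [r.cell[0] for r in results],
        "h_prior": [r.cell[1] for r in results],
        "error": [r.error for r in results],
        "misinterpreted": [r.misinterpreted for r in results],
        "network_id": [r.network_id for r in results],
    })


def summarize_errors(results: list[DistanceResult]) -> SweepMatrix:
    """Mean error per (segment, cell) over all pooled results."""
    df = _cell_frame(results)
    g = df.groupby(["segment", "h_sensor", "h_prior"], as_index=False).agg(
        mean_error=("error", "mean"), n_results=("error", "size"))
    g["misinterpretation_pct"] = np.nan
    g["masked"] = False
    return SweepMatrix(g)


def misinterpretation_rate(results: list[DistanceResult],
                           scribble_threshold: float = SCRIBBLE_THRESHOLD
                           ) -> SweepMatrix:
    """Misinterpretation percentage per cell, with scribble masking.

    A cell is masked when its mean error reaches the threshold (no
    representational drawing, so confusion between shapes is undefined) or
    contains no results. Percentages pool results across networks; a
    per-network breakdown is attached as ``matrix.per_network``.
    """
    df = _cell_frame(results)
    g = df.groupby(["segment", "h_sensor", "h_prior"], as_index=False).agg(
        mean_error=("error", "mean"),
        misinterpretation_pct=("misinterpreted",
                               lambda s: 100.0 * s.mean()),
        n_results=("error", "size"))
    g["masked"] = (g["mean_error"] >= scribble_threshold) \
        | (g["n_results"] == 0)
    g.loc[g["masked"], "misinterpretation_pct"] = np.nan
    matrix = SweepMatrix(g, scribble_threshold)
    matrix.per_network = df.groupby(
        ["segment", "h_sensor", "h_prior", "network_id"],
        as_index=False).agg(
            mean_error=("error", "mean"),
            misinterpretation_pct=("misinterpreted",
                                   lambda s: 100.0 * s.mean()))
    return matrix


# ---------------------------------------------------------------------------
# rendering


def render_outputs(matrix: SweepMatrix, results: list[CompletionResult],
                   out_dir: str | Path) -> None:
    """Write the drawing grid, the heatmaps, and the matrix JSON file.

    ``drawings.png`` shows one 3x3 panel grid of produced trajectories
    (presented part black solid / gray dashed by pen state, completion in
    green, dashed where the pen is up). ``error_<segment>.png`` and
    ``misinterpretation_<segment>.png`` are cell heatmaps; masked cells are
    drawn gray with an 'x'. ``matrix.json`` round-trips the SweepMatrix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no completion results to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix.to_json(out_dir / "matrix.json")

    hs = sorted({r.cell[0] for r in results}, reverse=True)
    hp = sorted({r.cell[1] for r in results}, reverse=True)
    fig, axes = plt.subplots(len(hp), len(hs),
                             figsize=(3 * len(hs), 3 * len(hp)))
    axes = np.atleast_2d(axes)
    # rows bottom-to-top: lowest prior precision (h_prior = 1000) at bottom
    for i, p in enumerate(hp):
        for j, s in enumerate(reversed(hs)):
            ax = axes[len(hp) - 1 - i, j]
            for r in results:
                if r.cell != (s, p) or r.repetition != 0 or r.network_id != 0:
                    continue
                split = r.prefix_steps
                _plot_segment(ax, r.drawn.points[:split], "black", "gray")
                _plot_segment(ax, r.drawn.points[split - 1:],
                              "tab:green", "tab:green")
            ax.set_xlim(-1.1, 1.1)
            ax.set_ylim(-1.1, 1.1)
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_xlabel(f"H_sensor={s:g}")
            if j == 0:
                ax.set_ylabel(f"H_prior={p:g}")
    fig.suptitle("Produced drawings per precision cell (network 0)")
    fig.savefig(out_dir / "drawings.png", dpi=110)
    plt.close(fig)

    for segment in SEGMENTS:
        _heatmap(matrix, segment, "mean_error",
                 out_dir / f"error_{segment}.png", mask=False)
        _heatmap(matrix, segment, "misinterpretation_pct",
                 out_dir / f"misinterpretation_{segment}.png", mask=True)


def _plot_segment(ax, pts: np.ndarray, down_color: str, up_color: str
                  ) -> None:
    """Plot a trajectory piece, styling pen-down and pen-up runs apart."""
    pen = pts[:, 2] >= 0.5
    start = 0
    for k in range(1, len(pts) + 1):
        if k == len(pts) or pen[k] != pen[start]:
            run = pts[max(start - 1, 0):k + 1]
            if pen[start]:
                ax.plot(run[:, 0], run[:, 1], color=down_color, lw=1.2)
            else:
                ax.plot(run[:, 0], run[:, 1], color=up_color, lw=0.8,
                        ls="--", alpha=0.7)
            start = k


def _heatmap(matrix: SweepMatrix, segment: str, field: str, path: Path,
             mask: bool) -> None:
    import matplotlib.pyplot as plt

    grid = matrix.grid(segment, field)
    masked = matrix.grid(segment, "masked").astype(bool) if mask else \
        np.zeros_like(grid, dtype=bool)
    hs = sorted(matrix.h_sensor_values, reverse=True)
    hp = sorted(matrix.h_prior_values, reverse=True)
    # orient like the drawing grid: bottom row = lowest precision
    show = np.flipud(np.fliplr(grid))
    shown_mask = np.flipud(np.fliplr(masked))
    fig, ax = plt.subplots(figsize=(4.6, 4))
    data = np.ma.masked_where(shown_mask, show)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgray")
    im = ax.imshow(data, cmap=cmap, origin="lower")
    for i in range(show.shape[0]):
        for j in range(show.shape[1]):
            txt = "x" if shown_mask[i, j] else f"{show[i, j]:.2f}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=9)
    ax.set_xticks(range(len(hs)), [f"{v:g}" for v in reversed(hs)])
    ax.set_yticks(range(len(hp)), [f"{v:g}" for v in reversed(hp)])
    ax.set_xlabel("H_sensor")
    ax.set_ylabel("H_prior")
    ax.set_title(f"{field} ({segment})")
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
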