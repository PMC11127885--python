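"""Beeswarm plots of discriminant scores against model fields and centroids.

Three layouts:

* ``basic`` — model fields with one symbol per group, both centroids and the
  unknown samples on a single axis;
* ``geog``  — model fields symbol-coded by survey location;
* ``phase`` — one stacked subplot per phase label (up to five), sharing the
  LD1 axis, centroids repeated per subplot.

Point placement uses a deterministic greedy non-overlap swarm seeded only by
input order, so re-plotting identical inputs yields byte-identical SVG (the
test profile pins fonts and the SVG hash salt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless; the tool only writes files

import matplotlib.pyplot as plt
import numpy as np

from .lda import DiscriminantResult, ModelDataset

__all__ = ["PlotSpec", "plot", "swarm_offsets"]

MAX_PHASES = 5

_DEFAULT_SYMBOLS = ("o", "s", "^", "D", "v", "P", "X", "*")
_DEFAULT_COLOURS = ("#1b6ca8", "#c0392b", "#27ae60", "#8e44ad", "#d35400",
                    "#16a085", "#7f8c8d", "#2c3e50")


@dataclass
class PlotSpec:
    """Styling and layout options (``gpch``/``gcol``/``gbg`` analogues)."""

    layout: str = "basic"
    phase_column: Sequence[str] | Mapping[str, str] | None = None
    symbols: Sequence[str] = _DEFAULT_SYMBOLS
    colours: Sequence[str] = _DEFAULT_COLOURS
    fills: Sequence[str] | None = None
    xlim: tuple[float, float] | None = None
    legend_loc: str = "upper right"
    compact: float = 1.0  # vertical packing step multiplier
    point_size: float = 45.0

    def __post_init__(self) -> None:
        if self.layout not in ("basic", "geog", "phase"):
            raise ValueError(f"layout must be basic, geog or phase, got {self.layout!r}")


def swarm_offsets(x: np.ndarray, width: float, step: float = 1.0) -> np.ndarray:
    """Deterministic greedy 1-D beeswarm row offsets.

    Points are processed in input order; each takes the smallest-magnitude
    integer row (0, +1, -1, +2, ...) at which it does not overlap an already
    placed point (overlap = horizontal distance < ``width`` in the same or an
    adjacent row).
    """
    x = np.asarray(x, dtype=float)
    offsets = np.zeros(len(x))
    placed: list[tuple[float, float]] = []
    for i, xi in enumerate(x):
        row = 0.0
        for k in range(0, 4 * len(x) + 1):
            row = ((k + 1) // 2) * (1 if k % 2 == 1 else -1) * step
            if k == 0:
                row = 0.0
            if not any(
                abs(xi - xj) < width and abs(row - rj) < step * 0.999
                for xj, rj in placed
            ):
                break
        offsets[i] = row
        placed.append((xi, row))
    return offsets


def _style(spec: PlotSpec, i: int) -> dict:
    marker = spec.symbols[i % len(spec.symbols)]
    colour = spec.colours[i % len(spec.colours)]
    fill = spec.fills[i % len(spec.fills)] if spec.fills else "none"
    return {"marker": marker, "edgecolors": colour, "facecolors": fill,
            "s": spec.point_size}


def _swarm(ax, x, y_base, width, spec: PlotSpec, gid: str, **style):
    offs = swarm_offsets(np.asarray(x), width=width, step=spec.compact)
    coll = ax.scatter(np.asarray(x), y_base + offs * 0.08, gid=gid, **style)
    return coll


def _draw_centroids(ax, model, spec: PlotSpec):
    for c, name in ((model.centroid_1, "group 1 centroid"),
                    (model.centroid_2, "group 2 centroid")):
        ax.scatter([c], [0.0], marker="+", s=200, linewidths=2.5,
                   color="black", zorder=5, gid="centroid", label=name)
        ax.axvline(c, color="0.7", linewidth=0.8, zorder=0)


def _point_width(values: np.ndarray, spec: PlotSpec) -> float:
    span = float(np.ptp(values)) if len(values) > 1 else 1.0
    if spec.xlim is not None:
        span = spec.xlim[1] - spec.xlim[0]
    return max(span, 1e-9) * 0.02


def plot(
    results: DiscriminantResult,
    model_data: ModelDataset,
    spec: PlotSpec,
    out: str | Path,
) -> Path:
    """Render discriminant scores to ``out`` (.svg or .png by extension).

    ``results`` and ``model_data`` must reference the same fitted model
    (checked via the model id).  Phase layout requires ``spec.phase_column``
    with 1-5 distinct labels covering every sample.
    """
    model = results.model
    if model.model_id != model_data.model_id:
        raise ValueError(
            f"results were fitted for model {model.model_id} but model data is "
            f"for model {model_data.model_id}"
        )
    unknown_ld1 = results.table["LD1_unstd"].to_numpy()
    field_scores = {
        g: model.score(model_data.group_matrix(g)).ravel() for g in (1, 2)
    }
    all_vals = np.concatenate([unknown_ld1, field_scores[1], field_scores[2],
                               [model.centroid_1, model.centroid_2]])
    width = _point_width(all_vals, spec)

    if spec.layout == "phase":
        fig = _plot_phase(results, model_data, spec, field_scores, width)
    else:
        fig, ax = plt.subplots(figsize=(8, 3.2), constrained_layout=True)
        if spec.layout == "basic":
            for g, y in ((1, 0.45), (2, -0.45)):
                _swarm(ax, field_scores[g], y, width, spec, gid=f"model-group{g}",
                       label=f"model group {g}", **_style(spec, g - 1))
        else:  # geog
            frame = model_data.frame
            locations = list(dict.fromkeys(frame["location"]))
            for i, loc in enumerate(locations):
                sub = frame[frame["location"] == loc]
                scores = model.score(
                    sub[list(model.predictors)].to_numpy(dtype=float)
                ).ravel()
                y = 0.45 if sub["group"].iloc[0] == 1 else -0.45
                _swarm(ax, scores, y, width, spec, gid=f"location-{loc}",
                       label=str(loc), **_style(spec, i))
        if len(unknown_ld1):
            _swarm(ax, unknown_ld1, 0.0, width, spec, gid="unknown",
                   label="archaeobotanical samples",
                   marker="o", facecolors="black", edgecolors="black",
                   s=spec.point_size * 0.7)
        _draw_centroids(ax, model, spec)
        _finish_axis(ax, spec)
        ax.legend(loc=spec.legend_loc, fontsize=8, frameon=False)

    out = Path(out)
    _save(fig, out)
    plt.close(fig)
    return out


def _phase_labels(results: DiscriminantResult, spec: PlotSpec) -> list[str]:
    samples = list(results.table.index)
    pc = spec.phase_column
    if pc is None:
        raise ValueError("phase layout requires phase_column labels")
    if isinstance(pc, Mapping):
        missing = [s for s in samples if s not in pc]
        if missing:
            raise ValueError(f"phase labels missing for sample(s): {missing}")
        labels = [str(pc[s]) for s in samples]
    else:
        if len(pc) != len(samples):
            raise ValueError(
                f"phase_column has {len(pc)} labels for {len(samples)} samples"
            )
        labels = [str(v) for v in pc]
    phases = list(dict.fromkeys(labels))  # first-appearance order
    if len(phases) > MAX_PHASES:
        raise ValueError(
            f"phase layout supports at most {MAX_PHASES} phases, got {len(phases)}: {phases}"
        )
    return labels


def _plot_phase(results, model_data, spec, field_scores, width):
    labels = _phase_labels(results, spec)
    phases = list(dict.fromkeys(labels))
    fig, axes = plt.subplots(
        len(phases), 1, sharex=True, figsize=(8, 1.9 * len(phases)),
        constrained_layout=True, squeeze=False,
    )
    ld1 = results.table["LD1_unstd"].to_numpy()
    model = results.model
    for i, phase in enumerate(phases):
        ax = axes[i, 0]
        mask = np.array([lab == phase for lab in labels])
        for g, y in ((1, 0.45), (2, -0.45)):
            _swarm(ax, field_scores[g], y, width, spec, gid=f"model-group{g}",
                   label=f"model group {g}" if i == 0 else None,
                   **_style(spec, g - 1))
        _swarm(ax, ld1[mask], 0.0, width, spec, gid=f"phase-{phase}",
               label=str(phase), marker="o", facecolors="black",
               edgecolors="black", s=spec.point_size * 0.7)
        _draw_centroids(ax, model, spec)
        ax.set_ylabel(str(phase), fontsize=8)
        _finish_axis(ax, spec, xlabel=(i == len(phases) - 1))
    return fig


def _finish_axis(ax, spec: PlotSpec, xlabel: bool = True):
    ax.set_yticks([])
    ax.set_ylim(-1.0, 1.0)
    if spec.xlim is not None:
        ax.set_xlim(*spec.xlim)
    if xlabel:
        ax.set_xlabel("LD1")
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)


def _save(fig, out: Path) -> None:
    with matplotlib.rc_context({"svg.hashsalt": "weedclass", "svg.fonttype": "none"}):
        if out.suffix.lower() == ".svg":
            fig.savefig(out, format="svg", metadata={"Date": None})
        else:
            fig.savefig(out)
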