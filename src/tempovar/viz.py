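"""Rendering: data temporal heat maps and IGT scatter plots.

Static PNG/SVG output goes through matplotlib; ``.html`` output is a
standalone, dependency-free document containing a hand-built SVG with
native hover tool-tips plus the exact numeric series embedded as a JSON
``<script>`` block (id ``tempovar-data``), so exported numbers can be
re-read programmatically and compared bit-for-bit.

Cell values are taken from the DTM matrices verbatim -- no renormalisation
happens at plot time.  Missing batches are drawn in a neutral "no data"
colour distinct from a zero frequency.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .dtm import DataTemporalMap
from .igt import IGTProjection

_FORMATS = (".png", ".svg", ".html")
_NODATA_COLOR = "#c8c8c8"

#: palette registry: id -> (kind, matplotlib colormap, CVD annotation)
_PALETTES = {
    "viridis": ("sequential", "viridis",
                "deuteranopia- and protanopia-safe perceptually uniform"),
    "cividis": ("sequential", "cividis",
                "optimised for color-vision deficiency; perceptually uniform"),
    "magma": ("sequential", "magma",
              "perceptually uniform sequential; CVD-friendly"),
    "twilight": ("cyclic", "twilight",
                 "cyclic, for seasonal coloring; muted CVD-friendly hues"),
    "twilight_shifted": ("cyclic", "twilight_shifted",
                         "cyclic, for seasonal coloring"),
}


def list_palettes() -> dict[str, dict[str, str]]:
    """Available palettes with their kind and color-vision-deficiency notes.

    Sequential palettes are for heat maps (perceptually monotonic);
    cyclic palettes (first and last colors adjacent) are for seasonal
    coloring of IGT batches.
    """
    return {
        pid: {"kind": kind, "colormap": cmap, "cvd": note}
        for pid, (kind, cmap, note) in _PALETTES.items()
    }


def _get_cmap(palette: str, kind: str):
    if palette not in _PALETTES:
        raise ValueError(f"unknown palette {palette!r}; see list_palettes()")
    pkind, cmap, _ = _PALETTES[palette]
    if pkind != kind:
        raise ValueError(f"palette {palette!r} is {pkind}, need {kind}")
    return colormaps[cmap]


def _check_out_path(out_path: str | Path) -> Path:
    out_path = Path(out_path)
    if out_path.suffix.lower() not in _FORMATS:
        raise ValueError(
            f"unsupported output format {out_path.suffix!r}; "
            f"supported: {', '.join(_FORMATS)}"
        )
    out_path.parent.mkdir(parents=True, exist_ok=True)
    return out_path


@dataclass
class HeatmapSpec:
    """Options for a data temporal heat map.

    ``mode="relative"`` colours by probabilities, ``"absolute"`` by raw
    counts.  ``top_k`` caps the displayed support cells after sorting
    (``"frequency-desc"`` ranks by overall frequency, mirroring
    "k most frequent" displays).
    """

    mode: str = "relative"
    value_sorting: str = "frequency-desc"
    top_k: int | None = 50
    palette: str = "viridis"

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.value_sorting not in ("frequency-desc", "alphabetical"):
            raise ValueError(f"unknown value_sorting {self.value_sorting!r}")
        if self.top_k is not None and self.top_k <= 0:
            raise ValueError("top_k must be positive")


@dataclass
class IGTPlotSpec:
    """Options for an IGT scatter plot (2 or 3 dimensions)."""

    dims: int = 2
    show_trajectory: bool = False
    label_mode: str = "text-labels"
    palette: str = "twilight"

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.label_mode not in ("text-labels", "points"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")


def select_heatmap_cells(dtm: DataTemporalMap, spec: HeatmapSpec):
    """Support-cell selection and ordering for display.

    Returns ``(indices, labels, matrix)`` where ``matrix`` is the selected
    sub-matrix of probabilities (relative mode) or counts (absolute mode),
    untouched otherwise.
    """
    matrix = dtm.probabilities if spec.mode == "relative" else dtm.counts
    labels = [str(v) for v in dtm.support.values]
    if spec.value_sorting == "frequency-desc":
        totals = np.nansum(dtm.counts, axis=0)
        order = np.argsort(-totals, kind="stable")
    else:
        order = np.argsort(labels, kind="stable")
    if spec.top_k is not None:
        order = order[: spec.top_k]
    return order, [labels[i] for i in order], matrix[:, order]


def plot_dtm_heatmap(
    dtm: DataTemporalMap, spec: HeatmapSpec, out_path: str | Path
) -> Path:
    """Render a DTM as a heat map (batches on x, support values on y).

    Output format follows the file extension: ``.png``/``.svg`` (static)
    or ``.html`` (standalone with hover tool-tips and embedded data).
    """
    out_path = _check_out_path(out_path)
    if dtm.n_batches == 0:
        raise ValueError("empty DTM")
    _, row_labels, matrix = select_heatmap_cells(dtm, spec)
    missing = dtm.missing_mask()
    display = np.ma.masked_invalid(matrix.T)  # rows = values, cols = batches
    if spec.mode == "absolute":
        display = np.ma.masked_array(display, mask=np.broadcast_to(missing, display.shape))
    col_labels = [d.isoformat() for d in dtm.batch_dates]

    if out_path.suffix.lower() == ".html":
        _heatmap_html(display, row_labels, col_labels, dtm, spec, out_path)
        return out_path

    cmap = _get_cmap(spec.palette, "sequential").copy()
    cmap.set_bad(_NODATA_COLOR)
    fig_w = max(6.0, 0.12 * len(col_labels) + 2)
    fig_h = max(4.0, 0.22 * len(row_labels) + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    im = ax.imshow(display, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_yticks(range(len(row_labels)), labels=row_labels, fontsize=7)
    step = max(1, len(col_labels) // 24)
    ax.set_xticks(range(0, len(col_labels), step),
                  labels=col_labels[::step], rotation=90, fontsize=7)
    ax.set_xlabel("time batch")
    ax.set_ylabel(dtm.variable)
    label = "relative frequency" if spec.mode == "relative" else "count"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(f"Data temporal heat map: {dtm.variable} ({dtm.granularity}ly batches)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_igt(
    projection: IGTProjection, spec: IGTPlotSpec, out_path: str | Path
) -> Path:
    """Render an IGT projection as a labelled 2D or 3D scatter plot.

    Batch labels follow the compact yym convention; point colors cycle
    with the season index so yearly cycles are visible.  The smoothed
    trajectory is overlaid when requested (it must be present on the
    projection).
    """
    out_path = _check_out_path(out_path)
    if spec.dims > projection.n_dims:
        raise ValueError(
            f"requested {spec.dims} dims but embedding has {projection.n_dims}"
        )
    if spec.show_trajectory and projection.trajectory is None:
        raise ValueError("projection has no trajectory; re-estimate with one")
    colors = _season_colors(projection, spec)

    if out_path.suffix.lower() == ".html":
        _igt_html(projection, spec, colors, out_path)
        return out_path

    E = projection.embedding
    if spec.dims == 3:
        fig = plt.figure(figsize=(8, 7))
        ax = fig.add_subplot(projection="3d")
        ax.scatter(E[:, 0], E[:, 1], E[:, 2], c=colors, s=18)
        if spec.label_mode == "text-labels":
            for i, lab in enumerate(projection.labels):
                ax.text(E[i, 0], E[i, 1], E[i, 2], lab, fontsize=6)
        if spec.show_trajectory:
            T = projection.trajectory
            ax.plot(T[:, 0], T[:, 1], T[:, 2], color="0.4", lw=1)
        ax.set_zlabel(_axis_label(projection, 2))
    else:
        fig, ax = plt.subplots(figsize=(8, 7))
        if spec.label_mode == "points":
            ax.scatter(E[:, 0], E[:, 1], c=colors, s=18)
        else:
            ax.scatter(E[:, 0], E[:, 1], c=colors, s=4)
            for i, lab in enumerate(projection.labels):
                ax.annotate(lab, (E[i, 0], E[i, 1]), fontsize=7,
                            color=to_hex(colors[i]))
        if spec.show_trajectory:
            T = projection.trajectory
            ax.plot(T[:, 0], T[:, 1], color="0.4", lw=1)
    ax.set_xlabel(_axis_label(projection, 0))
    ax.set_ylabel(_axis_label(projection, 1))
    ax.set_title("IGT plot")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _axis_label(projection: IGTProjection, j: int) -> str:
    ve = projection.variance_explained
    pct = f" ({100 * ve[j]:.1f}%)" if j < len(ve) else ""
    return f"D{j + 1}{pct}"


def _season_colors(projection: IGTProjection, spec: IGTPlotSpec) -> list:
    cmap = _get_cmap(spec.palette, "cyclic")
    if projection.season_indices is None:
        return ["#404040"] * projection.n_batches
    cycle = 12 if projection.granularity == "month" else 53
    return [cmap(((s - 1) % cycle) / cycle) for s in projection.season_indices]


# ---------------------------------------------------------------------------
# standalone HTML with embedded JSON data series


def _json_block(data: dict) -> str:
    payload = json.dumps(data, sort_keys=True, separators=(",", ":"))
    return f'<script type="application/json" id="tempovar-data">{payload}</script>'


def _html_doc(title: str, svg: str, data: dict) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{html.escape(title)}</title></head>\n"
        f"<body>\n<h1>{html.escape(title)}</h1>\n{svg}\n"
        f"{_json_block(data)}\n</body></html>\n"
    )


def _heatmap_html(display, row_labels, col_labels, dtm, spec, out_path: Path) -> None:
    cmap = _get_cmap(spec.palette, "sequential")
    arr = np.ma.filled(display, np.nan)
    finite = arr[np.isfinite(arr)]
    vmax = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    cw, ch, lx, ty = 14, 14, 160, 80
    width = lx + cw * len(col_labels) + 20
    height = ty + ch * len(row_labels) + 20
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
    ]
    for i, rl in enumerate(row_labels):
        parts.append(
            f'<text x="{lx - 4}" y="{ty + i * ch + 11}" text-anchor="end" '
            f'font-size="9">{html.escape(rl)}</text>'
        )
    step = max(1, len(col_labels) // 30)
    for j in range(0, len(col_labels), step):
        parts.append(
            f'<text x="{lx + j * cw + 10}" y="{ty - 6}" font-size="8" '
            f'transform="rotate(-60 {lx + j * cw + 10} {ty - 6})">'
            f'{html.escape(col_labels[j])}</text>'
        )
    for i, rl in enumerate(row_labels):
        for j, cl in enumerate(col_labels):
            v = arr[i, j]
            if np.isfinite(v):
                color = to_hex(cmap(v / vmax))
                tip = f"{rl} @ {cl}: {v:.6g}"
            else:
                color = _NODATA_COLOR
                tip = f"{rl} @ {cl}: no data"
            parts.append(
                f'<rect x="{lx + j * cw}" y="{ty + i * ch}" width="{cw}" '
                f'height="{ch}" fill="{color}"><title>{html.escape(tip)}</title></rect>'
            )
    parts.append("</svg>")
    data = {
        "kind": "dtm-heatmap",
        "variable": dtm.variable,
        "mode": spec.mode,
        "batches": col_labels,
        "values": row_labels,
        "matrix": [[None if not np.isfinite(v) else v for v in row] for row in arr.tolist()],
    }
    title = f"Data temporal heat map: {dtm.variable}"
    out_path.write_text(_html_doc(title, "".join(parts), data))


def _igt_html(projection: IGTProjection, spec: IGTPlotSpec, colors, out_path: Path) -> None:
    E = projection.embedding[:, : spec.dims]
    x, y = E[:, 0], E[:, 1]
    w, h, pad = 720, 640, 60

    def sx(v):
        span = x.max() - x.min() or 1.0
        return pad + (v - x.min()) / span * (w - 2 * pad)

    def sy(v):
        span = y.max() - y.min() or 1.0
        return h - pad - (v - y.min()) / span * (h - 2 * pad)

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}">']
    if spec.show_trajectory and projection.trajectory is not None:
        pts = " ".join(
            f"{sx(px):.2f},{sy(py):.2f}"
            for px, py in projection.trajectory[:, :2]
        )
        parts.append(
            f'<polyline points="{pts}" fill="none" stroke="#666666" stroke-width="1"/>'
        )
    for i in range(projection.n_batches):
        cx, cy = sx(x[i]), sy(y[i])
        color = to_hex(colors[i])
        tip = (
            f"{projection.batch_dates[i].isoformat()} "
            f"(D1={x[i]:.4g}, D2={y[i]:.4g})"
        )
        parts.append(
            f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="3" fill="{color}">'
            f"<title>{html.escape(tip)}</title></circle>"
        )
        if spec.label_mode == "text-labels":
            parts.append(
                f'<text x="{cx + 4:.2f}" y="{cy - 3:.2f}" font-size="9" '
                f'fill="{color}">{html.escape(projection.labels[i])}</text>'
            )
    parts.append("</svg>")
    data = {
        "kind": "igt-plot",
        "dims": spec.dims,
        "batches": [d.isoformat() for d in projection.batch_dates],
        "labels": projection.labels,
        "season_indices": projection.season_indices,
        "embedding": projection.embedding[:, : spec.dims].tolist(),
        "variance_explained": projection.variance_explained[: spec.dims].tolist(),
        "trajectory": (
            None
            if projection.trajectory is None or not spec.show_trajectory
            else projection.trajectory[:, : spec.dims].tolist()
        ),
    }
    out_path.write_text(_html_doc("IGT plot", "".join(parts), data))
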