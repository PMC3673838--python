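"""The canonical visualization: time on x, phase strata on y, outcome colors.

Nodes sit at (publication year + a small within-year offset, phase rank),
lowest phase at the bottom.  Fill color codes the outcome — green for
positive, red for negative, yellow for inconclusive — and contemplated
studies are drawn white with a blue border.  Lineage edges carry
arrowheads; same-report edges are plain lines.  Output is Graphviz DOT
(for external layout engines) or a standalone SVG from the native layered
layout.  Rendering is a pure function of the graph and style: repeated
calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .core import AeroGraph, AeroGraphError, Outcome, Status, Study
from .io import _dot_quote

__all__ = ["StyleConfig", "LayoutSpec", "layout", "render", "load_style"]

DEFAULT_STYLE = {
    "color_positive": "#2ca25f",
    "color_negative": "#de2d26",
    "color_inconclusive": "#fec44f",
    "color_contemplated_fill": "#ffffff",
    "color_contemplated_border": "#3182bd",
    "color_border": "#000000",
    "color_edge": "#555555",
    "node_radius": "14",
    "x_scale": "70",
    "y_scale": "90",
}


@dataclass(frozen=True)
class StyleConfig:
    """Rendering style; every key of ``DEFAULT_STYLE`` may be overridden."""

    values: dict = field(default_factory=lambda: dict(DEFAULT_STYLE))

    def __getitem__(self, key: str) -> str:
        return self.values[key]

    def fill(self, study: Study) -> str:
        if study.status is Status.CONTEMPLATED:
            return self["color_contemplated_fill"]
        return {
            Outcome.POSITIVE: self["color_positive"],
            Outcome.NEGATIVE: self["color_negative"],
            Outcome.INCONCLUSIVE: self["color_inconclusive"],
        }[study.outcome]

    def border(self, study: Study) -> str:
        if study.status is Status.CONTEMPLATED:
            return self["color_contemplated_border"]
        return self["color_border"]


def load_style(path: str | Path) -> StyleConfig:
    """Read ``key=value`` style overrides; unknown keys are rejected."""
    values = dict(DEFAULT_STYLE)
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise AeroGraphError(f"style line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in DEFAULT_STYLE:
            raise AeroGraphError(
                f"style line {lineno}: unknown key {key!r}; "
                f"known keys: {sorted(DEFAULT_STYLE)}"
            )
        values[key] = value
    return StyleConfig(values)


@dataclass(frozen=True)
class LayoutSpec:
    """Deterministic node coordinates in (year, phase-rank) space.

    x is the publication year plus a fixed within-year offset following
    the temporal order, so x strictly increases with the temporal order
    inside every phase band; y is the phase rank (lowest phase = 0, drawn
    at the bottom).
    """

    coordinates: dict[str, tuple[float, float]]
    x_range: tuple[float, float]
    n_bands: int

    def occupied_bands(self) -> set[int]:
        return {int(y) for _, y in self.coordinates.values()}


def layout(graph: AeroGraph) -> LayoutSpec:
    """Place every study; no two nodes coincide."""
    order = graph.temporal_order()
    coords: dict[str, tuple[float, float]] = {}
    # index nodes within each (phase, year) cell, following temporal order
    cells: dict[tuple[str, int], list[str]] = {}
    for sid in order:
        s = graph.study(sid)
        cells.setdefault((s.phase, s.year), []).append(sid)
    for (phase, year), members in cells.items():
        rank = graph.phase_schema.rank(phase)
        step = 0.8 / len(members)
        for i, sid in enumerate(members):
            coords[sid] = (year + i * step, float(rank))
    if coords:
        xs = [x for x, _ in coords.values()]
        x_range = (min(xs), max(xs))
    else:
        x_range = (0.0, 0.0)
    return LayoutSpec(
        coordinates=coords,
        x_range=x_range,
        n_bands=len(graph.phase_schema),
    )


def _render_dot(graph: AeroGraph, style: StyleConfig) -> str:
    lines = [
        "digraph aero {",
        "  rankdir=BT;",
        '  node [shape=circle, style=filled, fontname="Helvetica"];',
    ]
    spec = layout(graph)
    for sid in graph.temporal_order():
        s = graph.study(sid)
        x, y = spec.coordinates[sid]
        attrs = [
            f"fillcolor={_dot_quote(style.fill(s))}",
            f"color={_dot_quote(style.border(s))}",
            f"pos={_dot_quote(f'{x:.2f},{y:.2f}!')}",
            f"phase={_dot_quote(s.phase)}",
            f"year={_dot_quote(str(s.year))}",
            f"outcome={_dot_quote(s.outcome.value if s.outcome else '')}",
            f"status={_dot_quote(s.status.value)}",
        ]
        if s.status is Status.CONTEMPLATED:
            attrs.append("penwidth=2")
        lines.append(f"  {_dot_quote(sid)} [{', '.join(attrs)}];")
    for e in sorted(graph.edges, key=lambda e: e.key):
        attr = ' [dir=none, same_report="true"]' if e.same_report else ""
        lines.append(f"  {_dot_quote(e.parent)} -> {_dot_quote(e.child)}{attr};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _svg_xy(
    x: float, y: float, spec: LayoutSpec, style: StyleConfig, margin: float
) -> tuple[float, float]:
    x_scale = float(style["x_scale"])
    y_scale = float(style["y_scale"])
    px = margin + (x - spec.x_range[0]) * x_scale
    # SVG y grows downward; lowest phase band belongs at the bottom
    py = margin + (spec.n_bands - 1 - y) * y_scale
    return px, py


def _render_svg(graph: AeroGraph, style: StyleConfig) -> str:
    spec = layout(graph)
    margin = 60.0
    r = float(style["node_radius"])
    x_scale = float(style["x_scale"])
    y_scale = float(style["y_scale"])
    width = margin * 2 + (spec.x_range[1] - spec.x_range[0]) * x_scale
    height = margin * 2 + (spec.n_bands - 1) * y_scale
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width:.0f}" height="{height:.0f}" '
        f'viewBox="0 0 {width:.0f} {height:.0f}">',
        "  <defs>",
        '    <marker id="arrow" viewBox="0 0 10 10" refX="10" refY="5" '
        'markerWidth="7" markerHeight="7" orient="auto-start-reverse">',
        f'      <path d="M 0 0 L 10 5 L 0 10 z" fill="{style["color_edge"]}"/>',
        "    </marker>",
        "  </defs>",
    ]
    # phase band labels down the left edge
    for rank, phase in enumerate(graph.phase_schema.names):
        _, py = _svg_xy(0.0, float(rank), spec, style, margin)
        out.append(
            f'  <text x="8" y="{py:.1f}" font-size="12" '
            f'font-family="Helvetica" fill="#333333">'
            f"{graph.phase_schema.label(phase)}</text>"
        )
    for e in sorted(graph.edges, key=lambda ed: ed.key):
        x1, y1 = spec.coordinates[e.parent]
        x2, y2 = spec.coordinates[e.child]
        p1 = _svg_xy(x1, y1, spec, style, margin)
        p2 = _svg_xy(x2, y2, spec, style, margin)
        # shorten the segment so it meets the node circles, not their centers
        dx, dy = p2[0] - p1[0], p2[1] - p1[1]
        dist = max((dx * dx + dy * dy) ** 0.5, 1e-9)
        sx, sy = p1[0] + dx / dist * r, p1[1] + dy / dist * r
        ex, ey = p2[0] - dx / dist * r, p2[1] - dy / dist * r
        marker = "" if e.same_report else ' marker-end="url(#arrow)"'
        out.append(
            f'  <line x1="{sx:.1f}" y1="{sy:.1f}" x2="{ex:.1f}" y2="{ey:.1f}" '
            f'stroke="{style["color_edge"]}" stroke-width="1.5"'
            f"{marker} class=\"edge{' same-report' if e.same_report else ''}\"/>"
        )
    for sid in graph.temporal_order():
        s = graph.study(sid)
        px, py = _svg_xy(*spec.coordinates[sid], spec, style, margin)
        stroke_width = 2.5 if s.status is Status.CONTEMPLATED else 1.5
        out.append(
            f'  <circle cx="{px:.1f}" cy="{py:.1f}" r="{r:.1f}" '
            f'fill="{style.fill(s)}" stroke="{style.border(s)}" '
            f'stroke-width="{stroke_width}" class="study {s.status.value}"/>'
        )
        out.append(
            f'  <text x="{px:.1f}" y="{py + 4:.1f}" text-anchor="middle" '
            f'font-size="11" font-family="Helvetica">{sid}</text>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def render(
    graph: AeroGraph, target: str = "svg", style: StyleConfig | None = None
) -> str:
    """Render the graph to ``dot`` or ``svg`` as a string."""
    style = style or StyleConfig()
    fmt = target.lower()
    if fmt == "dot":
        return _render_dot(graph, style)
    if fmt == "svg":
        return _render_svg(graph, style)
    raise AeroGraphError(f"unknown render target {target!r}")
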