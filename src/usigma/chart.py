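"""Normalized sigma method decision charts.

Each assay is plotted at x = CV/TEa (%) against y = bias/TEa (%).  On these
normalized axes every sigma level s is the straight line ``y = 100 - s*x``
(all lines meet at (0, 100)), so five lines for s = 2..6 partition the plane
into six performance zones, world-class (sigma >= 6) at the bottom-left.

Rendering is plain hand-assembled SVG: output is byte-identical for a fixed
input (no timestamps, no hashed ids), which keeps charts diffable and lets
tests assert determinism exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ComputationError
from .metrics import PerformanceRecord

__all__ = ["ChartPoint", "ZONES", "band", "normalize_point", "render_chart"]

#: zone labels from best to worst; bands are closed on their lower sigma edge
ZONES = (
    "sigma>=6",
    "6>sigma>=5",
    "5>sigma>=4",
    "4>sigma>=3",
    "3>sigma>=2",
    "sigma<2",
)

_EDGES = (6.0, 5.0, 4.0, 3.0, 2.0)

#: values this close under a band edge are snapped onto it, so a point
#: constructed exactly on a sigma boundary line never falls to the worse
#: band through float rounding
_EDGE_TOL = 1e-9


def band(sigma: float) -> str:
    """Sigma band label; lower edge inclusive (band(6.0) -> 'sigma>=6').

    An infinite sigma falls in the top band, any sigma below 2 (including
    negative) in the bottom one.
    """
    if math.isnan(sigma):
        raise ComputationError("band undefined for NaN sigma")
    for label, edge in zip(ZONES, _EDGES):
        if sigma >= edge - _EDGE_TOL:
            return label
    return ZONES[-1]


@dataclass(frozen=True)
class ChartPoint:
    """One assay on the normalized decision chart."""

    lab_id: str
    analyte_id: str
    level: str
    x: float  # CV/TEa * 100 (%)
    y: float  # bias/TEa * 100 (%)
    zone: str


def normalize_point(record: PerformanceRecord) -> ChartPoint:
    """Map a performance record onto the normalized chart.

    x = 100*CV/TEa, y = 100*bias/TEa; the zone follows from
    sigma = (100 - y)/x, which equals the record's own sigma.
    """
    if record.tea_percent <= 0:
        raise ComputationError("normalization needs TEa > 0")
    x = 100.0 * record.cv_percent / record.tea_percent
    y = 100.0 * record.bias_percent / record.tea_percent
    return ChartPoint(record.lab_id, record.analyte_id, record.level, x, y, band((100.0 - y) / x))


# fixed lab palette; extended deterministically if more labs appear
_PALETTE = ("#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf")

_W, _H = 640, 560
_ML, _MR, _MT, _MB = 70, 170, 40, 60  # margins: right one holds the legend
_PW, _PH = _W - _ML - _MR, _H - _MT - _MB


def _sx(x: float) -> float:
    return _ML + x / 100.0 * _PW


def _sy(y: float) -> float:
    return _MT + (100.0 - y) / 100.0 * _PH


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def render_chart(points: Iterable[ChartPoint], level: str, out_path,
                 title: str | None = None) -> Path:
    """Render a normalized method decision chart to SVG.

    Both axes span 0-100%; the five boundary lines y = 100 - s*x for
    s = 2..6 are drawn and labelled; points are coloured by lab with a
    legend.  Points beyond 100% on either axis are clamped to the plot edge
    and drawn as open triangles (out-of-range markers).  All points must
    share ``level``.
    """
    points = list(points)
    for p in points:
        if p.level != level:
            raise ComputationError(
                f"point {(p.lab_id, p.analyte_id)} has level {p.level!r}, chart is {level!r}"
            )
    labs = sorted({p.lab_id for p in points})
    colors = {lab: _PALETTE[i % len(_PALETTE)] for i, lab in enumerate(labs)}
    title = title or f"Normalized method decision chart ({level})"

    e: list[str] = []
    e.append(f'<svg xmlns="http://www.w3.org/2000/svg" width="{_W}" height="{_H}" '
             f'viewBox="0 0 {_W} {_H}" font-family="Helvetica, Arial, sans-serif">')
    e.append(f'<rect x="0" y="0" width="{_W}" height="{_H}" fill="white"/>')
    e.append(f'<text x="{_ML + _PW / 2:.1f}" y="24" font-size="15" text-anchor="middle">'
             f'{title}</text>')

    # axes box, ticks and grid every 20%
    e.append(f'<rect x="{_ML}" y="{_MT}" width="{_PW}" height="{_PH}" fill="none" '
             f'stroke="black" stroke-width="1"/>')
    for t in range(0, 101, 20):
        e.append(f'<line x1="{_sx(t):.1f}" y1="{_MT}" x2="{_sx(t):.1f}" y2="{_MT + _PH}" '
                 f'stroke="#dddddd" stroke-width="0.5"/>')
        e.append(f'<line x1="{_ML}" y1="{_sy(t):.1f}" x2="{_ML + _PW}" y2="{_sy(t):.1f}" '
                 f'stroke="#dddddd" stroke-width="0.5"/>')
        e.append(f'<text x="{_sx(t):.1f}" y="{_MT + _PH + 18}" font-size="11" '
                 f'text-anchor="middle">{t}</text>')
        e.append(f'<text x="{_ML - 8}" y="{_sy(t) + 4:.1f}" font-size="11" '
                 f'text-anchor="end">{t}</text>')
    e.append(f'<text x="{_ML + _PW / 2:.1f}" y="{_H - 16}" font-size="13" '
             f'text-anchor="middle">CV / TEa (%)</text>')
    e.append(f'<text x="20" y="{_MT + _PH / 2:.1f}" font-size="13" text-anchor="middle" '
             f'transform="rotate(-90 20 {_MT + _PH / 2:.1f})">Bias / TEa (%)</text>')

    # sigma boundary lines y = 100 - s*x, clipped to the 0..100 box
    for s in (2, 3, 4, 5, 6):
        x_end = min(100.0, 100.0 / s)  # where the line leaves the box (y=0)
        e.append(f'<line x1="{_sx(0):.1f}" y1="{_sy(100):.1f}" '
                 f'x2="{_sx(x_end):.1f}" y2="{_sy(100.0 - s * x_end):.1f}" '
                 f'stroke="#555555" stroke-width="1" stroke-dasharray="4,3"/>')
        lx = x_end * 0.92
        e.append(f'<text x="{_sx(lx) + 4:.1f}" y="{_sy(100.0 - s * lx) - 4:.1f}" '
                 f'font-size="10" fill="#555555">{s}&#963;</text>')

    # points, deterministic order
    for p in sorted(points, key=lambda p: (p.lab_id, p.analyte_id, p.level)):
        cx, cy = min(p.x, 100.0), min(p.y, 100.0)
        sx, sy = _sx(cx), _sy(cy)
        color = colors[p.lab_id]
        if p.x > 100.0 or p.y > 100.0:  # clamped: open triangle marks out-of-range
            e.append(f'<polygon points="{sx:.1f},{sy - 5:.1f} {sx - 5:.1f},{sy + 4:.1f} '
                     f'{sx + 5:.1f},{sy + 4:.1f}" fill="none" stroke="{color}" '
                     f'stroke-width="1.5"><title>{p.lab_id} {p.analyte_id} (out of range: '
                     f'x={_fmt(p.x)}, y={_fmt(p.y)})</title></polygon>')
        else:
            e.append(f'<circle cx="{sx:.1f}" cy="{sy:.1f}" r="4" fill="{color}" '
                     f'fill-opacity="0.85"><title>{p.lab_id} {p.analyte_id} '
                     f'(x={_fmt(p.x)}, y={_fmt(p.y)}, {p.zone})</title></circle>')

    # legend by lab
    lx0 = _ML + _PW + 20
    e.append(f'<text x="{lx0}" y="{_MT + 10}" font-size="12" font-weight="bold">Lab</text>')
    for i, lab in enumerate(labs):
        ly = _MT + 30 + i * 20
        e.append(f'<circle cx="{lx0 + 6}" cy="{ly - 4}" r="4" fill="{colors[lab]}"/>')
        e.append(f'<text x="{lx0 + 18}" y="{ly}" font-size="12">{lab}</text>')
    e.append("</svg>")

    out_path = Path(out_path)
    out_path.write_text("\n".join(e) + "\n", encoding="utf-8")
    return out_path
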