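"""Layout and SVG rendering of the three synchronized genome views.

Three levels of detail are drawn: **karyotype** (all chromosomes side
by side as banded ideograms), **chromosome** (one ideogram with band
labels and a highlighted slider window) and **zoom** (one lane per
annotation track over a chromosome interval).

Interactivity is represented headlessly: every drawable carries a
stable element id (``chr-10``, ``band-15-q11``,
``feat-genes-UBE3A``) and popup metadata is embedded as XML
attributes, so a thin HTML/JS wrapper can attach behavior later without
the renderer knowing about it.

Tracks are drawn with one of four devices:

* ``mark``  — a glyph at each feature's midpoint, single row;
* ``track`` — rectangles packed into rows so overlapping features
  stack (greedy first-fit);
* ``line``  — all rectangles on one row, overlaps allowed;
* ``chart`` — a histogram of feature counts in 100 equal-width bins.

Legends read ``{display_name} ({count})`` where the count is the number
of the track's features intersecting the window — clipped features are
"in this region" and count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence
from xml.sax.saxutils import escape, quoteattr

from .core import (
    Assembly,
    Cytoband,
    GenomicFeature,
    RegionQuery,
    TrackSource,
    clip_feature,
    regions_intersect,
)
from .query import DEFAULT_ENSEMBL_BASE, ensembl_region_url

__all__ = [
    "LayoutRow",
    "LegendEntry",
    "SceneElement",
    "Scene",
    "pack_features",
    "genome_to_pixel",
    "pixel_to_genome",
    "render_karyotype",
    "render_chromosome",
    "render_zoom",
    "feature_popup_info",
]

#: ideogram shading per Giemsa stain class
STAIN_FILL = {
    "gneg": "#ffffff",
    "gpos25": "#bfbfbf",
    "gpos50": "#808080",
    "gpos75": "#404040",
    "gpos100": "#000000",
    "acen": "#d92f2f",
    "gvar": "#d9d9d9",
    "stalk": "url(#stalk-hatch)",
}

CHART_BINS = 100


@dataclass(frozen=True)
class LayoutRow:
    """One packed row: features with their pixel intervals."""

    index: int
    placed: tuple[tuple[GenomicFeature, float, float], ...]


@dataclass(frozen=True)
class LegendEntry:
    display_name: str
    color: str
    count: int
    selected: bool = True

    @property
    def text(self) -> str:
        return f"{self.display_name} ({self.count})"


@dataclass(frozen=True)
class SceneElement:
    """A drawable's stable id plus its genomic anchor."""

    element_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Scene:
    view: str  # karyotype | chromosome | zoom
    width: int
    height: int
    svg: str
    elements: tuple[SceneElement, ...] = ()
    legend: tuple[LegendEntry, ...] = ()


# ---------------------------------------------------------------------------
# coordinate mapping and packing


def genome_to_pixel(pos: int, window: RegionQuery, width_px: float) -> float:
    """Affine base->pixel map: window.start -> 0, window.end -> width_px."""
    if pos < window.start or pos > window.end:
        raise ValueError(f"position {pos} outside window {window}")
    if window.end == window.start:
        return width_px / 2.0
    return (pos - window.start) / (window.end - window.start) * width_px


def pixel_to_genome(x: float, window: RegionQuery, width_px: float) -> int:
    """Inverse of :func:`genome_to_pixel`, rounded to the nearest base."""
    if window.end == window.start:
        return window.start
    pos = window.start + x / width_px * (window.end - window.start)
    return round(pos)


def pack_features(
    features: Iterable[GenomicFeature],
    min_gap_px: float,
    scale: Callable[[int], float],
) -> list[LayoutRow]:
    """Greedy first-fit row packing for the ``track`` device.

    Features are sorted by (start, end, feature_id) and each is placed
    in the lowest row whose occupied pixel intervals it clears by at
    least ``min_gap_px``.  The union of placed features equals the
    input.  ``scale`` must be monotone in the base coordinate.
    """
    ordered = sorted(features, key=lambda f: (f.start, f.end, f.feature_id))
    rows: list[list[tuple[GenomicFeature, float, float]]] = []
    row_right: list[float] = []  # rightmost occupied pixel per row
    for f in ordered:
        x0, x1 = scale(f.start), scale(f.end)
        placed = False
        for i in range(len(rows)):
            if x0 >= row_right[i] + min_gap_px:
                rows[i].append((f, x0, x1))
                row_right[i] = x1
                placed = True
                break
        if not placed:
            rows.append([(f, x0, x1)])
            row_right.append(x1)
    return [LayoutRow(i, tuple(r)) for i, r in enumerate(rows)]


# ---------------------------------------------------------------------------
# SVG assembly helpers


def _fmt(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return "0" if s in ("", "-0") else s


class _Svg:
    """Minimal deterministic SVG 1.1 document builder."""

    def __init__(self, width: int, height: int):
        self.width = width
        self.height = height
        self.lines: list[str] = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{width}" height="{height}" '
            f'viewBox="0 0 {width} {height}">',
            "  <defs>",
            '    <pattern id="stalk-hatch" width="4" height="4" '
            'patternUnits="userSpaceOnUse">'
            '<path d="M0,4 L4,0" stroke="#808080" stroke-width="1"/></pattern>',
            "  </defs>",
        ]

    def rect(self, x: float, y: float, w: float, h: float, fill: str,
             elem_id: str = "", stroke: str = "#333333",
             extra: Mapping[str, str] | None = None) -> None:
        attrs = []
        if elem_id:
            attrs.append(f"id={quoteattr(elem_id)}")
        attrs += [
            f'x="{_fmt(x)}"', f'y="{_fmt(y)}"',
            f'width="{_fmt(max(w, 0.5))}"', f'height="{_fmt(h)}"',
            f"fill={quoteattr(fill)}", f"stroke={quoteattr(stroke)}",
            'stroke-width="0.5"',
        ]
        for k in sorted(extra or {}):
            attrs.append(f"{k}={quoteattr(extra[k])}")
        self.lines.append(f"  <rect {' '.join(attrs)}/>")

    def circle(self, cx: float, cy: float, r: float, fill: str,
               elem_id: str = "", extra: Mapping[str, str] | None = None) -> None:
        attrs = []
        if elem_id:
            attrs.append(f"id={quoteattr(elem_id)}")
        attrs += [f'cx="{_fmt(cx)}"', f'cy="{_fmt(cy)}"', f'r="{_fmt(r)}"',
                  f"fill={quoteattr(fill)}"]
        for k in sorted(extra or {}):
            attrs.append(f"{k}={quoteattr(extra[k])}")
        self.lines.append(f"  <circle {' '.join(attrs)}/>")

    def text(self, x: float, y: float, s: str, size: int = 10,
             anchor: str = "start", elem_id: str = "") -> None:
        idp = f"id={quoteattr(elem_id)} " if elem_id else ""
        self.lines.append(
            f'  <text {idp}x="{_fmt(x)}" y="{_fmt(y)}" '
            f'font-size="{size}" font-family="sans-serif" '
            f'text-anchor="{anchor}">{escape(s)}</text>'
        )

    def finish(self) -> str:
        return "\n".join(self.lines + ["</svg>"]) + "\n"


def _popup_attrs(f: GenomicFeature, ensembl_base: str) -> dict[str, str]:
    info = feature_popup_info(f, ensembl_base=ensembl_base)
    attrs = {
        "data-label": info["Label"],
        "data-type-id": info["Type Id"],
        "data-method": info["Method"],
        "data-position": info["Position"],
        "data-ensembl": info["Display Annotations in Ensembl"],
    }
    if f.notes:
        attrs["data-notes"] = ";".join(f.notes)
    if f.links:
        attrs["data-links"] = ";".join(href for href, _ in f.links)
    return attrs


def feature_popup_info(
    f: GenomicFeature, ensembl_base: str = DEFAULT_ENSEMBL_BASE
) -> dict[str, str]:
    """Ordered popup fields for one feature.

    The Type Id field carries the DAS type id — for genotype sources
    this is the genotype call itself.  Score is omitted when absent.
    """
    info: dict[str, str] = {
        "Label": f.label,
        "Id": f.feature_id,
        "Type Id": f.type_id,
        "Method": f.method,
        "Position": f"{f.chrom}:{f.start}-{f.end}",
    }
    if f.score is not None:
        info["Score"] = _fmt(f.score)
    info["Notes"] = "; ".join(f.notes)
    info["Links"] = "; ".join(f"{text} <{href}>" for href, text in f.links)
    info["Display Annotations in Ensembl"] = ensembl_region_url(
        f.region, base=ensembl_base
    )
    return info


# ---------------------------------------------------------------------------
# karyotype view


def render_karyotype(
    assembly: Assembly,
    tracks: Sequence[tuple[TrackSource, Sequence[GenomicFeature]]] = (),
    *,
    width: int = 1200,
    max_chrom_height: int = 400,
    ensembl_base: str = DEFAULT_ENSEMBL_BASE,
) -> Scene:
    """Draw every chromosome side by side, lengths to scale.

    Each ideogram carries id ``chr-{name}`` for click-through into the
    chromosome view.  Tracks whose view set includes ``karyotype`` are
    drawn as marks beside the chromosomes.
    """
    if not assembly.chromosomes:
        raise ValueError("assembly has no chromosomes")
    n = len(assembly.chromosomes)
    max_len = max(c.length for c in assembly.chromosomes)
    top, label_h = 20, 16
    svg = _Svg(width, max_chrom_height + top + label_h + 10)
    slot = width / n
    bar_w = min(18.0, slot * 0.4)
    elements: list[SceneElement] = []
    legend: list[LegendEntry] = []

    kary_tracks = [(t, fs) for t, fs in tracks if "karyotype" in t.views]
    for t, fs in kary_tracks:
        legend.append(LegendEntry(t.display_name, t.color, len(fs)))

    for i, chrom in enumerate(assembly.chromosomes):
        x = i * slot + (slot - bar_w) / 2
        h = chrom.length / max_len * max_chrom_height
        y = top + (max_chrom_height - h)
        svg.rect(x, y, bar_w, h, "#f4f4f4", elem_id=f"chr-{chrom.name}")
        elements.append(SceneElement(f"chr-{chrom.name}", chrom.name, 1, chrom.length))
        scale = chrom.length / max_len * max_chrom_height
        for band in assembly.bands(chrom.name):
            by = top + (max_chrom_height - h) + (band.start - 1) / chrom.length * h
            bh = (band.end - band.start + 1) / chrom.length * h
            svg.rect(x, by, bar_w, bh, STAIN_FILL[band.stain])
        svg.text(x + bar_w / 2, top + max_chrom_height + 12, chrom.name,
                 anchor="middle")
        for t, fs in kary_tracks:
            for f in fs:
                if f.chrom != chrom.name:
                    continue
                mid = (f.start + f.end) / 2
                fy = top + (max_chrom_height - h) + (mid - 1) / chrom.length * h
                svg.circle(x + bar_w + 4, fy, 2.0, t.color,
                           elem_id=f"feat-{t.name}-{f.feature_id}",
                           extra=_popup_attrs(f, ensembl_base))
                elements.append(
                    SceneElement(f"feat-{t.name}-{f.feature_id}", f.chrom,
                                 f.start, f.end)
                )
    return Scene("karyotype", width, svg.height, svg.finish(),
                 tuple(elements), tuple(legend))


# ---------------------------------------------------------------------------
# chromosome view


def render_chromosome(
    assembly: Assembly,
    chrom: str,
    slider_window: Optional[RegionQuery] = None,
    tracks: Sequence[tuple[TrackSource, Sequence[GenomicFeature]]] = (),
    *,
    width: int = 1200,
    ensembl_base: str = DEFAULT_ENSEMBL_BASE,
) -> Scene:
    """Draw one horizontal ideogram with labelled bands and a slider highlight.

    Band elements carry ids ``band-{chrom}-{band_name}`` so a click can
    load the band's interval into the zoom view.
    """
    info = assembly.chromosome(chrom)  # raises KeyError for unknown chromosome
    chrom = info.name
    full = RegionQuery(chrom, 1, info.length)
    top, bar_h, height = 30, 28, 110
    svg = _Svg(width, height)
    elements: list[SceneElement] = []

    svg.rect(0, top, width, bar_h, "#f4f4f4", elem_id=f"chr-{chrom}")
    for band in assembly.bands(chrom):
        x0 = genome_to_pixel(band.start, full, width)
        x1 = genome_to_pixel(band.end, full, width)
        bid = f"band-{chrom}-{band.band_name}"
        svg.rect(x0, top, max(x1 - x0, 0.5), bar_h, STAIN_FILL[band.stain],
                 elem_id=bid)
        svg.text((x0 + x1) / 2, top + bar_h + 14, band.band_name,
                 size=9, anchor="middle")
        elements.append(SceneElement(bid, chrom, band.start, band.end))

    if slider_window is not None:
        if slider_window.chrom != chrom:
            raise ValueError("slider window is on a different chromosome")
        sx0 = genome_to_pixel(max(slider_window.start, 1), full, width)
        sx1 = genome_to_pixel(min(slider_window.end, info.length), full, width)
        svg.rect(sx0, top - 6, max(sx1 - sx0, 0.5), bar_h + 12, "none",
                 elem_id="slider-window", stroke="#e6a817")
        elements.append(
            SceneElement("slider-window", chrom, slider_window.start,
                         slider_window.end)
        )

    legend = []
    for t, fs in tracks:
        if "chromosome" not in t.views:
            continue
        on_chrom = [f for f in fs if f.chrom == chrom]
        legend.append(LegendEntry(t.display_name, t.color, len(on_chrom)))
        for f in on_chrom:
            mid = (f.start + f.end) / 2
            fx = genome_to_pixel(min(max(mid, 1), info.length), full, width)
            svg.circle(fx, top + bar_h + 24, 2.0, t.color,
                       elem_id=f"feat-{t.name}-{f.feature_id}",
                       extra=_popup_attrs(f, ensembl_base))
            elements.append(
                SceneElement(f"feat-{t.name}-{f.feature_id}", f.chrom,
                             f.start, f.end)
            )
    return Scene("chromosome", width, height, svg.finish(),
                 tuple(elements), tuple(legend))


# ---------------------------------------------------------------------------
# zoom view


def _draw_chart(svg: _Svg, feats: Sequence[GenomicFeature], window: RegionQuery,
                width: int, y: float, lane_h: float, color: str) -> None:
    counts = [0] * CHART_BINS
    span = window.end - window.start + 1
    for f in feats:
        mid = (f.start + f.end) // 2
        b = min((mid - window.start) * CHART_BINS // span, CHART_BINS - 1)
        counts[max(b, 0)] += 1
    peak = max(counts) or 1
    bin_w = width / CHART_BINS
    for i, c in enumerate(counts):
        if c == 0:
            continue
        h = c / peak * (lane_h - 4)
        svg.rect(i * bin_w, y + lane_h - 2 - h, bin_w, h, color, stroke="none")


def render_zoom(
    window: RegionQuery,
    tracks_with_features: Sequence[tuple[TrackSource, Sequence[GenomicFeature]]],
    *,
    width: int = 1200,
    lane_height: int = 52,
    min_gap_px: float = 2.0,
    ensembl_base: str = DEFAULT_ENSEMBL_BASE,
) -> Scene:
    """Draw the zoom view: one lane per selected track over ``window``.

    Features only partially inside the window are clipped to it and
    still counted in the legend.  Every feature element carries a
    stable id ``feat-{track}-{feature_id}`` and popup metadata
    attributes.  At least one track must be selected.
    """
    if not tracks_with_features:
        raise ValueError("at least one source has to be selected")
    legend: list[LegendEntry] = []
    elements: list[SceneElement] = []
    lanes: list[tuple[TrackSource, list[GenomicFeature], list[LayoutRow]]] = []
    scale = lambda pos: genome_to_pixel(pos, window, width)

    header_h, legend_row_h, ruler_h = 8, 16, 22
    for t, fs in tracks_with_features:
        clipped = [c for f in fs if (c := clip_feature(f, window)) is not None]
        clipped.sort(key=lambda f: (f.start, f.end, f.feature_id))
        legend.append(LegendEntry(t.display_name, t.color, len(clipped)))
        rows = (
            pack_features(clipped, min_gap_px, scale)
            if t.device == "track"
            else []
        )
        lanes.append((t, clipped, rows))

    lane_heights = []
    for t, clipped, rows in lanes:
        if t.device == "track":
            lane_heights.append(max(len(rows), 1) * 14 + 6)
        else:
            lane_heights.append(lane_height)
    height = (header_h + legend_row_h * len(lanes) + ruler_h
              + sum(lane_heights) + 10)
    svg = _Svg(width, height)

    y = header_h
    for entry in legend:
        svg.rect(4, y + 3, 10, 10, entry.color, stroke="none")
        svg.text(20, y + 12, entry.text, size=11,
                 elem_id=f"legend-{entry.display_name.replace(' ', '_')}")
        y += legend_row_h
    svg.text(4, y + 14, f"{window.chrom}:{window.start:,}-{window.end:,}",
             size=11)
    y += ruler_h

    for (t, clipped, rows), lh in zip(lanes, lane_heights):
        svg.rect(0, y, width, lh, "#fbfbfb", stroke="#dddddd")
        if t.device == "mark":
            for f in clipped:
                cx = scale((f.start + f.end) // 2)
                svg.circle(cx, y + lh / 2, 3.0, t.color,
                           elem_id=f"feat-{t.name}-{f.feature_id}",
                           extra=_popup_attrs(f, ensembl_base))
                elements.append(
                    SceneElement(f"feat-{t.name}-{f.feature_id}", f.chrom,
                                 f.start, f.end)
                )
        elif t.device == "track":
            for row in rows:
                ry = y + 4 + row.index * 14
                for f, x0, x1 in row.placed:
                    svg.rect(x0, ry, max(x1 - x0, 1.0), 10, t.color,
                             elem_id=f"feat-{t.name}-{f.feature_id}",
                             extra=_popup_attrs(f, ensembl_base))
                    elements.append(
                        SceneElement(f"feat-{t.name}-{f.feature_id}", f.chrom,
                                     f.start, f.end)
                    )
        elif t.device == "line":
            ry = y + lh / 2 - 5
            for f in clipped:
                x0, x1 = scale(f.start), scale(f.end)
                svg.rect(x0, ry, max(x1 - x0, 1.0), 10, t.color,
                         elem_id=f"feat-{t.name}-{f.feature_id}",
                         extra=_popup_attrs(f, ensembl_base))
                elements.append(
                    SceneElement(f"feat-{t.name}-{f.feature_id}", f.chrom,
                                 f.start, f.end)
                )
        elif t.device == "chart":
            _draw_chart(svg, clipped, window, width, y, lh, t.color)
            elements.append(
                SceneElement(f"chart-{t.name}", window.chrom, window.start,
                             window.end)
            )
        y += lh
    return Scene("zoom", width, height, svg.finish(), tuple(elements),
                 tuple(legend))
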