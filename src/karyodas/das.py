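"""DAS 1.53 XML I/O: sources, entry points, DASGFF features.

The reader is deliberately lenient (DAS 1.6E replies that differ only in
optional attributes still parse; unknown child elements are ignored);
the writer is strict and byte-stable, with fixed attribute order, ``\\n``
line endings and UTF-8 encoding, so that fixture output is reproducible
and round-trip tests can compare documents exactly.

Feature retrieval supports two transports:

* **HTTP mode** — ``location`` is a DAS base URL; a GET is issued to
  ``{base}/features?segment={chrom}:{start},{stop}``.
* **File mode** — ``location`` is a directory of canned replies named
  ``features.segment={chrom}_{start}_{stop}.xml`` plus a
  ``manifest.tsv`` (a local convention so test suites and offline
  sessions need no server).
"""

from __future__ import annotations

import logging
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

from .core import (
    ChromosomeInfo,
    GenomicFeature,
    RegionQuery,
    TrackSource,
    normalize_chrom,
    regions_intersect,
)

log = logging.getLogger(__name__)

__all__ = [
    "DasError",
    "DasParseError",
    "SourceUnavailableError",
    "WindowTooLargeError",
    "DasSourceDescriptor",
    "SegmentFeatures",
    "parse_features_doc",
    "parse_entry_points",
    "parse_sources_doc",
    "write_features_doc",
    "write_entry_points_doc",
    "fetch_features",
    "export_raw_text",
]

#: cap on a single features request, in bases; whole-genome pulls of
#: dense sources can hold far more than the few-thousand-feature scale
#: the renderer is designed for
MAX_WINDOW_BASES = 50_000_000

#: network policy for live sources
HTTP_TIMEOUT_S = 10.0
HTTP_RETRIES = 2


class DasError(Exception):
    """Base class for DAS client errors."""


class DasParseError(DasError):
    """Malformed DAS XML; message names the offending line where known."""


class SourceUnavailableError(DasError):
    """The remote source could not be reached; carries the URL tried."""

    def __init__(self, url: str, reason: str):
        self.url = url
        super().__init__(f"DAS source unavailable: {url} ({reason})")


class WindowTooLargeError(DasError):
    """Requested segment exceeds the single-request window cap."""


@dataclass(frozen=True)
class DasSourceDescriptor:
    """Metadata of one DAS source, as listed in a sources document."""

    source_id: str
    title: str
    base_url: str
    coordinates: str = ""
    capabilities: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SegmentFeatures:
    """Features served for one segment (the DASGFF SEGMENT container)."""

    segment: RegionQuery
    features: tuple[GenomicFeature, ...]
    source: str = ""

    def __post_init__(self) -> None:
        for f in self.features:
            if f.chrom != self.segment.chrom:
                raise ValueError(
                    f"feature {f.feature_id!r} on chrom {f.chrom!r} inside "
                    f"segment {self.segment.chrom!r}"
                )


# ---------------------------------------------------------------------------
# parsing


def _parse_xml(xml_text: str) -> etree._Element:
    try:
        return etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise DasParseError(f"malformed DAS XML: {exc}") from exc


def _text(elem: Optional[etree._Element]) -> str:
    return (elem.text or "").strip() if elem is not None else ""


def _parse_feature(fe: etree._Element, chrom: str) -> Optional[GenomicFeature]:
    fid = fe.get("id", "")
    label = fe.get("label") or fid
    type_el = fe.find("TYPE")
    method_el = fe.find("METHOD")
    start_s = _text(fe.find("START"))
    end_s = _text(fe.find("END"))
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        log.warning("feature %r: non-integer START/END (%r, %r); record dropped",
                    fid, start_s, end_s)
        return None
    if start > end:
        log.warning("feature %r: START %d > END %d; record dropped", fid, start, end)
        return None
    score_s = _text(fe.find("SCORE"))
    score: Optional[float] = None
    if score_s and score_s != "-":
        try:
            score = float(score_s)
        except ValueError:
            log.warning("feature %r: unparseable SCORE %r ignored", fid, score_s)
    strand = _text(fe.find("ORIENTATION")) or "."
    if strand not in ("+", "-", "."):
        strand = "."
    notes = tuple(_text(n) for n in fe.findall("NOTE"))
    links = tuple(
        (ln.get("href", ""), _text(ln)) for ln in fe.findall("LINK")
    )
    try:
        return GenomicFeature(
            feature_id=fid,
            label=label,
            chrom=chrom,
            start=start,
            end=end,
            type_id=type_el.get("id", "") if type_el is not None else "",
            type_label=_text(type_el),
            method=_text(method_el),
            score=score,
            strand=strand,
            notes=notes,
            links=links,
        )
    except ValueError as exc:
        log.warning("feature %r rejected: %s", fid, exc)
        return None


def parse_features_doc(xml_text: str, source: str = "") -> list[SegmentFeatures]:
    """Parse a DASGFF features document into one SegmentFeatures per SEGMENT.

    Records with START > END or other invariant violations are dropped
    with a logged warning; the rest of the document still parses.
    """
    root = _parse_xml(xml_text)
    out: list[SegmentFeatures] = []
    for seg in root.iter("SEGMENT"):
        chrom = normalize_chrom(seg.get("id", ""))
        try:
            start = int(seg.get("start", "1"))
            stop = int(seg.get("stop", seg.get("end", "1")))
        except ValueError as exc:
            raise DasParseError(f"SEGMENT {chrom!r}: bad start/stop: {exc}") from exc
        feats = []
        for fe in seg.findall("FEATURE"):
            f = _parse_feature(fe, chrom)
            if f is not None:
                feats.append(f)
        out.append(
            SegmentFeatures(
                segment=RegionQuery(chrom, start, max(stop, start)),
                features=tuple(feats),
                source=source,
            )
        )
    return out


def parse_entry_points(xml_text: str) -> list[ChromosomeInfo]:
    """Parse a DAS entry_points document into chromosome lengths.

    Segments without a usable ``stop`` attribute are skipped with a warning.
    """
    root = _parse_xml(xml_text)
    out: list[ChromosomeInfo] = []
    for seg in root.iter("SEGMENT"):
        name = normalize_chrom(seg.get("id", ""))
        stop_s = seg.get("stop", seg.get("size", ""))
        try:
            stop = int(stop_s)
        except ValueError:
            log.warning("entry point %r: missing/bad stop %r; skipped", name, stop_s)
            continue
        out.append(ChromosomeInfo(name, stop))
    return out


def parse_sources_doc(xml_text: str) -> list[DasSourceDescriptor]:
    """Parse a DAS sources document into source descriptors."""
    root = _parse_xml(xml_text)
    out = []
    for src in root.iter("SOURCE"):
        caps = set()
        base_url = ""
        coords = ""
        for ver in src.findall("VERSION"):
            for cap in ver.findall("CAPABILITY"):
                ctype = cap.get("type", "")
                caps.add(ctype.split(":")[-1])
                if ctype.endswith("features"):
                    base_url = (cap.get("query_uri", "") or "").rsplit("/features", 1)[0]
            coord = ver.find("COORDINATES")
            if coord is not None:
                coords = _text(coord)
        out.append(
            DasSourceDescriptor(
                source_id=src.get("uri", ""),
                title=src.get("title", src.get("uri", "")),
                base_url=base_url,
                coordinates=coords,
                capabilities=frozenset(caps),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writing


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _fmt_score(score: float) -> str:
    # integral scores print without a trailing .0 so round-trips are stable
    return repr(score) if score != int(score) else str(int(score))


def write_features_doc(segments: Iterable[SegmentFeatures]) -> str:
    """Serialize segments as a DASGFF document.

    Output is byte-stable: fixed attribute order, two-space indentation,
    ``\\n`` line endings.  ``parse_features_doc`` inverts it exactly.
    """
    lines = [
        '<?xml version="1.0" encoding="UTF-8" standalone="no"?>',
        "<DASGFF>",
        '  <GFF version="1.0">',
    ]
    for sf in segments:
        seg = sf.segment
        lines.append(
            f'    <SEGMENT id="{_xml_escape(seg.chrom)}" start="{seg.start}" '
            f'stop="{seg.end}" version="1.0">'
        )
        for f in sf.features:
            lines.append(
                f'      <FEATURE id="{_xml_escape(f.feature_id)}" '
                f'label="{_xml_escape(f.label)}">'
            )
            lines.append(
                f'        <TYPE id="{_xml_escape(f.type_id)}">'
                f"{_xml_escape(f.type_label)}</TYPE>"
            )
            lines.append(f"        <METHOD>{_xml_escape(f.method)}</METHOD>")
            lines.append(f"        <START>{f.start}</START>")
            lines.append(f"        <END>{f.end}</END>")
            if f.score is not None:
                lines.append(f"        <SCORE>{_fmt_score(f.score)}</SCORE>")
            lines.append(f"        <ORIENTATION>{f.strand}</ORIENTATION>")
            for note in f.notes:
                lines.append(f"        <NOTE>{_xml_escape(note)}</NOTE>")
            for href, text in f.links:
                lines.append(
                    f'        <LINK href="{_xml_escape(href)}">'
                    f"{_xml_escape(text)}</LINK>"
                )
            lines.append("      </FEATURE>")
        lines.append("    </SEGMENT>")
    lines.append("  </GFF>")
    lines.append("</DASGFF>")
    return "\n".join(lines) + "\n"


def write_entry_points_doc(chromosomes: Iterable[ChromosomeInfo]) -> str:
    """Serialize chromosome lengths as a DAS entry_points document."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8" standalone="no"?>',
        "<DASEP>",
        "  <ENTRY_POINTS>",
    ]
    for c in chromosomes:
        lines.append(
            f'    <SEGMENT id="{_xml_escape(c.name)}" start="1" '
            f'stop="{c.length}" orientation="+"/>'
        )
    lines.append("  </ENTRY_POINTS>")
    lines.append("</DASEP>")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# retrieval


def _segment_file_name(chrom: str, start: int, stop: int) -> str:
    return f"features.segment={chrom}_{start}_{stop}.xml"


_SEGMENT_FILE_RE = re.compile(r"^features\.segment=(\w+)_(\d+)_(\d+)\.xml$")


def _fetch_http(url: str, timeout: float, retries: int) -> str:
    last_err: Exception | None = None
    for attempt in range(retries + 1):
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                if resp.status != 200:
                    raise SourceUnavailableError(url, f"HTTP {resp.status}")
                return resp.read().decode("utf-8")
        except SourceUnavailableError:
            raise
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            last_err = exc
            if attempt < retries:
                time.sleep(0.2 * (attempt + 1))
    raise SourceUnavailableError(url, str(last_err))


def fetch_features(
    source: TrackSource,
    region: RegionQuery,
    *,
    cache: Optional[dict] = None,
    timeout: float = HTTP_TIMEOUT_S,
    retries: int = HTTP_RETRIES,
    max_window: int = MAX_WINDOW_BASES,
) -> SegmentFeatures:
    """Fetch the features of ``source`` intersecting ``region``.

    One request is issued per (source, window); replies containing
    multiple SEGMENTs are merged.  A ``cache`` dict, if given, memoizes
    bodies per (location, segment) for the session.

    Raises :class:`WindowTooLargeError` above ``max_window`` bases and
    :class:`SourceUnavailableError` on network failure; an unavailable
    source never corrupts other tracks (the error carries the URL).
    """
    if region.end - region.start + 1 > max_window:
        raise WindowTooLargeError(
            f"window {region} spans {region.end - region.start + 1} bases; "
            f"cap is {max_window} per request"
        )
    loc = source.location
    if loc.startswith(("http://", "https://")):
        url = f"{loc.rstrip('/')}/features?segment={region.chrom}:{region.start},{region.end}"
        if cache is not None and url in cache:
            body = cache[url]
        else:
            body = _fetch_http(url, timeout, retries)
            if cache is not None:
                cache[url] = body
        segments = parse_features_doc(body, source=source.name)
    else:
        segments = _read_file_mode(Path(loc), region, source.name)

    feats = [
        f
        for sf in segments
        for f in sf.features
        if regions_intersect(f.region, region)
    ]
    feats.sort(key=lambda f: (f.start, f.end, f.feature_id))
    return SegmentFeatures(segment=region, features=tuple(feats), source=source.name)


def load_all_features(source: TrackSource) -> list[SegmentFeatures]:
    """Load every canned segment of a file-mode source.

    Whole-source scans back identifier lookups (rsID, gene symbol); they
    are only supported for local sources, since a remote DAS server
    cannot be enumerated without a segment.
    """
    directory = Path(source.location)
    if source.location.startswith(("http://", "https://")):
        raise DasError(
            f"source {source.name!r} is remote; identifier lookup requires "
            "a local file-mode source"
        )
    if not directory.is_dir():
        raise SourceUnavailableError(str(directory), "not a directory")
    out: list[SegmentFeatures] = []
    for p in sorted(directory.iterdir()):
        if _SEGMENT_FILE_RE.match(p.name):
            out.extend(parse_features_doc(p.read_text("utf-8"), source=source.name))
    return out


def _read_file_mode(
    directory: Path, region: RegionQuery, source_name: str
) -> list[SegmentFeatures]:
    if not directory.is_dir():
        raise SourceUnavailableError(str(directory), "not a directory")
    out: list[SegmentFeatures] = []
    for p in sorted(directory.iterdir()):
        m = _SEGMENT_FILE_RE.match(p.name)
        if not m:
            continue
        chrom, start, stop = m.group(1), int(m.group(2)), int(m.group(3))
        if chrom != region.chrom:
            continue
        if not regions_intersect(RegionQuery(chrom, start, stop), region):
            continue
        out.extend(parse_features_doc(p.read_text("utf-8"), source=source_name))
    return out


# ---------------------------------------------------------------------------
# raw export ("Show Original Source")

_RAW_HEADER = (
    "feature_id\tlabel\tchrom\tstart\tend\ttype_id\tmethod\tscore\tnotes"
)


def export_raw_text(sf: SegmentFeatures) -> str:
    """Dump a segment's features as copy-pasteable tab-separated text.

    Rows are sorted by (start, end, feature_id); an empty segment yields
    the header line only.
    """
    rows = [_RAW_HEADER]
    for f in sorted(sf.features, key=lambda f: (f.start, f.end, f.feature_id)):
        score = "" if f.score is None else _fmt_score(f.score)
        rows.append(
            "\t".join(
                [
                    f.feature_id,
                    f.label,
                    f.chrom,
                    str(f.start),
                    str(f.end),
                    f.type_id,
                    f.method,
                    score,
                    ";".join(f.notes),
                ]
            )
        )
    return "\n".join(rows) + "\n"
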