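"""Query parsing and resolution: region strings, gene symbols, rsIDs.

The query grammar mirrors the search box of a genome browser: a
chromosome location is a chromosome, start and end separated by a colon
and a comma (``1:2000000,3000000``); an rs-number routes to SNP search;
anything else is treated as a gene symbol.  The Unicode ratio colon
(U+2236), which word processors substitute for ASCII ``:``, is accepted
as well.

SNP resolution centres a zoom window of +-100 kb (configurable) on the
SNP position; gene resolution uses the gene's own start/end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .core import Assembly, RegionQuery, TrackSource, normalize_chrom
from .das import load_all_features

log = logging.getLogger(__name__)

__all__ = [
    "QueryError",
    "InvalidQueryError",
    "NotFoundError",
    "AmbiguousGeneError",
    "ParsedQuery",
    "SessionConfig",
    "parse_query",
    "resolve_snp",
    "resolve_gene",
    "suggest_genes",
    "ensembl_region_url",
    "load_config",
]

#: half-width of the window centred on a SNP hit, in bases
DEFAULT_SNP_WINDOW_HALF = 100_000
#: archive host serving the NCBI36-era coordinate system
DEFAULT_ENSEMBL_BASE = "http://may2009.archive.ensembl.org"

_REGION_RE = re.compile(r"^(?:chr)?(\w+):(\d+),(\d+)$", re.IGNORECASE)
_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
#: Unicode ratio colon, seen when queries pass through word processors
_RATIO_COLON = "∶"


class QueryError(Exception):
    """Base class for query-layer errors."""


class InvalidQueryError(QueryError):
    """Syntactically invalid query string."""


class NotFoundError(QueryError):
    """rsID or gene symbol absent from every loaded source."""


class AmbiguousGeneError(QueryError):
    """Several features share the requested gene symbol."""

    def __init__(self, symbol: str, candidates: Sequence[str]):
        self.candidates = list(candidates)
        super().__init__(
            f"gene symbol {symbol!r} is ambiguous: {', '.join(candidates)}"
        )


@dataclass(frozen=True)
class ParsedQuery:
    """A routed query: exactly one of region / gene symbol / rsid."""

    kind: str  # region | gene | snp
    payload: Union[RegionQuery, str]

    def __post_init__(self) -> None:
        if self.kind not in ("region", "gene", "snp"):
            raise ValueError(f"unknown query kind {self.kind!r}")
        if self.kind == "region" and not isinstance(self.payload, RegionQuery):
            raise ValueError("region query requires a RegionQuery payload")
        if self.kind in ("gene", "snp") and not isinstance(self.payload, str):
            raise ValueError(f"{self.kind} query requires a string payload")


def parse_query(s: str) -> ParsedQuery:
    """Route a raw query string to region, SNP or gene search.

    Routing is total: every non-empty string yields exactly one kind or
    raises :class:`InvalidQueryError`.  Disambiguation is syntactic —
    ``rs``-prefixed numbers are SNPs and never fall back to gene search.
    """
    s = s.strip().replace(_RATIO_COLON, ":")
    if not s:
        raise InvalidQueryError("empty query")
    m = _REGION_RE.match(s)
    if m:
        chrom, start, end = normalize_chrom(m.group(1)), int(m.group(2)), int(m.group(3))
        if start < 1:
            raise InvalidQueryError(f"region start must be >= 1, got {start}")
        if end < start:
            raise InvalidQueryError(f"region end ({end}) before start ({start})")
        return ParsedQuery("region", RegionQuery(chrom, start, end))
    if _RSID_RE.match(s):
        return ParsedQuery("snp", s.lower())
    return ParsedQuery("gene", s)


def _clamp_window(
    chrom: str, center: int, half: int, assembly: Optional[Assembly]
) -> RegionQuery:
    start = max(1, center - half)
    end = center + half
    if assembly is not None:
        end = min(end, assembly.chromosome(chrom).length)
    return RegionQuery(chrom, start, end)


def resolve_snp(
    rsid: str,
    sources: Sequence[TrackSource],
    assembly: Optional[Assembly] = None,
    half_width: int = DEFAULT_SNP_WINDOW_HALF,
) -> RegionQuery:
    """Resolve an rsID to a zoom window centred +-``half_width`` on its position.

    Sources are scanned in roster order; the first one carrying the
    rsID fixes the position, and a conflicting position in a later
    source is logged as a warning.  The window is clamped to the
    chromosome when an assembly is supplied.
    """
    rsid = rsid.lower()
    hit: Optional[tuple[str, int]] = None
    for src in sources:
        try:
            segments = load_all_features(src)
        except Exception as exc:  # a broken source must not hide the others
            log.warning("source %s skipped during SNP lookup: %s", src.name, exc)
            continue
        for sf in segments:
            for f in sf.features:
                if f.feature_id.lower() == rsid:
                    if hit is None:
                        hit = (f.chrom, f.start)
                    elif (f.chrom, f.start) != hit:
                        log.warning(
                            "rsid %s at %s:%d in source %s conflicts with "
                            "first-loaded position %s:%d; first wins",
                            rsid, f.chrom, f.start, src.name, hit[0], hit[1],
                        )
    if hit is None:
        raise NotFoundError(f"rsid {rsid!r} not found in any loaded source")
    chrom, pos = hit
    return _clamp_window(chrom, pos, half_width, assembly)


def resolve_gene(symbol: str, gene_track: TrackSource) -> RegionQuery:
    """Resolve a gene symbol (case-insensitive exact label match) to its span."""
    matches = [
        f
        for sf in load_all_features(gene_track)
        for f in sf.features
        if f.label.lower() == symbol.lower()
    ]
    if not matches:
        raise NotFoundError(f"gene symbol {symbol!r} not found in track "
                            f"{gene_track.name!r}")
    if len({(f.chrom, f.start, f.end) for f in matches}) > 1:
        raise AmbiguousGeneError(
            symbol, [f"{f.label}@{f.chrom}:{f.start}-{f.end}" for f in matches]
        )
    f = matches[0]
    return RegionQuery(f.chrom, f.start, f.end)


def suggest_genes(
    prefix: str, gene_track: TrackSource, limit: int = 20
) -> list[str]:
    """Case-insensitive prefix suggestions, sorted, capped at ``limit``."""
    if not prefix:
        return []
    p = prefix.lower()
    symbols = {
        f.label
        for sf in load_all_features(gene_track)
        for f in sf.features
        if f.label.lower().startswith(p)
    }
    return sorted(symbols)[:limit]


def ensembl_region_url(w: RegionQuery, base: str = DEFAULT_ENSEMBL_BASE) -> str:
    """Deterministic Ensembl region-view URL for a window."""
    return (
        f"{base.rstrip('/')}/Homo_sapiens/Location/View"
        f"?r={w.chrom}:{w.start}-{w.end}"
    )


# ---------------------------------------------------------------------------
# session configuration


@dataclass
class SessionConfig:
    """Session settings: assembly, SNP window, Ensembl base, track roster."""

    assembly_id: str = "NCBI36"
    snp_window_half: int = DEFAULT_SNP_WINDOW_HALF
    ensembl_base: str = DEFAULT_ENSEMBL_BASE
    tracks: list[TrackSource] = field(default_factory=list)


def load_config(path: str | Path) -> SessionConfig:
    """Read a plain ``key=value`` config file.

    Recognised keys: ``assembly``, ``snp_window_half``, ``ensembl_base``
    and repeated ``track`` lines of the form
    ``name|display name|location|device|view+view|#colour``.
    Unknown keys are ignored with a warning; ``#`` lines are comments.
    """
    cfg = SessionConfig()
    for lineno, raw in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            log.warning("config line %d: no '='; ignored", lineno)
            continue
        key, value = (part.strip() for part in line.split("=", 1))
        if key == "assembly":
            cfg.assembly_id = value
        elif key == "snp_window_half":
            cfg.snp_window_half = int(value)
        elif key == "ensembl_base":
            cfg.ensembl_base = value
        elif key == "track":
            fields = [f.strip() for f in value.split("|")]
            if len(fields) != 6:
                log.warning("config line %d: track needs 6 '|' fields; ignored",
                            lineno)
                continue
            name, display, location, device, views, color = fields
            cfg.tracks.append(
                TrackSource(name, display, location, device=device,
                            views=tuple(views.split("+")), color=color)
            )
        else:
            log.warning("config line %d: unknown key %r ignored", lineno, key)
    return cfg
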