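"""Core domain model: genomic features, tracks, assemblies and interval algebra.

All coordinates in this package are 1-based and fully inclusive, the
convention of the DAS 1.53 segment addressing scheme (``chrom:start,end``
where both endpoints are annotated bases).  Any 0-based half-open input
dialect (BED-style positions) must be converted at the I/O boundary.

Chromosome names are stored bare, without a ``chr`` prefix (``"10"``,
``"X"``); parsers strip a leading ``chr`` case-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "GenomicFeature",
    "TrackSource",
    "ChromosomeInfo",
    "Cytoband",
    "RegionQuery",
    "Assembly",
    "normalize_chrom",
    "region_length",
    "regions_intersect",
    "clip_feature",
]

#: drawing styles a track may use ("device" in genome-browser parlance)
DEVICES = ("mark", "track", "line", "chart")
#: the three synchronized zoom levels
VIEWS = ("karyotype", "chromosome", "zoom")
#: recognised Giemsa stain classes for ideogram shading
STAINS = ("gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar", "stalk")


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome name."""
    name = name.strip()
    if name[:3].lower() == "chr":
        name = name[3:]
    return name


@dataclass(frozen=True)
class RegionQuery:
    """A chromosome interval, 1-based inclusive at both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"region end ({self.end}) must be >= start ({self.start})"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start},{self.end}"


@dataclass(frozen=True)
class GenomicFeature:
    """One annotation record as served by a DAS features request.

    ``type_id`` carries the DAS TYPE id; for personal-genotype sources
    the convention is that the type id *is* the genotype call ("TT").
    """

    feature_id: str
    label: str
    chrom: str
    start: int
    end: int
    type_id: str
    type_label: str = ""
    method: str = ""
    score: Optional[float] = None
    strand: str = "."
    notes: tuple[str, ...] = ()
    links: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end}]"
            )
        if not self.type_id:
            raise ValueError(f"feature {self.feature_id!r}: empty type_id")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    @property
    def region(self) -> RegionQuery:
        return RegionQuery(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TrackSource:
    """A named annotation source plus its display configuration.

    ``location`` is either an ``http(s)`` DAS base URL or a local
    file-mode directory (see :mod:`karyodas.das`).
    """

    name: str
    display_name: str
    location: str
    device: str = "track"
    views: tuple[str, ...] = ("zoom",)
    color: str = "#1f77b4"

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValueError(
                f"track {self.name!r}: device must be one of {DEVICES}, "
                f"got {self.device!r}"
            )
        if not self.views:
            raise ValueError(f"track {self.name!r}: views must be non-empty")
        bad = [v for v in self.views if v not in VIEWS]
        if bad:
            raise ValueError(f"track {self.name!r}: unknown views {bad}")


@dataclass(frozen=True)
class ChromosomeInfo:
    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")


@dataclass(frozen=True)
class Cytoband:
    """A Giemsa band (e.g. 15q11) with its stain class."""

    chrom: str
    start: int
    end: int
    band_name: str
    stain: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"band {self.band_name!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.stain not in STAINS:
            raise ValueError(f"band {self.band_name!r}: unknown stain {self.stain!r}")


@dataclass(frozen=True)
class Assembly:
    """A reference assembly: ordered chromosomes plus cytoband table.

    Chromosome order is the left-to-right display order of the
    karyotype view.  Default coordinate system is human NCBI36 to match
    the 23andMe raw-file coordinate basis.
    """

    assembly_id: str = "NCBI36"
    chromosomes: tuple[ChromosomeInfo, ...] = ()
    cytobands: tuple[Cytoband, ...] = ()

    def __post_init__(self) -> None:
        if not self.assembly_id:
            raise ValueError("assembly_id must be non-empty")
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in assembly")

    def chromosome(self, name: str) -> ChromosomeInfo:
        name = normalize_chrom(name)
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in assembly {self.assembly_id}")

    def bands(self, chrom: str) -> tuple[Cytoband, ...]:
        chrom = normalize_chrom(chrom)
        return tuple(b for b in self.cytobands if b.chrom == chrom)


def region_length(r: RegionQuery) -> int:
    """Number of bases in ``r`` under the inclusive convention."""
    return r.end - r.start + 1


def regions_intersect(a: RegionQuery, b: RegionQuery) -> bool:
    """True iff the two regions share at least one base."""
    return a.chrom == b.chrom and max(a.start, b.start) <= min(a.end, b.end)


def clip_feature(f: GenomicFeature, w: RegionQuery) -> Optional[GenomicFeature]:
    """Clamp a feature into a window, or return None if they are disjoint.

    All non-coordinate fields are preserved on the clipped copy.
    """
    if not regions_intersect(f.region, w):
        return None
    return replace(f, start=max(f.start, w.start), end=min(f.end, w.end))
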