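"""Direct-to-consumer genotype profiles and family (trio) analysis.

Parses 23andMe-style raw downloads (tab-separated rsid / chromosome /
position / genotype, ``#`` comment header), converts a profile into DAS
feature segments — the type id of each feature *is* the genotype call —
and checks Mendelian consistency of child/mother/father calls at a site.

Insertion/deletion alleles (D, I) are carried as opaque allele symbols;
trio splitting is allele-agnostic.  ``--`` denotes an assayed no-call,
which is distinct from a site absent from the chip ("not assayed"):
density counts reflect chip content, so no-calls count and absent sites
do not.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Optional, Sequence

from .core import GenomicFeature, RegionQuery, normalize_chrom
from .das import SegmentFeatures

log = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "PersonProfile",
    "InheritanceVerdict",
    "NOT_ASSAYED",
    "parse_raw_genotypes",
    "profile_to_features",
    "features_to_profile",
    "mendelian_consistency",
    "genotype_table",
    "snp_density",
]

#: marker returned by genotype_table for a site absent from a chip;
#: distinct from the assayed-but-failed call "--"
NOT_ASSAYED = "not assayed"

_RSID_RE = re.compile(r"^(rs|i)\d+$")
_CALL_RE = re.compile(r"^[ACGTDI\-]{1,2}$")


@dataclass(frozen=True)
class Genotype:
    """One genotyping call: rsid, genomic position and 1-2 allele string."""

    rsid: str
    chrom: str
    pos: int
    call: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        if not (1 <= len(self.call) <= 2):
            raise ValueError(f"{self.rsid}: call {self.call!r} must have 1-2 alleles")


@dataclass(frozen=True)
class PersonProfile:
    """One individual's call set, keyed by rsid."""

    label: str
    relation: str = "other"  # self | mother | father | sibling | other
    calls: Mapping[str, Genotype] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class InheritanceVerdict:
    """Outcome of a single-site trio consistency check.

    ``transmissions`` holds every (maternal allele, paternal allele)
    assignment compatible with the trio when consistent.
    """

    consistent: bool
    transmissions: frozenset[tuple[str, str]] = frozenset()
    reason: str = ""

    def __post_init__(self) -> None:
        if self.consistent and not self.transmissions:
            raise ValueError("consistent verdict requires >= 1 transmission")


def parse_raw_genotypes(text: str, label: str = "", relation: str = "other") -> PersonProfile:
    """Parse a 23andMe-style raw genotype text into a profile.

    Lines starting ``#`` are comments.  Data rows are tab-separated
    rsid, chromosome, position, genotype.  Malformed rows are dropped
    with a warning; on duplicate rsids the last row wins.
    """
    calls: dict[str, Genotype] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            log.warning("line %d: fewer than 4 columns; row dropped", lineno)
            continue
        rsid, chrom, pos_s, call = (p.strip() for p in parts[:4])
        try:
            pos = int(pos_s)
        except ValueError:
            log.warning("line %d: non-integer position %r; row dropped", lineno, pos_s)
            continue
        if not _CALL_RE.match(call):
            log.warning("line %d: unrecognized genotype %r; row dropped", lineno, call)
            continue
        try:
            g = Genotype(rsid, normalize_chrom(chrom), pos, call)
        except ValueError as exc:
            log.warning("line %d: %s; row dropped", lineno, exc)
            continue
        if rsid in calls:
            log.warning("duplicate rsid %s: last row wins", rsid)
        calls[rsid] = g
    return PersonProfile(label=label, relation=relation, calls=calls)


def format_raw_genotypes(p: PersonProfile) -> str:
    """Serialize a profile back into the raw dialect (header + rows).

    Rows are ordered by (chrom, pos, rsid); ``parse_raw_genotypes``
    inverts the output exactly.
    """
    lines = [
        "# This data file generated by karyodas",
        "# rsid\tchromosome\tposition\tgenotype",
    ]
    for g in sorted(p.calls.values(), key=lambda g: (g.chrom, g.pos, g.rsid)):
        lines.append(f"{g.rsid}\t{g.chrom}\t{g.pos}\t{g.call}")
    return "\n".join(lines) + "\n"


def profile_to_features(p: PersonProfile) -> list[SegmentFeatures]:
    """Turn a profile into DAS segments, one per chromosome.

    Each call becomes a 1-base feature at its position whose type id
    carries the genotype string, so a DAS client popup shows the call
    in its Type Id field.
    """
    by_chrom = sorted(p.calls.values(), key=lambda g: (g.chrom, g.pos, g.rsid))
    out: list[SegmentFeatures] = []
    for chrom, group in groupby(by_chrom, key=lambda g: g.chrom):
        calls = list(group)
        feats = tuple(
            GenomicFeature(
                feature_id=g.rsid,
                label=g.rsid,
                chrom=chrom,
                start=g.pos,
                end=g.pos,
                type_id=g.call,
                type_label="genotype",
                method="genotyping",
            )
            for g in calls
        )
        out.append(
            SegmentFeatures(
                segment=RegionQuery(chrom, calls[0].pos, calls[-1].pos),
                features=feats,
                source=p.label,
            )
        )
    return out


def features_to_profile(
    segments: Iterable[SegmentFeatures], label: str = "", relation: str = "other"
) -> PersonProfile:
    """Inverse of :func:`profile_to_features` for genotype sources."""
    calls = {
        f.feature_id: Genotype(f.feature_id, f.chrom, f.start, f.type_id)
        for sf in segments
        for f in sf.features
    }
    return PersonProfile(label=label, relation=relation, calls=calls)


def mendelian_consistency(child: str, mother: str, father: str) -> InheritanceVerdict:
    """Check a child's diploid call against the parents' calls at one site.

    The trio is consistent iff the child's allele pair splits into one
    allele drawn from the mother's pair and one from the father's
    (unordered within the child).  All compatible (maternal, paternal)
    transmissions are enumerated.  Any ``--`` participant makes the
    verdict undecidable, as does a hemizygous (single-letter) call.
    """
    for who, call in (("child", child), ("mother", mother), ("father", father)):
        if len(call) == 1:
            return InheritanceVerdict(
                False,
                reason=f"hemizygous site — autosomal trio logic not applicable ({who}={call})",
            )
        if len(call) != 2:
            return InheritanceVerdict(False, reason=f"{who} call {call!r} is not diploid")
        if call == "--":
            return InheritanceVerdict(False, reason=f"{who} has no call at this site")

    transmissions = set()
    child_pair = sorted(child)
    for m in mother:
        for f in father:
            if sorted((m, f)) == child_pair:
                transmissions.add((m, f))
    if transmissions:
        return InheritanceVerdict(True, frozenset(transmissions))
    return InheritanceVerdict(
        False,
        reason=(
            f"child {child} cannot be formed from mother {mother} "
            f"and father {father}"
        ),
    )


def genotype_table(
    rsid: str, profiles: Sequence[PersonProfile]
) -> dict[str, str]:
    """Calls of every profile at one rsid, in profile order.

    A profile whose chip lacks the rsid maps to :data:`NOT_ASSAYED`,
    which is distinct from the assayed no-call ``--``.
    """
    if not profiles:
        raise ValueError("genotype_table requires at least one profile")
    return {
        p.label: (p.calls[rsid].call if rsid in p.calls else NOT_ASSAYED)
        for p in profiles
    }


def snp_density(p: PersonProfile, w: RegionQuery) -> int:
    """Number of assayed sites (including no-calls) inside a window."""
    return sum(
        1
        for g in p.calls.values()
        if g.chrom == w.chrom and w.start <= g.pos <= w.end
    )
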