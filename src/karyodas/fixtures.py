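"""Deterministic synthetic fixtures: DAS file-mode sources, cytobands, raw files.

Two curated scenarios are generated alongside randomized stress inputs:

* the **family case** — five personal-genotype sources (son, mother,
  father, sister, aunt) around the prostate-cancer risk marker
  rs10993994 on chromosome 10, next to the MSMB gene, with a
  cancer-mutation track and two copy-number-variation tracks; and
* the **region case** — a chromosome-15 gene track with 45 genes in
  20,000,000-24,000,000 (the 15q11 deletion region of Prader-Willi /
  Angelman syndromes), 15 of them disease genes including UBE3A, plus a
  0.4 Mb deletion ("Variation 7051") overlapping UBE3A.

Landmark coordinates (rs10993994 at 51,219,502; MSMB start 51,219,559,
57 bp downstream of the SNP; four somatic mutations within MSMB; the
2x SNP-chip density difference between the son's chip and the newer
chip of the other family members) are fixed constants of the scenario.
All other coordinates are invented and may change between versions —
assert only the landmarks.

Everything is reproducible: the same seed yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .core import (
    Assembly,
    ChromosomeInfo,
    Cytoband,
    GenomicFeature,
    RegionQuery,
    TrackSource,
)
from .das import SegmentFeatures, write_entry_points_doc, write_features_doc
from .personal import Genotype, PersonProfile, format_raw_genotypes

__all__ = [
    "FixtureManifest",
    "synthetic_assembly",
    "make_family_case",
    "make_region_case",
    "make_random_tracks",
    "make_raw_genotype_file",
    "family_track_sources",
    "region_track_sources",
    "RS10993994_POS",
    "MSMB_START",
    "MSMB_END",
    "FAMILY_WINDOW",
]

# -- family-case landmarks (scenario constants) -----------------------------
RS10993994_POS = 51_219_502
MSMB_START = 51_219_559  # 57 bp after the SNP
MSMB_END = 51_232_000  # invented; only the start is a landmark
SNP_WINDOW_HALF = 100_000
FAMILY_WINDOW = RegionQuery(
    "10", RS10993994_POS - SNP_WINDOW_HALF, RS10993994_POS + SNP_WINDOW_HALF
)
FAMILY_GENOTYPES = {
    "son": "TT",
    "mother": "CT",
    "father": "CT",
    "sister": "CT",
    "aunt": "CC",
}

# -- region-case landmarks ---------------------------------------------------
REGION_CASE_WINDOW = RegionQuery("15", 20_000_000, 24_000_000)
UBE3A_START = 23_133_000  # invented interval; overlap with the CNV is the landmark
UBE3A_END = 23_235_000
VARIATION_7051_START = 23_000_000
VARIATION_7051_LEN = 400_000  # the reported 0.4 Mb deletion

# NCBI36 (hg18) chromosome lengths, the assembly of 23andMe raw files
_NCBI36_LENGTHS: tuple[tuple[str, int], ...] = (
    ("1", 247_249_719), ("2", 242_951_149), ("3", 199_501_827),
    ("4", 191_273_063), ("5", 180_857_866), ("6", 170_899_992),
    ("7", 158_821_424), ("8", 146_274_826), ("9", 140_273_252),
    ("10", 135_374_737), ("11", 134_452_384), ("12", 132_349_534),
    ("13", 114_142_980), ("14", 106_368_585), ("15", 100_338_915),
    ("16", 88_827_254), ("17", 78_774_742), ("18", 76_117_153),
    ("19", 63_811_651), ("20", 62_435_964), ("21", 46_944_323),
    ("22", 49_691_432), ("X", 154_913_754), ("Y", 57_772_954),
)


@dataclass(frozen=True)
class FixtureManifest:
    """What a fixture wrote: per-source counts per window, and landmarks."""

    name: str
    seed: int
    #: source name -> {window string -> feature count}
    counts: Mapping[str, Mapping[str, int]]
    #: landmark label -> (chrom, start, end)
    landmarks: Mapping[str, tuple[str, int, int]]

    def to_tsv(self) -> str:
        lines = [f"meta\tname\t{self.name}", f"meta\tseed\t{self.seed}"]
        for source in sorted(self.counts):
            for window in sorted(self.counts[source]):
                lines.append(f"count\t{source}\t{window}\t{self.counts[source][window]}")
        for label in sorted(self.landmarks):
            chrom, start, end = self.landmarks[label]
            lines.append(f"landmark\t{label}\t{chrom}\t{start}\t{end}")
        return "\n".join(lines) + "\n"


def _synthetic_cytobands(chrom: str, length: int) -> list[Cytoband]:
    # 8 bands: 3 p bands, an acen pair, 3 q bands; centromere at 45% of
    # length except acrocentric chr15, placed at 17% so the first q band
    # (q11) contains the 20-24 Mb region of the worked example
    cen_frac = 0.17 if chrom == "15" else 0.45
    cen_mid = int(length * cen_frac)
    acen_w = max(1, int(length * 0.02))
    bands: list[Cytoband] = []
    p_end = cen_mid - acen_w
    p_bounds = [(p_end * i) // 3 for i in range(4)]
    for i, name in enumerate(("p13", "p12", "p11")):
        stain = "gneg" if i % 2 == 0 else "gpos50"
        bands.append(Cytoband(chrom, p_bounds[i] + 1, p_bounds[i + 1], name, stain))
    bands.append(Cytoband(chrom, p_end + 1, cen_mid, "p10", "acen"))
    bands.append(Cytoband(chrom, cen_mid + 1, cen_mid + acen_w, "q10", "acen"))
    q_start = cen_mid + acen_w + 1
    q_span = length - q_start + 1
    q_bounds = [q_start - 1 + (q_span * i) // 3 for i in range(4)]
    for i, name in enumerate(("q11", "q12", "q13")):
        stain = "gpos50" if i % 2 == 0 else "gneg"
        bands.append(Cytoband(chrom, q_bounds[i] + 1, q_bounds[i + 1], name, stain))
    return bands


def synthetic_assembly() -> Assembly:
    """The fixture assembly: NCBI36 chromosome lengths, synthetic banding."""
    chroms = tuple(ChromosomeInfo(n, l) for n, l in _NCBI36_LENGTHS)
    bands = tuple(
        b for n, l in _NCBI36_LENGTHS for b in _synthetic_cytobands(n, l)
    )
    return Assembly("NCBI36", chroms, bands)


def _cytoband_tsv(assembly: Assembly) -> str:
    lines = ["chrom\tstart\tend\tband\tstain"]
    for b in assembly.cytobands:
        lines.append(f"{b.chrom}\t{b.start}\t{b.end}\t{b.band_name}\t{b.stain}")
    return "\n".join(lines) + "\n"


def _write_source(
    outdir: Path, name: str, segment: RegionQuery, features: Sequence[GenomicFeature]
) -> None:
    d = outdir / name
    d.mkdir(parents=True, exist_ok=True)
    sf = SegmentFeatures(
        segment=segment,
        features=tuple(sorted(features, key=lambda f: (f.start, f.end, f.feature_id))),
        source=name,
    )
    fname = f"features.segment={segment.chrom}_{segment.start}_{segment.end}.xml"
    (d / fname).write_text(write_features_doc([sf]), "utf-8")


def _write_common(outdir: Path, manifest: FixtureManifest) -> None:
    asm = synthetic_assembly()
    (outdir / "cytobands.tsv").write_text(_cytoband_tsv(asm), "utf-8")
    (outdir / "entry_points.xml").write_text(
        write_entry_points_doc(asm.chromosomes), "utf-8"
    )
    (outdir / "manifest.tsv").write_text(manifest.to_tsv(), "utf-8")


# ---------------------------------------------------------------------------
# family case


def _family_snp_positions() -> tuple[list[int], list[int]]:
    """Positions of the son's chip (6 sites) and the newer chip (12 sites).

    The newer chip is a superset: every son site plus one interleaved
    filler between each, doubling the density in the +-100 kb window.
    """
    w = FAMILY_WINDOW
    son_offsets = [0, 36_000, 72_000, 100_000, 144_000, 180_000]
    extra_offsets = [18_000, 54_000, 90_000, 126_000, 162_000, 198_000]
    son = [w.start + o for o in son_offsets]
    newer = sorted(son + [w.start + o for o in extra_offsets])
    assert RS10993994_POS in son
    return son, newer


def _family_profiles(seed: int) -> dict[str, PersonProfile]:
    rng = random.Random(seed)
    son_pos, newer_pos = _family_snp_positions()
    rsid_of = {
        pos: ("rs10993994" if pos == RS10993994_POS else f"rs{7000000 + i}")
        for i, pos in enumerate(newer_pos)
    }
    # filler genotypes: biallelic A/G sites with random diploid calls
    filler_calls = {
        pos: {
            member: "".join(sorted(rng.choice("AG") for _ in range(2)))
            for member in FAMILY_GENOTYPES
        }
        for pos in newer_pos
        if pos != RS10993994_POS
    }
    profiles = {}
    relations = {"son": "self", "mother": "mother", "father": "father",
                 "sister": "sibling", "aunt": "other"}
    for member, landmark_call in FAMILY_GENOTYPES.items():
        positions = son_pos if member == "son" else newer_pos
        calls = {}
        for pos in positions:
            rsid = rsid_of[pos]
            call = landmark_call if pos == RS10993994_POS else filler_calls[pos][member]
            calls[rsid] = Genotype(rsid, "10", pos, call)
        profiles[member] = PersonProfile(member, relations[member], calls)
    return profiles


def make_family_case(outdir: str | Path, seed: int = 20111026) -> FixtureManifest:
    """Write the family-case fixture into ``outdir``.

    Emits five genotype sources on chromosome 10 (son TT, mother CT,
    father CT, sister CT, aunt CC at rs10993994), a gene source with
    MSMB starting 57 bp after the SNP, a cancer-mutation source with
    four mutations inside MSMB, and two CNV sources jointly holding
    four variable regions overlapping the +-100 kb window.  Also writes
    raw genotype text files, the cytoband table, entry points and a
    manifest.  Output is byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    canned = RegionQuery("10", 51_000_000, 51_500_000)
    w = FAMILY_WINDOW

    profiles = _family_profiles(seed)
    counts: dict[str, dict[str, int]] = {}
    for member, profile in profiles.items():
        feats = [
            GenomicFeature(
                g.rsid, g.rsid, "10", g.pos, g.pos, g.call, "genotype", "genotyping"
            )
            for g in profile.calls.values()
        ]
        _write_source(outdir, member, canned, feats)
        (outdir / "raw").mkdir(exist_ok=True)
        (outdir / "raw" / f"{member}.txt").write_text(
            format_raw_genotypes(profile), "utf-8"
        )
        counts[member] = {str(w): sum(1 for f in feats if w.start <= f.start <= w.end)}

    # gene track: MSMB plus two invented neighbours
    genes = [
        GenomicFeature("MSMB", "MSMB", "10", MSMB_START, MSMB_END, "gene",
                       "gene", "HGNC"),
        GenomicFeature("TIMM23", "TIMM23", "10", 51_289_000, 51_322_000, "gene",
                       "gene", "HGNC"),
        GenomicFeature("NCOA4", "NCOA4", "10", 51_245_000, 51_270_000, "gene",
                       "gene", "HGNC"),
    ]
    _write_source(outdir, "genes", canned, genes)
    counts["genes"] = {str(w): 3}

    # four somatic mutations, all within the MSMB interval
    muts = []
    for i in range(4):
        pos = MSMB_START + 500 + i * 2_500
        muts.append(
            GenomicFeature(
                f"COSM{9100 + i}", "MSMB:ENST00000358559", "10", pos, pos,
                "substitution", "somatic mutation", "COSMIC",
            )
        )
    _write_source(outdir, "cancer_mutations", canned, muts)
    counts["cancer_mutations"] = {str(w): 4}

    # two variable-region tracks, jointly four CNVs overlapping the window
    cnv_a = [
        GenomicFeature("Variation_0300", "Variation 0300", "10",
                       51_150_000, 51_240_000, "copy number variation", "CNV", "DGV"),
        GenomicFeature("Variation_0301", "Variation 0301", "10",
                       51_200_000, 51_310_000, "copy number variation", "CNV", "DGV"),
    ]
    cnv_b = [
        GenomicFeature("cnp_0870", "cnp 0870", "10",
                       51_100_000, 51_190_000, "copy number variation", "CNV", "Redon"),
        GenomicFeature("cnp_0871", "cnp 0871", "10",
                       51_280_000, 51_400_000, "copy number variation", "CNV", "Redon"),
    ]
    _write_source(outdir, "variable_regions_1", canned, cnv_a)
    _write_source(outdir, "variable_regions_2", canned, cnv_b)
    counts["variable_regions_1"] = {str(w): 2}
    counts["variable_regions_2"] = {str(w): 2}

    manifest = FixtureManifest(
        name="family-case",
        seed=seed,
        counts=counts,
        landmarks={
            "rs10993994": ("10", RS10993994_POS, RS10993994_POS),
            "MSMB": ("10", MSMB_START, MSMB_END),
        },
    )
    _write_common(outdir, manifest)
    return manifest


def family_track_sources(outdir: str | Path) -> list[TrackSource]:
    """Track roster for a family-case fixture directory."""
    outdir = Path(outdir)
    palette = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
               "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22"]
    names = [
        ("son", "son genotypes", "mark"),
        ("mother", "mother genotypes", "mark"),
        ("father", "father genotypes", "mark"),
        ("sister", "sister genotypes", "mark"),
        ("aunt", "aunt genotypes", "mark"),
        ("genes", "gene names", "track"),
        ("cancer_mutations", "cancer mutations", "track"),
        ("variable_regions_1", "variable regions", "track"),
        ("variable_regions_2", "variable regions (clones)", "track"),
    ]
    return [
        TrackSource(n, disp, str(outdir / n), device=dev,
                    views=("zoom",), color=palette[i % len(palette)])
        for i, (n, disp, dev) in enumerate(names)
    ]


# ---------------------------------------------------------------------------
# region case


def make_region_case(outdir: str | Path, seed: int = 15_011) -> FixtureManifest:
    """Write the region-case fixture (chromosome 15, 20-24 Mb) into ``outdir``.

    The gene source holds 45 genes inside the window (plus three
    outside, exercising intersection filtering); the disease-gene
    source lists 15 of the 45, among them UBE3A; the variable-region
    source holds the 400,000-bp deletion "Variation 7051" overlapping
    UBE3A.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    w = REGION_CASE_WINDOW
    canned = RegionQuery("15", 18_000_000, 26_000_000)

    genes: list[GenomicFeature] = [
        GenomicFeature("UBE3A", "UBE3A", "15", UBE3A_START, UBE3A_END, "gene",
                       "gene", "HGNC")
    ]
    # 44 more inside the window, non-landmark positions invented
    span = w.end - w.start
    for i in range(44):
        start = w.start + 1_000 + (span - 300_000) * i // 44 + rng.randrange(0, 20_000)
        length = rng.randrange(5_000, 120_000)
        end = min(start + length, w.end)
        sym = f"C15ORF{i + 10}"
        genes.append(
            GenomicFeature(sym, sym, "15", start, end, "gene", "gene", "HGNC")
        )
    # three genes outside the query window, inside the canned segment
    for i, start in enumerate((18_200_000, 19_100_000, 24_800_000)):
        sym = f"C15ORF{90 + i}"
        genes.append(
            GenomicFeature(sym, sym, "15", start, start + 40_000, "gene",
                           "gene", "HGNC")
        )
    _write_source(outdir, "genes", canned, genes)

    disease_symbols = ["UBE3A"] + sorted(
        rng.sample([g.feature_id for g in genes[1:45]], 14)
    )
    by_id = {g.feature_id: g for g in genes}
    disease = [
        GenomicFeature(s, by_id[s].label, "15", by_id[s].start, by_id[s].end,
                       "disease gene", "gene", "OMIM")
        for s in disease_symbols
    ]
    _write_source(outdir, "disease_genes", canned, disease)

    cnvs = [
        GenomicFeature(
            "Variation_7051", "Variation 7051", "15",
            VARIATION_7051_START, VARIATION_7051_START + VARIATION_7051_LEN - 1,
            "deletion", "CNV", "DGV",
            notes=("0.4 Mb deletion, Agilent 185k CGH array",),
        ),
        GenomicFeature("Variation_7122", "Variation 7122", "15",
                       20_400_000, 20_650_000, "copy number variation", "CNV", "DGV"),
        GenomicFeature("Variation_7140", "Variation 7140", "15",
                       21_900_000, 22_050_000, "copy number variation", "CNV", "DGV"),
    ]
    _write_source(outdir, "variable_regions", canned, cnvs)

    manifest = FixtureManifest(
        name="region-case",
        seed=seed,
        counts={
            "genes": {str(w): 45},
            "disease_genes": {str(w): 15},
            "variable_regions": {str(w): 3},
        },
        landmarks={
            "UBE3A": ("15", UBE3A_START, UBE3A_END),
            "Variation 7051": (
                "15", VARIATION_7051_START,
                VARIATION_7051_START + VARIATION_7051_LEN - 1,
            ),
        },
    )
    _write_common(outdir, manifest)
    return manifest


def region_track_sources(outdir: str | Path) -> list[TrackSource]:
    """Track roster for a region-case fixture directory."""
    outdir = Path(outdir)
    return [
        TrackSource("genes", "gene names", str(outdir / "genes"),
                    device="track", views=("zoom",), color="#1f77b4"),
        TrackSource("disease_genes", "genes involved in disease",
                    str(outdir / "disease_genes"),
                    device="track", views=("zoom",), color="#d62728"),
        TrackSource("variable_regions", "variable regions",
                    str(outdir / "variable_regions"),
                    device="track", views=("zoom",), color="#2ca02c"),
    ]


# ---------------------------------------------------------------------------
# randomized stress inputs


def make_random_tracks(
    n_features: int,
    chrom_lengths: Mapping[str, int],
    seed: int,
    outdir: str | Path | None = None,
    source_name: str = "random",
) -> tuple[FixtureManifest, list[SegmentFeatures]]:
    """Generate ``n_features`` uniformly placed features with log-uniform
    lengths in [1, 10^6], reproducibly for a fixed seed.

    Returns the manifest and the in-memory segments; if ``outdir`` is
    given the segments are also written as a file-mode source.
    """
    if n_features < 0:
        raise ValueError("n_features must be >= 0")
    rng = random.Random(seed)
    chroms = sorted(chrom_lengths)
    per_chrom: dict[str, list[GenomicFeature]] = {c: [] for c in chroms}
    for i in range(n_features):
        chrom = chroms[rng.randrange(len(chroms))]
        clen = chrom_lengths[chrom]
        length = min(int(10 ** rng.uniform(0, 6)), clen)
        start = rng.randint(1, max(1, clen - length + 1))
        per_chrom[chrom].append(
            GenomicFeature(
                f"rf{i:06d}", f"rf{i:06d}", chrom, start, start + length - 1,
                "random", "synthetic", "simulated",
                score=round(rng.uniform(0, 100), 2),
            )
        )
    segments = []
    counts: dict[str, dict[str, int]] = {source_name: {}}
    for chrom in chroms:
        seg = RegionQuery(chrom, 1, chrom_lengths[chrom])
        feats = tuple(
            sorted(per_chrom[chrom], key=lambda f: (f.start, f.end, f.feature_id))
        )
        segments.append(SegmentFeatures(seg, feats, source=source_name))
        counts[source_name][str(seg)] = len(feats)
    manifest = FixtureManifest(
        name=f"random-{n_features}", seed=seed, counts=counts, landmarks={}
    )
    if outdir is not None:
        outdir = Path(outdir)
        for sf in segments:
            _write_source(outdir, source_name, sf.segment, list(sf.features))
        (outdir / "manifest.tsv").write_text(manifest.to_tsv(), "utf-8")
    return manifest, segments


def make_raw_genotype_file(profile: PersonProfile, path: str | Path) -> Path:
    """Write a profile as a 23andMe-style raw text file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(format_raw_genotypes(profile), "utf-8")
    return path
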