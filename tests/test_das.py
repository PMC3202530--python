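"""DAS XML reading/writing, segment fetching and raw export."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyodas.core import GenomicFeature, RegionQuery, TrackSource
from karyodas.das import (
    DasParseError,
    SegmentFeatures,
    SourceUnavailableError,
    WindowTooLargeError,
    export_raw_text,
    fetch_features,
    parse_entry_points,
    parse_features_doc,
    write_entry_points_doc,
    write_features_doc,
)
from karyodas.fixtures import synthetic_assembly

from conftest import segment_features


def test_empty_segment_parses_to_empty_feature_list():
    doc = write_features_doc(
        [SegmentFeatures(RegionQuery("3", 1, 1000), ())]
    )
    parsed = parse_features_doc(doc)
    assert len(parsed) == 1 and parsed[0].features == ()


def test_genotype_type_id_survives_round_trip():
    f = GenomicFeature("rs10993994", "rs10993994", "10", 51219502, 51219502,
                       "TT", "genotype", "genotyping")
    sf = SegmentFeatures(RegionQuery("10", 1, 51219502), (f,))
    [back] = parse_features_doc(write_features_doc([sf]))
    assert back.features[0].type_id == "TT"


@given(st.lists(segment_features(), max_size=3))
@settings(max_examples=150)
def test_write_parse_round_trip_identity(segments):
    assert parse_features_doc(write_features_doc(segments)) == segments


def test_writer_output_is_byte_stable():
    sf = SegmentFeatures(
        RegionQuery("10", 1, 100),
        (GenomicFeature("a", "a & <b>", "10", 5, 10, "t", notes=('say "hi"',)),),
    )
    assert write_features_doc([sf]) == write_features_doc([sf])


def test_notes_preserve_order():
    f = GenomicFeature("f", "f", "1", 1, 2, "t", notes=("first", "second"))
    sf = SegmentFeatures(RegionQuery("1", 1, 2), (f,))
    [back] = parse_features_doc(write_features_doc([sf]))
    assert back.features[0].notes == ("first", "second")


def test_malformed_xml_raises_parse_error_naming_line():
    with pytest.raises(DasParseError) as err:
        parse_features_doc("<DASGFF><GFF><SEGMENT id='1'")
    assert "line" in str(err.value)


def test_start_after_end_record_dropped_but_document_parses(caplog):
    doc = """<?xml version="1.0"?>
<DASGFF><GFF version="1.0">
<SEGMENT id="1" start="1" stop="100" version="1.0">
<FEATURE id="bad"><TYPE id="t"/><START>50</START><END>10</END></FEATURE>
<FEATURE id="good"><TYPE id="t"/><START>10</START><END>20</END></FEATURE>
</SEGMENT></GFF></DASGFF>"""
    [sf] = parse_features_doc(doc)
    assert [f.feature_id for f in sf.features] == ["good"]


def test_lenient_reader_ignores_unknown_children_and_extra_attrs():
    doc = """<?xml version="1.0"?>
<DASGFF><GFF version="1.0" href="http://x">
<SEGMENT id="chr7" start="1" stop="100" version="1.0" label="seven">
<FEATURE id="f1" label="F1">
<TYPE id="exon" category="structural" reference="no">exon</TYPE>
<METHOD id="curated">curated</METHOD>
<START>10</START><END>20</END>
<FANCY_NEW_ELEMENT>ignored</FANCY_NEW_ELEMENT>
</FEATURE></SEGMENT></GFF></DASGFF>"""
    [sf] = parse_features_doc(doc)
    assert sf.segment.chrom == "7"  # chr prefix stripped
    f = sf.features[0]
    assert (f.type_id, f.type_label, f.method) == ("exon", "exon", "curated")


def test_entry_points_round_trip_and_order():
    chroms = synthetic_assembly().chromosomes
    parsed = parse_entry_points(write_entry_points_doc(chroms))
    assert parsed == list(chroms)
    assert parsed[9].name == "10" and parsed[9].length == 135374737


def test_entry_points_missing_stop_skipped():
    doc = """<?xml version="1.0"?>
<DASEP><ENTRY_POINTS>
<SEGMENT id="1" start="1" stop="500"/>
<SEGMENT id="2" start="1"/>
</ENTRY_POINTS></DASEP>"""
    parsed = parse_entry_points(doc)
    assert [c.name for c in parsed] == ["1"]


def test_empty_entry_points():
    assert parse_entry_points('<?xml version="1.0"?><DASEP/>') == []


# ---------------------------------------------------------------------------
# fetching


def _file_source(tmp_path, features, chrom="5", seg=(1, 10_000)):
    d = tmp_path / "src"
    d.mkdir(exist_ok=True)
    sf = SegmentFeatures(RegionQuery(chrom, *seg), tuple(features))
    (d / f"features.segment={chrom}_{seg[0]}_{seg[1]}.xml").write_text(
        write_features_doc([sf]), "utf-8"
    )
    return TrackSource("src", "src", str(d))


def test_fetch_filters_to_intersecting_features(tmp_path):
    rng = random.Random(7)
    feats = []
    for i in range(200):
        start = rng.randint(1, 9_000)
        feats.append(
            GenomicFeature(f"f{i}", f"f{i}", "5", start,
                           start + rng.randint(0, 500), "t")
        )
    src = _file_source(tmp_path, feats)
    region = RegionQuery("5", 2_000, 4_000)
    got = fetch_features(src, region)
    expected = {f.feature_id for f in feats
                if max(f.start, region.start) <= min(f.end, region.end)}
    assert {f.feature_id for f in got.features} == expected


def test_fetch_absent_chromosome_yields_empty_not_error(tmp_path):
    src = _file_source(tmp_path, [])
    got = fetch_features(src, RegionQuery("21", 1, 100))
    assert got.features == ()


def test_unreachable_host_raises_source_unavailable():
    src = TrackSource("x", "x", "http://127.0.0.1:1/das/x")
    with pytest.raises(SourceUnavailableError) as err:
        fetch_features(src, RegionQuery("1", 1, 100), retries=0, timeout=0.2)
    assert "127.0.0.1" in str(err.value)


def test_oversized_window_rejected(tmp_path):
    src = _file_source(tmp_path, [])
    with pytest.raises(WindowTooLargeError):
        fetch_features(src, RegionQuery("5", 1, 60_000_000))


# ---------------------------------------------------------------------------
# raw export


def test_export_empty_segment_is_header_only():
    out = export_raw_text(SegmentFeatures(RegionQuery("1", 1, 10), ()))
    assert out.count("\n") == 1 and out.startswith("feature_id\t")


def test_export_rows_sorted_by_coordinates():
    feats = [
        GenomicFeature("c", "c", "1", 30, 40, "t"),
        GenomicFeature("a", "a", "1", 10, 20, "t"),
        GenomicFeature("b", "b", "1", 10, 15, "t"),
    ]
    out = export_raw_text(SegmentFeatures(RegionQuery("1", 1, 100), tuple(feats)))
    lines = out.strip().split("\n")
    assert len(lines) == 4
    ids = [line.split("\t")[0] for line in lines[1:]]
    assert ids == sorted(
        (f.feature_id for f in feats),
        key=lambda i: next((f.start, f.end, f.feature_id)
                           for f in feats if f.feature_id == i),
    )
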