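"""Layout packing, coordinate mapping and the three SVG views."""

import random
import xml.etree.ElementTree as ET

import pytest
from hypothesis import given
from hypothesis import strategies as st

from karyodas.core import GenomicFeature, RegionQuery, TrackSource, regions_intersect
from karyodas.das import fetch_features
from karyodas.fixtures import (
    FAMILY_WINDOW,
    family_track_sources,
    make_random_tracks,
    synthetic_assembly,
)
from karyodas.render import (
    feature_popup_info,
    genome_to_pixel,
    pack_features,
    pixel_to_genome,
    render_chromosome,
    render_karyotype,
    render_zoom,
)


def _feat(i, start, end, chrom="1"):
    return GenomicFeature(f"f{i}", f"f{i}", chrom, start, end, "t")


# ---------------------------------------------------------------------------
# coordinate mapping


def test_pixel_map_endpoints_and_midpoint():
    w = RegionQuery("1", 1, 101)
    assert genome_to_pixel(1, w, 100) == 0
    assert genome_to_pixel(101, w, 100) == 100
    assert genome_to_pixel(51, w, 100) == 50


def test_pixel_map_rejects_out_of_window_positions():
    with pytest.raises(ValueError):
        genome_to_pixel(102, RegionQuery("1", 1, 101), 100)


@given(st.integers(min_value=1, max_value=1_000_000))
def test_pixel_map_inverts_within_one_base(pos):
    w = RegionQuery("1", 1, 1_000_000)
    x = genome_to_pixel(pos, w, 1200)
    assert abs(pixel_to_genome(x, w, 1200) - pos) <= 1


# ---------------------------------------------------------------------------
# packing


def test_mutually_overlapping_features_need_distinct_rows():
    feats = [_feat(0, 10, 100), _feat(1, 20, 110), _feat(2, 30, 120)]
    rows = pack_features(feats, 1.0, float)
    assert len(rows) == 3


def test_disjoint_features_share_one_row():
    feats = [_feat(0, 10, 20), _feat(1, 40, 50), _feat(2, 80, 90)]
    rows = pack_features(feats, 1.0, float)
    assert len(rows) == 1 and len(rows[0].placed) == 3


def test_packing_on_random_inputs_is_admissible_and_count_conserving():
    rng = random.Random(99)
    feats = []
    for i in range(500):
        start = rng.randint(1, 100_000)
        feats.append(_feat(i, start, start + rng.randint(0, 2_000)))
    min_gap = 2.0
    scale = lambda pos: pos / 100.0
    rows = pack_features(feats, min_gap, scale)
    placed = [f for row in rows for f, _, _ in row.placed]
    assert sorted(f.feature_id for f in placed) == \
        sorted(f.feature_id for f in feats)
    for row in rows:  # brute-force pairwise check within each row
        for (fa, a0, a1) in row.placed:
            for (fb, b0, b1) in row.placed:
                if fa.feature_id != fb.feature_id:
                    assert a1 + min_gap <= b0 or b1 + min_gap <= a0


# ---------------------------------------------------------------------------
# karyotype and chromosome views


def test_karyotype_draws_all_chromosomes_with_click_ids(assembly):
    scene = render_karyotype(assembly)
    ids = {e.element_id for e in scene.elements}
    assert ids == {f"chr-{c.name}" for c in assembly.chromosomes}
    root = ET.fromstring(scene.svg)  # SVG well-formedness oracle
    assert root.tag.endswith("svg")


def test_karyotype_requires_chromosomes():
    from karyodas.core import Assembly

    with pytest.raises(ValueError):
        render_karyotype(Assembly("NCBI36", (), ()))


def test_chromosome_view_band_ids_and_tiling(assembly):
    scene = render_chromosome(assembly, "15")
    assert 'id="band-15-q11"' in scene.svg
    band_elems = sorted(
        (e for e in scene.elements if e.element_id.startswith("band-")),
        key=lambda e: e.start,
    )
    info = assembly.chromosome("15")
    assert band_elems[0].start == 1 and band_elems[-1].end == info.length
    for prev, nxt in zip(band_elems, band_elems[1:]):
        assert nxt.start == prev.end + 1


def test_chromosome_view_full_length_slider(assembly):
    info = assembly.chromosome("10")
    scene = render_chromosome(
        assembly, "10", RegionQuery("10", 1, info.length)
    )
    slider = next(e for e in scene.elements if e.element_id == "slider-window")
    assert (slider.start, slider.end) == (1, info.length)


def test_chromosome_view_unknown_chromosome_errors(assembly):
    with pytest.raises(KeyError):
        render_chromosome(assembly, "99")


# ---------------------------------------------------------------------------
# zoom view


def _random_tracks_with_features(n_tracks, n_feats, seed, window):
    rng = random.Random(seed)
    out = []
    devices = ["mark", "track", "line", "chart"]
    for t in range(n_tracks):
        feats = []
        for i in range(n_feats):
            start = rng.randint(1, window.end + 50_000)
            feats.append(
                _feat(f"{t}_{i}", start, start + rng.randint(0, 30_000),
                      chrom=window.chrom)
            )
        out.append(
            (TrackSource(f"t{t}", f"track {t}", "/dev/null",
                         device=devices[t % 4]), feats)
        )
    return out


def test_zoom_requires_at_least_one_track():
    with pytest.raises(ValueError, match="at least one source"):
        render_zoom(RegionQuery("1", 1, 100), [])


def test_zoom_legend_counts_match_linear_scan():
    window = RegionQuery("7", 100_000, 300_000)
    tracks = _random_tracks_with_features(4, 120, seed=5, window=window)
    scene = render_zoom(window, tracks)
    for (track, feats), entry in zip(tracks, scene.legend):
        expected = sum(
            1 for f in feats if regions_intersect(f.region, window)
        )
        assert entry.count == expected
        assert entry.text == f"{track.display_name} ({expected})"
        assert f"{track.display_name} ({expected})" in scene.svg


def test_zoom_zero_feature_track_draws_empty_lane():
    scene = render_zoom(
        RegionQuery("1", 1, 1000),
        [(TrackSource("t", "empty track", "/dev/null"), [])],
    )
    assert scene.legend[0].text == "empty track (0)"


def test_zoom_clipped_features_still_drawn_and_counted():
    window = RegionQuery("1", 100, 200)
    straddler = _feat("x", 50, 150)
    scene = render_zoom(
        window, [(TrackSource("t", "t", "/dev/null", device="track"),
                  [straddler])]
    )
    assert scene.legend[0].count == 1
    elem = next(e for e in scene.elements if e.element_id == "feat-t-fx")
    assert elem.start == 100 and elem.end == 150  # clamped into the window


def test_zoom_feature_ids_and_popup_metadata_embedded(family_dir):
    tracks = family_track_sources(family_dir)
    fetched = [(t, fetch_features(t, FAMILY_WINDOW).features) for t in tracks]
    scene = render_zoom(FAMILY_WINDOW, fetched)
    assert 'id="feat-son-rs10993994"' in scene.svg
    assert 'data-type-id="TT"' in scene.svg
    legend = {e.display_name: e.count for e in scene.legend}
    assert legend["cancer mutations"] == 4
    ET.fromstring(scene.svg)


def test_zoom_determinism_byte_identical():
    window = RegionQuery("2", 1, 500_000)
    tracks = _random_tracks_with_features(3, 60, seed=11, window=window)
    assert render_zoom(window, tracks).svg == render_zoom(window, tracks).svg


def test_zoom_handles_several_thousand_features():
    lengths = {"1": 200_000_000}
    _, segs = make_random_tracks(5_000, lengths, seed=3)
    window = RegionQuery("1", 1, 50_000_000)
    track = TrackSource("big", "big", "/dev/null", device="track")
    scene = render_zoom(window, [(track, segs[0].features)])
    assert scene.legend[0].count > 0
    ET.fromstring(scene.svg)


def test_chart_device_renders_histogram():
    window = RegionQuery("3", 1, 100_000)
    feats = [_feat(i, 1 + i * 200, 1 + i * 200, chrom="3") for i in range(300)]
    scene = render_zoom(
        window, [(TrackSource("d", "density", "/dev/null", device="chart"),
                  feats)]
    )
    assert scene.legend[0].count == 300
    ET.fromstring(scene.svg)


# ---------------------------------------------------------------------------
# popups


def test_popup_fields_in_order_with_ensembl_link():
    f = GenomicFeature(
        "rs10993994", "rs10993994", "10", 51219502, 51219502, "TT",
        "genotype", "genotyping", notes=("risk allele T",),
        links=(("http://x/1", "source"),),
    )
    info = feature_popup_info(f)
    assert list(info)[:5] == ["Label", "Id", "Type Id", "Method", "Position"]
    assert info["Type Id"] == "TT"
    assert info["Position"] == "10:51219502-51219502"
    assert "Score" not in info
    assert info["Display Annotations in Ensembl"].endswith(
        "r=10:51219502-51219502"
    )


def test_popup_includes_score_when_present():
    f = GenomicFeature("f", "f", "1", 1, 2, "t", score=12.5)
    assert feature_popup_info(f)["Score"] == "12.5"
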