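"""Shared fixtures and hypothesis strategies for the test suite.

Fixture data is generated programmatically into session-scoped temp
directories; no test touches the network.
"""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from karyodas.core import GenomicFeature, RegionQuery
from karyodas.das import SegmentFeatures
from karyodas.fixtures import (
    make_family_case,
    make_region_case,
    synthetic_assembly,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def family_dir(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("family_case")
    make_family_case(d)
    return d


@pytest.fixture(scope="session")
def region_dir(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("region_case")
    make_region_case(d)
    return d


@pytest.fixture(scope="session")
def assembly():
    return synthetic_assembly()


# ---------------------------------------------------------------------------
# strategies

# XML attribute values are whitespace-normalized by conforming parsers,
# so round-trippable identifiers avoid tabs/newlines and edge whitespace
_ident = st.from_regex(r"[A-Za-z0-9_.:-]{1,12}", fullmatch=True)
_label = st.from_regex(
    r"[A-Za-z0-9_.()&<>'\"-](?:[ A-Za-z0-9_.()&<>'\"-]{0,18}[A-Za-z0-9_.()&<>'\"-])?",
    fullmatch=True,
)
_chrom = st.sampled_from([str(i) for i in range(1, 23)] + ["X", "Y"])


@st.composite
def genomic_features(draw, chrom: str | None = None) -> GenomicFeature:
    start = draw(st.integers(min_value=1, max_value=200_000_000))
    length = draw(st.integers(min_value=1, max_value=1_000_000))
    return GenomicFeature(
        feature_id=draw(_ident),
        label=draw(_label),
        chrom=chrom if chrom is not None else draw(_chrom),
        start=start,
        end=start + length - 1,
        type_id=draw(_ident),
        type_label=draw(_label) if draw(st.booleans()) else "",
        method=draw(_label) if draw(st.booleans()) else "",
        score=draw(
            st.none()
            | st.floats(allow_nan=False, allow_infinity=False, width=32)
        ),
        strand=draw(st.sampled_from(["+", "-", "."])),
        notes=tuple(draw(st.lists(_label, max_size=3))),
        links=tuple(
            draw(st.lists(st.tuples(_ident.map(lambda s: f"http://x/{s}"), _label),
                          max_size=2))
        ),
    )


@st.composite
def segment_features(draw) -> SegmentFeatures:
    chrom = draw(_chrom)
    feats = draw(st.lists(genomic_features(chrom=chrom), max_size=8))
    hi = max((f.end for f in feats), default=1_000)
    return SegmentFeatures(
        segment=RegionQuery(chrom, 1, hi),
        features=tuple(feats),
    )


@st.composite
def small_regions(draw, max_pos: int = 1_000) -> RegionQuery:
    start = draw(st.integers(min_value=1, max_value=max_pos))
    end = draw(st.integers(min_value=start, max_value=max_pos))
    return RegionQuery(draw(st.sampled_from(["1", "10", "X"])), start, end)
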