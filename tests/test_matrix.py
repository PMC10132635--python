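"""Capture-matrix construction, site filters, and MARK .inp interchange."""

import datetime as dt
import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reefcmr import (
    CaptureMatrix, SightingRecord, StudyDesign, build_capture_matrix,
    filter_sites, read_inp, write_inp,
)
from reefcmr.matrix import EmptyMatrixError, drop_first_primary


def _sight(tid, y, m, d, site="A", species="green"):
    return SightingRecord(turtle_id=tid, species=species,
                          date=dt.date(y, m, d), site=site, atoll="X")


@pytest.fixture
def design():
    return StudyDesign.from_window("2016-05", "2017-04")  # 2 primaries x 6


def test_within_month_sightings_collapse_to_one(design):
    recs = [_sight("T1", 2016, 6, d) for d in (1, 10, 25)]
    m = build_capture_matrix(recs, design, "A", "green")
    assert m.data.sum() == 1
    june = [o.index for o in design.occasions if o.month == 6][0]
    assert m.data[0, june] == 1


def test_disjoint_months_two_rows(design):
    recs = [_sight("T1", 2016, 5, 2), _sight("T2", 2016, 8, 9)]
    m = build_capture_matrix(recs, design, "A", "green")
    assert m.data.shape == (2, 12)
    assert m.data.sum() == 2
    assert (m.data.sum(axis=1) == 1).all()


def test_rows_always_have_a_detection(design):
    recs = [_sight(f"T{i}", 2016, 5 + i % 6, 3) for i in range(10)]
    m = build_capture_matrix(recs, design, "A", "green")
    assert (m.data.sum(axis=1) >= 1).all()


def test_other_site_species_excluded(design):
    recs = [_sight("T1", 2016, 5, 2), _sight("T2", 2016, 5, 2, site="B"),
            _sight("T3", 2016, 5, 2, species="hawksbill")]
    m = build_capture_matrix(recs, design, "A", "green")
    assert m.individuals == ["T1"]


def test_empty_matrix_signal(design):
    with pytest.raises(EmptyMatrixError):
        build_capture_matrix([], design, "A", "green")


@given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 11),
                          st.integers(1, 28)), min_size=1, max_size=30))
def test_deduplication_idempotence(sightings):
    """Adding duplicate records never changes the matrix."""
    design = StudyDesign.from_window("2016-05", "2017-04")
    recs = []
    for tid, occ, day in sightings:
        o = design.occasions[occ]
        recs.append(_sight(f"T{tid}", o.year, o.month, day))
    m1 = build_capture_matrix(recs, design, "A", "green")
    m2 = build_capture_matrix(recs + recs, design, "A", "green")
    assert m1.individuals == m2.individuals
    assert (m1.data == m2.data).all()


def _matrix_with_n(n, design, site="A"):
    recs = [_sight(f"T{i:02d}", 2016, 5 + (i % 6), 1, site=site)
            for i in range(n)]
    return build_capture_matrix(recs, design, site, "green")


def test_filter_sites_threshold(design):
    m9 = _matrix_with_n(9, design, "A")
    m10 = _matrix_with_n(10, design, "B")
    kept, log = filter_sites([m9, m10], min_individuals=10)
    assert [m.site for m in kept] == ["B"]
    assert any("excluded" in line and "A" in line for line in log)


def test_filter_sites_identity_when_all_pass(design):
    ms = [_matrix_with_n(12, design, s) for s in "AB"]
    kept, log = filter_sites(ms, min_individuals=10)
    assert kept == ms and log == []


def test_filter_sites_monotone_in_threshold(design):
    ms = [_matrix_with_n(n, design, s) for s, n in zip("ABCD", (5, 9, 10, 20))]
    previous = None
    for thr in (1, 5, 9, 10, 15, 25):
        kept, _ = filter_sites(ms, min_individuals=thr)
        sites = {m.site for m in kept}
        if previous is not None:
            assert sites <= previous
        previous = sites


def test_omit_first_drops_primary_and_orphan_rows(design):
    # T1 only in primary 1; T2 in both
    recs = [_sight("T1", 2016, 5, 2), _sight("T2", 2016, 6, 2),
            _sight("T2", 2016, 12, 2)]
    m = build_capture_matrix(recs, design, "A", "green")
    out = drop_first_primary(m)
    assert out.individuals == ["T2"]
    assert out.design.n_primary == 1
    assert out.design.occasions[0].month == 11
    kept, log = filter_sites([m], min_individuals=1, omit_first=["A"])
    assert kept[0].individuals == ["T2"]
    assert any("first primary omitted" in line for line in log)


def test_inp_single_history():
    design = StudyDesign.regular("2016-05", 2, 2)
    m = CaptureMatrix(["T1"], np.array([[1, 0, 1, 0]]), design)
    buf = io.StringIO()
    write_inp(m, buf)
    assert buf.getvalue() == "1010 1;\n"


def test_inp_collapses_identical_histories():
    design = StudyDesign.regular("2016-05", 2, 2)
    m = CaptureMatrix(["T1", "T2"], np.array([[1, 1, 0, 0], [1, 1, 0, 0]]),
                      design)
    buf = io.StringIO()
    write_inp(m, buf)
    assert buf.getvalue() == "1100 2;\n"


@given(st.integers(1, 12), st.integers(0, 2 ** 30))
def test_inp_round_trip_lossless(n_ind, seed):
    """read(write(M)) reproduces histories and frequencies up to row order."""
    design = StudyDesign.regular("2016-05", 2, 3)
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 2, size=(n_ind, 6), dtype=np.int8)
    data[data.sum(axis=1) == 0, 0] = 1
    m = CaptureMatrix([f"T{i}" for i in range(n_ind)], data, design)
    buf = io.StringIO()
    write_inp(m, buf)
    back = read_inp(io.StringIO(buf.getvalue()), design)
    a = sorted(map(tuple, m.data.tolist()))
    b = sorted(map(tuple, back.data.tolist()))
    assert a == b


def test_csv_round_trip(full_design):
    rng = np.random.default_rng(0)
    data = rng.integers(0, 2, size=(5, full_design.n_occasions), dtype=np.int8)
    data[data.sum(axis=1) == 0, 0] = 1
    m = CaptureMatrix([f"T{i}" for i in range(5)], data, full_design,
                      site="A", species="green")
    buf = io.StringIO()
    m.to_csv(buf)
    back = CaptureMatrix.from_csv(io.StringIO(buf.getvalue()), site="A",
                                  species="green")
    assert back.individuals == m.individuals
    assert (back.data == m.data).all()
    assert back.design == m.design


def test_matrix_invariants_rejected():
    design = StudyDesign.regular("2016-05", 1, 2)
    with pytest.raises(ValueError):
        CaptureMatrix(["T1"], np.array([[0, 0]]), design)   # empty row
    with pytest.raises(ValueError):
        CaptureMatrix(["T1"], np.array([[2, 0]]), design)   # non-binary
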