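"""Window construction, padded overlap detection, summaries — checked against
an exhaustive day-set oracle and hand-traced boundary fixtures."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rxddi as rx
from rxddi.episodes import (MAX_GAP_DAYS, PAD_DAYS, build_windows_table,
                            find_overlaps_table, summarize_table)

D0 = dt.date(2000, 1, 1)


def day(offset: int) -> dt.date:
    return D0 + dt.timedelta(days=offset)


def ev(offset: int, drug="citalopram", pid="p1") -> rx.PrescriptionEvent:
    return rx.PrescriptionEvent(pid, drug, day(offset))


def win(start: int, end: int, drug="omeprazole", pid="p1", n=None) -> rx.PrescriptionWindow:
    if n is None:
        n = 1 if start == end else 2
    return rx.PrescriptionWindow(pid, drug, day(start), day(end), n)


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def test_single_event_gives_degenerate_window():
    (w,) = rx.build_windows([ev(0)])
    assert (w.start, w.end, w.n_prescriptions) == (day(0), day(0), 1)


def test_gap_rule_merges_then_splits():
    # 90-day gap merges; 110-day gap starts a new window
    w = rx.build_windows([ev(0), ev(90), ev(200)])
    assert [(x.start, x.end, x.n_prescriptions) for x in w] == [
        (day(0), day(90), 2), (day(200), day(200), 1)]


def test_gap_boundary_is_inclusive_at_98_days():
    assert len(rx.build_windows([ev(0), ev(98)])) == 1
    assert len(rx.build_windows([ev(0), ev(99)])) == 2


def test_same_day_duplicates_collapse():
    (w,) = rx.build_windows([ev(0), ev(0), ev(30), ev(30)])
    assert w.n_prescriptions == 2


def test_empty_input_gives_empty_output():
    assert rx.build_windows([]) == []


def test_mixed_participants_rejected():
    with pytest.raises(ValueError):
        rx.build_windows([ev(0, pid="p1"), ev(5, pid="p2")])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(0, 3000), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_window_invariants_on_random_event_sets(offsets, rnd):
    events = [ev(o) for o in offsets]
    rnd.shuffle(events)
    windows = rx.build_windows(events)
    # order/duplicate invariance
    assert windows == rx.build_windows(sorted(events, key=lambda e: e.date))
    # conservation: total prescriptions = distinct dates
    assert sum(w.n_prescriptions for w in windows) == len(set(offsets))
    # chaining: gaps within <= 98, gaps between > 98; idempotence per window
    dates = sorted(set(offsets))
    for a, b in zip(windows, windows[1:]):
        assert (b.start - a.end).days > MAX_GAP_DAYS
    for w in windows:
        inside = [d for d in dates if w.start <= day(d) <= w.end]
        assert w.n_prescriptions == len(inside)
        assert rx.build_windows([ev(d) for d in inside]) == [w]


# ---------------------------------------------------------------------------
# padded overlap
# ---------------------------------------------------------------------------

def test_overlap_inside_window():
    (inst,) = rx.find_overlaps([win(0, 100, "citalopram")], [win(50, 60)])
    assert inst.overlap_days == 39          # padded intersection [36, 74]
    assert not inst.single_prescription


def test_disjoint_windows_produce_no_instance():
    assert rx.find_overlaps([win(0, 10, "citalopram")], [win(40, 50)]) == []


def test_padded_touch_at_28_day_gap():
    (inst,) = rx.find_overlaps([win(0, 10, "citalopram")], [win(38, 50)])
    assert inst.overlap_days == 1
    assert rx.find_overlaps([win(0, 10, "citalopram")], [win(39, 50)]) == []


def test_negative_padding_rejected():
    with pytest.raises(ValueError):
        rx.find_overlaps([win(0, 10, "citalopram")], [win(5, 6)], pad_days=-1)


def _oracle_instances(cital, drugs, pad=PAD_DAYS):
    """Exhaustive day-set oracle: expand each padded window to its covered days
    and intersect."""
    out = []
    for c in cital:
        c_days = set(range((c.start - D0).days - pad, (c.end - D0).days + pad + 1))
        for d in drugs:
            d_days = set(range((d.start - D0).days - pad, (d.end - D0).days + pad + 1))
            inter = c_days & d_days
            if inter:
                out.append((d.canonical_drug, (c.start, c.end), (d.start, d.end),
                            len(inter)))
    return sorted(out)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(0, 3000), min_size=1, max_size=25),
       st.lists(st.integers(0, 3000), min_size=1, max_size=25))
def test_find_overlaps_matches_day_set_oracle(cital_offsets, drug_offsets):
    cital = rx.build_windows([ev(o) for o in cital_offsets])
    drugs = rx.build_windows([ev(o, "omeprazole") for o in drug_offsets])
    got = sorted((i.interacting_drug,
                  (i.citalopram_window.start, i.citalopram_window.end),
                  (i.drug_window.start, i.drug_window.end), i.overlap_days)
                 for i in rx.find_overlaps(cital, drugs))
    assert got == _oracle_instances(cital, drugs)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(0, 2000), min_size=1, max_size=15),
       st.lists(st.integers(0, 2000), min_size=1, max_size=15),
       st.integers(0, 30), st.integers(0, 30))
def test_more_padding_never_loses_instances(c_off, d_off, pad_a, pad_b):
    cital = rx.build_windows([ev(o) for o in c_off])
    drugs = rx.build_windows([ev(o, "omeprazole") for o in d_off])
    lo, hi = sorted((pad_a, pad_b))
    assert len(rx.find_overlaps(cital, drugs, hi)) >= len(rx.find_overlaps(cital, drugs, lo))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _inst(drug, overlap, single=False, pid="p1"):
    c = win(0, 100, "citalopram", pid)
    d = win(10, 10, drug, pid) if single else win(10, 40, drug, pid)
    return rx.CoPrescriptionInstance(pid, drug, c, d, overlap, single)


def test_summary_empty_participant():
    s = rx.summarize_participant([], participant_id="p0")
    assert (s.ddi_status, s.n_distinct_drugs, s.n_instances) == (False, 0, 0)
    assert s.longest_overlap_days is None and not s.durations_excluded


def test_summary_counts_distinct_drugs_and_instances():
    s = rx.summarize_participant(
        [_inst("omeprazole", 30), _inst("omeprazole", 50), _inst("diazepam", 20)])
    assert (s.n_distinct_drugs, s.n_instances, s.longest_overlap_days) == (2, 3, 50)
    assert not s.durations_excluded


def test_single_prescription_only_excluded_from_duration():
    s = rx.summarize_participant([_inst("omeprazole", 29, single=True)])
    assert s.ddi_status and s.longest_overlap_days is None and s.durations_excluded


# ---------------------------------------------------------------------------
# vectorised path agrees with the reference API
# ---------------------------------------------------------------------------

def test_table_path_matches_reference_on_synthetic_cohort(small_cohort, catalog):
    events = small_cohort.events.copy()
    events["date"] = pd.to_datetime(events["date"])
    annot = rx.annotate_names(events["drug_name"].unique(), catalog)
    mapped = (events.assign(canonical_drug=events["drug_name"].map(annot))
                    .explode("canonical_drug").dropna(subset=["canonical_drug"]))
    mapped = mapped[mapped["canonical_drug"].isin(
        catalog.interacting_names() | {"citalopram"})]
    table = build_windows_table(mapped)

    rng = np.random.default_rng(0)
    pids = rng.choice(mapped["participant_id"].unique(), 60, replace=False)
    for pid in pids:
        sub = mapped[mapped["participant_id"] == pid]
        ref_windows = []
        for drug in sorted(sub["canonical_drug"].unique()):
            evs = [rx.PrescriptionEvent(pid, drug, d.date())
                   for d in sub.loc[sub["canonical_drug"] == drug, "date"]]
            ref_windows.extend(rx.build_windows(evs))
        tab = table[table["participant_id"] == pid]
        got = sorted((r.canonical_drug, r.start.date(), r.end.date(), r.n_prescriptions)
                     for r in tab.itertuples())
        expected = sorted((w.canonical_drug, w.start, w.end, w.n_prescriptions)
                          for w in ref_windows)
        assert got == expected

        cital = [w for w in ref_windows if w.canonical_drug == "citalopram"]
        drugs = [w for w in ref_windows if w.canonical_drug != "citalopram"]
        ref_inst = rx.find_overlaps(cital, drugs)
        tab_inst = find_overlaps_table(
            tab[tab["canonical_drug"] == "citalopram"],
            tab[tab["canonical_drug"] != "citalopram"])
        assert sorted(tab_inst["overlap_days"]) == sorted(i.overlap_days for i in ref_inst)

        ref_sum = rx.summarize_participant(ref_inst, participant_id=pid)
        tab_sum = summarize_table(tab_inst, [pid]).iloc[0]
        assert bool(tab_sum.ddi_status) == ref_sum.ddi_status
        assert int(tab_sum.n_distinct_drugs) == ref_sum.n_distinct_drugs
        assert int(tab_sum.n_instances) == ref_sum.n_instances


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def test_participant_without_anchor_events_is_excluded(catalog):
    events = pd.DataFrame({
        "participant_id": ["a", "a", "b"],
        "drug_name": ["citalopram", "omeprazole", "omeprazole"],
        "date": ["2001-01-01", "2001-01-10", "2001-01-10"],
    })
    covs = pd.DataFrame({"participant_id": ["a", "b"]})
    cohort = rx.cohort_ddi_table(events, covs, catalog)
    assert list(cohort["participant_id"]) == ["a"]
    assert bool(cohort["ddi_status"].iloc[0])


def test_cohort_derives_citalopram_exposure_columns(small_build, small_cohort):
    cohort = small_build.cohort
    assert {"age_at_first_citalopram", "cital_longest_days",
            "n_citalopram_rx"} <= set(cohort.columns)
    assert (cohort["n_citalopram_rx"] >= 1).all()
    assert (cohort["cital_longest_days"] >= 1).all()
    assert len(cohort) == len(small_cohort.covariates)


def test_enlarging_catalogue_never_flips_status_off(small_cohort, catalog):
    full = rx.cohort_ddi_table(small_cohort.events, small_cohort.covariates, catalog)
    narrow = rx.cohort_ddi_table(small_cohort.events, small_cohort.covariates,
                                 catalog, mode="contraindicated_only")
    merged = narrow.merge(full, on="participant_id", suffixes=("_narrow", "_full"))
    assert not (merged["ddi_status_narrow"] & ~merged["ddi_status_full"]).any()
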