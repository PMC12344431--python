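"""Prescription windows, padded co-prescription overlap, per-participant summaries.

A *prescription window* is a maximal run of consecutive dispensings of one drug
for one participant in which successive dates are at most 14 weeks (98 days)
apart; a longer gap means the drug was probably suspended and starts a new
window.  A *co-prescription instance* is a pair (anchor-drug window,
interacting-drug window) whose intervals, padded symmetrically by ±2 weeks to
model the treatment span carried by each dispensing, intersect.  The outcome is
lifetime and binary: a participant is in the DDI group iff at least one
instance exists.

Two equivalent implementations are provided: a per-participant functional API
on small dataclasses (the readable reference), and vectorised pandas routines
(`build_windows_table`, `find_overlaps_table`) used for cohort-scale runs.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, annotate_names, filter_catalog

logger = logging.getLogger(__name__)

MAX_GAP_DAYS = 98          # "consecutive prescriptions ≤14 weeks apart" (inclusive)
PAD_DAYS = 14              # "±2 weeks" around each window, both sides


# ---------------------------------------------------------------------------
# Domain types (per-participant reference API)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrescriptionEvent:
    """One dispensing record."""
    participant_id: str
    canonical_drug: str
    date: dt.date


@dataclass(frozen=True)
class PrescriptionWindow:
    """Merged episode of consecutive prescriptions of one drug."""
    participant_id: str
    canonical_drug: str
    start: dt.date
    end: dt.date
    n_prescriptions: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start after end")
        if (self.n_prescriptions == 1) != (self.start == self.end):
            raise ValueError("single-prescription window must have start == end")

    @property
    def duration_days(self) -> int:
        """Inclusive span of the raw window in days."""
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class CoPrescriptionInstance:
    """An anchor window and an interacting-drug window whose padded intervals meet."""
    participant_id: str
    interacting_drug: str
    citalopram_window: PrescriptionWindow
    drug_window: PrescriptionWindow
    overlap_days: int
    single_prescription: bool


@dataclass(frozen=True)
class DdiSummary:
    """Lifetime DDI status and exposure intensity for one participant."""
    participant_id: str
    ddi_status: bool
    n_distinct_drugs: int
    n_instances: int
    longest_overlap_days: int | None
    durations_excluded: bool


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def build_windows(events: Sequence[PrescriptionEvent],
                  max_gap_days: int = MAX_GAP_DAYS) -> list[PrescriptionWindow]:
    """Chain one participant's dated events of one drug into prescription windows.

    Events are sorted and deduplicated by date (same-day repeat dispensings
    collapse), then chained greedily: a gap of more than ``max_gap_days``
    between consecutive dates starts a new window.  The 98-day default makes
    the 14-week comparison inclusive (a gap of exactly 98 days merges).
    """
    if not events:
        return []
    pids = {e.participant_id for e in events}
    drugs = {e.canonical_drug for e in events}
    if len(pids) > 1 or len(drugs) > 1:
        raise ValueError("build_windows expects events of one participant and one drug")
    dates = sorted({e.date for e in events})
    pid, drug = pids.pop(), drugs.pop()

    windows: list[PrescriptionWindow] = []
    run_start = dates[0]
    prev = dates[0]
    n = 1
    for d in dates[1:]:
        if (d - prev).days > max_gap_days:
            windows.append(PrescriptionWindow(pid, drug, run_start, prev, n))
            run_start, n = d, 1
        else:
            n += 1
        prev = d
    windows.append(PrescriptionWindow(pid, drug, run_start, prev, n))
    return windows


def find_overlaps(citalopram_windows: Sequence[PrescriptionWindow],
                  interacting_windows: Sequence[PrescriptionWindow],
                  pad_days: int = PAD_DAYS) -> list[CoPrescriptionInstance]:
    """Pair anchor and interacting windows whose padded intervals intersect.

    Both windows are padded symmetrically: [start − pad, end + pad], closed.
    ``overlap_days`` is the inclusive day count of the padded intersection, so
    two raw windows separated by exactly ``2*pad_days`` touch with overlap 1.
    """
    if pad_days < 0:
        raise ValueError("pad_days must be non-negative")
    pad = dt.timedelta(days=pad_days)
    out: list[CoPrescriptionInstance] = []
    for c in citalopram_windows:
        for d in interacting_windows:
            if c.participant_id != d.participant_id:
                raise ValueError("overlap detection is per participant")
            lo = max(c.start, d.start) - pad
            hi = min(c.end, d.end) + pad
            if lo <= hi:
                out.append(CoPrescriptionInstance(
                    participant_id=c.participant_id,
                    interacting_drug=d.canonical_drug,
                    citalopram_window=c,
                    drug_window=d,
                    overlap_days=(hi - lo).days + 1,
                    single_prescription=d.n_prescriptions == 1,
                ))
    return out


def summarize_participant(instances: Sequence[CoPrescriptionInstance],
                          participant_id: str | None = None) -> DdiSummary:
    """Collapse one participant's co-prescription instances to a lifetime summary.

    Overlap duration is estimated only from instances whose interacting-drug
    window has repeated prescriptions; participants whose instances are all
    single-prescription keep DDI status but are flagged ``durations_excluded``.
    """
    if instances:
        pids = {i.participant_id for i in instances}
        if len(pids) > 1:
            raise ValueError("instances must share one participant")
        participant_id = pids.pop()
    if participant_id is None:
        raise ValueError("participant_id required for an empty instance list")
    multi = [i.overlap_days for i in instances if not i.single_prescription]
    return DdiSummary(
        participant_id=participant_id,
        ddi_status=bool(instances),
        n_distinct_drugs=len({i.interacting_drug for i in instances}),
        n_instances=len(instances),
        longest_overlap_days=max(multi) if multi else None,
        durations_excluded=bool(instances) and not multi,
    )


# ---------------------------------------------------------------------------
# Vectorised table path
# ---------------------------------------------------------------------------

def build_windows_table(events: pd.DataFrame,
                        max_gap_days: int = MAX_GAP_DAYS) -> pd.DataFrame:
    """Vectorised window construction over a whole events table.

    ``events`` needs columns participant_id, canonical_drug, date (datetime64).
    Returns one row per window: participant_id, canonical_drug, start, end,
    n_prescriptions.
    """
    if events.empty:
        return pd.DataFrame(columns=["participant_id", "canonical_drug",
                                     "start", "end", "n_prescriptions"])
    df = (events[["participant_id", "canonical_drug", "date"]]
          .drop_duplicates()
          .sort_values(["participant_id", "canonical_drug", "date"],
                       kind="mergesort")
          .reset_index(drop=True))
    day = df["date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    new_group = ((df["participant_id"] != df["participant_id"].shift())
                 | (df["canonical_drug"] != df["canonical_drug"].shift())).to_numpy()
    gap = np.diff(day, prepend=day[:1])
    wid = np.cumsum(new_group | (gap > max_gap_days))
    out = (df.assign(_wid=wid)
             .groupby("_wid", sort=True)
             .agg(participant_id=("participant_id", "first"),
                  canonical_drug=("canonical_drug", "first"),
                  start=("date", "first"),
                  end=("date", "last"),
                  n_prescriptions=("date", "size"))
             .reset_index(drop=True))
    return out


def find_overlaps_table(citalopram_windows: pd.DataFrame,
                        interacting_windows: pd.DataFrame,
                        pad_days: int = PAD_DAYS) -> pd.DataFrame:
    """Vectorised padded-overlap detection across participants.

    Returns one row per co-prescription instance with columns participant_id,
    interacting_drug, citalopram start/end, drug start/end, overlap_days,
    single_prescription.
    """
    if pad_days < 0:
        raise ValueError("pad_days must be non-negative")
    cols = ["participant_id", "interacting_drug", "cital_start", "cital_end",
            "drug_start", "drug_end", "drug_n_prescriptions",
            "overlap_days", "single_prescription"]
    if citalopram_windows.empty or interacting_windows.empty:
        return pd.DataFrame(columns=cols)
    c = citalopram_windows.rename(columns={"start": "cital_start", "end": "cital_end"})
    d = interacting_windows.rename(columns={
        "canonical_drug": "interacting_drug", "start": "drug_start",
        "end": "drug_end", "n_prescriptions": "drug_n_prescriptions"})
    pairs = c[["participant_id", "cital_start", "cital_end"]].merge(
        d[["participant_id", "interacting_drug", "drug_start", "drug_end",
           "drug_n_prescriptions"]],
        on="participant_id", how="inner")
    lo = pairs[["cital_start", "drug_start"]].max(axis=1)
    hi = pairs[["cital_end", "drug_end"]].min(axis=1)
    overlap = (hi - lo).dt.days + 2 * pad_days + 1
    pairs = pairs.assign(overlap_days=overlap,
                         single_prescription=pairs["drug_n_prescriptions"] == 1)
    return pairs.loc[pairs["overlap_days"] >= 1, cols].reset_index(drop=True)


def summarize_table(instances: pd.DataFrame,
                    participant_ids: Iterable) -> pd.DataFrame:
    """Per-participant lifetime DDI summaries over a whole cohort.

    ``participant_ids`` lists every participant that should get a row (those
    without instances get ddi_status False).
    """
    idx = pd.Index(pd.unique(pd.Series(list(participant_ids))), name="participant_id")
    if instances.empty:
        out = pd.DataFrame(index=idx)
        out["ddi_status"] = False
        out["n_distinct_drugs"] = 0
        out["n_instances"] = 0
        out["longest_overlap_days"] = np.nan
        out["durations_excluded"] = False
        return out.reset_index()
    grp = instances.groupby("participant_id")
    multi = instances.loc[~instances["single_prescription"]]
    summary = pd.DataFrame({
        "n_distinct_drugs": grp["interacting_drug"].nunique(),
        "n_instances": grp.size(),
        "longest_overlap_days": multi.groupby("participant_id")["overlap_days"].max(),
    }).reindex(idx)
    summary["n_distinct_drugs"] = summary["n_distinct_drugs"].fillna(0).astype(int)
    summary["n_instances"] = summary["n_instances"].fillna(0).astype(int)
    summary["ddi_status"] = summary["n_instances"] > 0
    summary["durations_excluded"] = (summary["ddi_status"]
                                     & summary["longest_overlap_days"].isna())
    return summary.reset_index()[["participant_id", "ddi_status", "n_distinct_drugs",
                                  "n_instances", "longest_overlap_days",
                                  "durations_excluded"]]


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortBuild:
    """Full result of the annotation → windows → overlaps → summary chain."""
    cohort: pd.DataFrame
    windows: pd.DataFrame
    instances: pd.DataFrame
    annotation: dict[str, tuple[str, ...]]
    counts: dict[str, int]


def build_cohort(events: pd.DataFrame,
                 covariates: pd.DataFrame,
                 catalog: Catalog,
                 mode: str = "default",
                 max_gap_days: int = MAX_GAP_DAYS,
                 pad_days: int = PAD_DAYS) -> CohortBuild:
    """Run the exposure pipeline and join summaries onto participant covariates.

    ``events`` has columns participant_id, drug_name (free text), date.  The
    result has exactly one row per participant with at least one anchor-drug
    prescription; participants with interacting-drug events but no anchor
    events are excluded and counted.  Derived columns: age_at_first_citalopram
    (from a birth_year covariate when present), cital_longest_days (inclusive
    span of the longest anchor window), n_citalopram_rx.
    """
    events = events.copy()
    events["date"] = pd.to_datetime(events["date"])
    filtered = filter_catalog(catalog, mode)
    interacting = filtered.interacting_names()

    annotation = annotate_names(events["drug_name"].unique(), filtered)
    n_unmatched = sum(1 for v in annotation.values() if not v)

    mapped = (events.assign(canonical_drug=events["drug_name"].map(annotation))
                    .explode("canonical_drug")
                    .dropna(subset=["canonical_drug"]))
    keep = mapped["canonical_drug"].isin(interacting | {catalog.index_drug})
    mapped = mapped.loc[keep, ["participant_id", "canonical_drug", "date"]]

    windows = build_windows_table(mapped, max_gap_days=max_gap_days)
    is_anchor = windows["canonical_drug"] == catalog.index_drug
    cital_w = windows.loc[is_anchor]
    drug_w = windows.loc[~is_anchor]

    with_cital = set(cital_w["participant_id"])
    dropped = set(drug_w["participant_id"]) - with_cital
    if dropped:
        logger.info("excluded %d participant(s) with interacting-drug events "
                    "but no %s events", len(dropped), catalog.index_drug)
    drug_w = drug_w[drug_w["participant_id"].isin(with_cital)]

    instances = find_overlaps_table(cital_w, drug_w, pad_days=pad_days)
    summary = summarize_table(instances, with_cital)

    cital_stats = (cital_w.assign(
                       span=(cital_w["end"] - cital_w["start"]).dt.days + 1)
                   .groupby("participant_id")
                   .agg(first_citalopram=("start", "min"),
                        cital_longest_days=("span", "max"),
                        n_citalopram_rx=("n_prescriptions", "sum"))
                   .reset_index())

    cohort = (covariates.merge(cital_stats, on="participant_id", how="inner")
                        .merge(summary, on="participant_id", how="left"))
    if "birth_year" in cohort.columns and "age_at_first_citalopram" not in cohort.columns:
        cohort["age_at_first_citalopram"] = (
            cohort["first_citalopram"].dt.year - cohort["birth_year"]).astype(float)

    counts = {
        "events_read": int(len(events)),
        "names_unmatched": int(n_unmatched),
        "events_mapped": int(len(mapped)),
        "windows_built": int(len(windows)),
        "participants_no_anchor_excluded": int(len(dropped)),
        "instances_found": int(len(instances)),
        "participants": int(len(cohort)),
        "participants_ddi": int(cohort["ddi_status"].sum()),
        "participants_non_ddi": int((~cohort["ddi_status"]).sum()),
    }
    return CohortBuild(cohort=cohort, windows=windows, instances=instances,
                       annotation=annotation, counts=counts)


def cohort_ddi_table(events: pd.DataFrame, covariates: pd.DataFrame,
                     catalog: Catalog, mode: str = "default") -> pd.DataFrame:
    """One row per anchor-treated participant: covariates + DDI summary."""
    return build_cohort(events, covariates, catalog, mode).cohort
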