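"""Cohort construction for TNF-inhibitor treatment trajectories.

Reproduces the attrition flow used to turn raw longitudinal medication-order
tables into a switching cohort:

1. normalize free-text drug names to canonical TNFi categories (dropping
   orders that match no TNFi pattern);
2. drop patients without demographic data;
3. deduplicate orders on (patient, date, canonical drug);
4. drop orders at encounters with no associated clinical note, and attach the
   last (max-timestamp) note to every surviving encounter;
5. drop encounters where two or more distinct TNFi were ordered on the same
   date;
6. detect switches — a change in canonical TNFi between two consecutive
   TNFi-order encounters of one patient;
7. classify each patient as switcher, non-switcher with sufficient follow-up,
   or lost to follow-up (no encounter at least six months after the last TNFi
   order).

Every stage logs (records in, removed, out) to an :class:`AttritionLog` whose
chaining is checked, so the flow-chart accounting is exact by construction.

Working tables are pandas DataFrames with the column conventions in
``ORDER_COLUMNS``/``NOTE_COLUMNS``/``ENCOUNTER_COLUMNS``; dates are
datetime64 (parsed from ISO-8601 text on load).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import CANONICAL_DRUGS, Lexicon, default_lexicon

ORDER_COLUMNS = ("patient_id", "encounter_id", "order_date", "raw_name")
NOTE_COLUMNS = ("note_id", "encounter_id", "timestamp", "text")
ENCOUNTER_COLUMNS = ("patient_id", "encounter_id", "date")

#: Patient status labels (exhaustive, disjoint partition of the cohort).
STATUS_SWITCHER = "switcher"
STATUS_NO_SWITCH = "no_switch_followed"
STATUS_LOST = "lost_to_followup"

#: Six calendar months, as whole days (365.25 / 2 rounded to nearest integer).
DEFAULT_HORIZON_DAYS = 183
DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class SwitchEvent:
    """An ordered TNFi change between two consecutive order encounters."""

    patient_id: str
    ordinal: int
    from_drug: str
    to_drug: str
    from_date: pd.Timestamp
    to_date: pd.Timestamp
    note_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.from_drug == self.to_drug:
            raise ValueError("switch requires distinct drugs")
        if not self.from_date < self.to_date:
            raise ValueError("switch requires from_date < to_date")
        if self.ordinal < 1:
            raise ValueError("ordinal is 1-based")


@dataclass(frozen=True)
class PatientStatus:
    patient_id: str
    status: str
    n_switches: int
    followup_years: float

    def __post_init__(self) -> None:
        if (self.status == STATUS_SWITCHER) != (self.n_switches >= 1):
            raise ValueError("status 'switcher' iff n_switches >= 1")
        if self.status == STATUS_LOST and self.n_switches != 0:
            raise ValueError("lost_to_followup implies zero switches")


@dataclass(frozen=True)
class AttritionStage:
    stage: str
    n_in: int
    n_removed: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - self.n_removed:
            raise ValueError(f"stage {self.stage}: out != in - removed")


@dataclass
class AttritionLog:
    """Chained record of per-stage attrition (the flow-chart accounting)."""

    stages: list[AttritionStage] = field(default_factory=list)

    def append(self, stage: str, n_in: int, n_removed: int) -> AttritionStage:
        entry = AttritionStage(stage, n_in, n_removed, n_in - n_removed)
        if self.stages and self.stages[-1].n_out != entry.n_in:
            raise ValueError(
                f"attrition chain broken at {stage}: previous out "
                f"{self.stages[-1].n_out} != in {entry.n_in}"
            )
        self.stages.append(entry)
        return entry

    def validate(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(f"attrition chain broken before {nxt.stage}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.stages])

    def to_json(self) -> str:
        return json.dumps([asdict(s) for s in self.stages], indent=2)


@dataclass
class Cohort:
    """Output bundle of :func:`build_cohort`."""

    orders: pd.DataFrame
    note_map: dict[str, str]           # encounter_id -> note_id
    switches: list[SwitchEvent]
    statuses: pd.DataFrame             # patient_id, status, n_switches, followup_years
    attrition: AttritionLog

    @property
    def patients(self) -> pd.Index:
        return pd.Index(self.statuses["patient_id"])

    def first_drug(self) -> pd.Series:
        """First documented canonical TNFi per patient."""
        o = self.orders.sort_values(["patient_id", "order_date", "canonical"])
        return o.groupby("patient_id")["canonical"].first()

    def switches_by_patient(self) -> dict[str, list[SwitchEvent]]:
        out: dict[str, list[SwitchEvent]] = {}
        for ev in self.switches:
            out.setdefault(ev.patient_id, []).append(ev)
        for evs in out.values():
            evs.sort(key=lambda e: e.ordinal)
        return out

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "attrition.json").write_text(self.attrition.to_json())
        with (out / "switch_events.jsonl").open("w") as fh:
            for ev in self.switches:
                d = asdict(ev)
                d["from_date"] = str(pd.Timestamp(d["from_date"]).date())
                d["to_date"] = str(pd.Timestamp(d["to_date"]).date())
                fh.write(json.dumps(d) + "\n")
        statuses = self.statuses.copy()
        statuses["first_tnfi"] = statuses["patient_id"].map(self.first_drug())
        statuses.to_csv(out / "patient_status.csv", index=False)
        pd.Series(self.note_map, name="note_id").rename_axis("encounter_id").to_csv(
            out / "note_map.csv"
        )


# ---------------------------------------------------------------------------
# pipeline stages


def normalize_orders(orders: pd.DataFrame, lexicon: Lexicon) -> tuple[pd.DataFrame, int]:
    """Assign canonical TNFi categories; drop orders matching no pattern."""
    orders = orders.copy()
    orders["order_date"] = pd.to_datetime(orders["order_date"])
    orders["canonical"] = orders["raw_name"].map(lexicon.normalize)
    kept = orders[orders["canonical"].notna()].copy()
    return kept, len(orders) - len(kept)


def deduplicate_orders(orders: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep at most one order per (patient, date, canonical drug) triple.

    Rows are sorted on all identifying columns before taking the first of each
    group, so the result is invariant under input permutation.
    """
    ordered = orders.sort_values(
        ["patient_id", "order_date", "canonical", "encounter_id", "raw_name"],
        kind="mergesort",
    )
    kept = ordered.drop_duplicates(
        subset=["patient_id", "order_date", "canonical"], keep="first"
    ).reset_index(drop=True)
    return kept, len(orders) - len(kept)


def drop_multi_tnfi_encounters(orders: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove all orders on any (patient, date) with >= 2 distinct TNFi."""
    n_distinct = orders.groupby(["patient_id", "order_date"])["canonical"].transform(
        "nunique"
    )
    kept = orders[n_distinct < 2].reset_index(drop=True)
    return kept, len(orders) - len(kept)


def attach_last_note(
    orders: pd.DataFrame, notes: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, str], int]:
    """Drop orders at note-less encounters; attach the last note elsewhere.

    For an encounter with several notes, the note with the maximum timestamp
    is used (it is the most complete version); timestamp ties are broken by
    lexicographically greatest note_id for determinism.

    Returns (surviving orders, encounter_id -> note_id map, n orders removed).
    """
    notes = notes.copy()
    notes["timestamp"] = pd.to_datetime(notes["timestamp"])
    last = (
        notes.sort_values(["encounter_id", "timestamp", "note_id"], kind="mergesort")
        .groupby("encounter_id")
        .tail(1)
    )
    note_map_all = dict(zip(last["encounter_id"], last["note_id"]))
    has_note = orders["encounter_id"].isin(note_map_all)
    kept = orders[has_note].reset_index(drop=True)
    note_map = {e: note_map_all[e] for e in kept["encounter_id"].unique()}
    return kept, note_map, int((~has_note).sum())


def detect_switches(
    timeline: pd.DataFrame, note_map: Optional[Mapping[str, str]] = None
) -> list[SwitchEvent]:
    """Switch events for one patient's date-ordered TNFi order timeline.

    The timeline must be deduplicated, carry one canonical per encounter, and
    be sorted by date (unsorted input raises).  One event is emitted per
    adjacent pair of order encounters with different canonicals; ordinals are
    consecutive from 1.  The infliximab bio-originator and biosimilars are
    distinct categories, so transitions between them count as switches.
    """
    if timeline.empty:
        return []
    if timeline["patient_id"].nunique() > 1:
        raise ValueError("detect_switches expects a single patient's timeline")
    dates = pd.to_datetime(timeline["order_date"]).to_numpy()
    if not (dates[:-1] <= dates[1:]).all():
        raise ValueError("timeline must be sorted by order_date")
    patient = timeline["patient_id"].iloc[0]
    drugs = timeline["canonical"].to_list()
    encounters = timeline["encounter_id"].to_list()
    events: list[SwitchEvent] = []
    ordinal = 0
    for i in range(1, len(drugs)):
        if drugs[i] != drugs[i - 1]:
            ordinal += 1
            note_id = note_map.get(encounters[i]) if note_map is not None else None
            events.append(
                SwitchEvent(
                    patient_id=patient,
                    ordinal=ordinal,
                    from_drug=drugs[i - 1],
                    to_drug=drugs[i],
                    from_date=pd.Timestamp(dates[i - 1]),
                    to_date=pd.Timestamp(dates[i]),
                    note_id=note_id,
                )
            )
    return events


def classify_followup(
    patient_orders: pd.DataFrame,
    patient_encounters: pd.DataFrame,
    switches: Optional[Sequence[SwitchEvent]] = None,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
) -> PatientStatus:
    """Assign switcher / no_switch_followed / lost_to_followup to one patient.

    A patient with at least one switch is a switcher regardless of follow-up
    (the flow branches switchers off before the follow-up exclusion).  A
    non-switcher needs some encounter at least ``horizon_days`` after their
    last TNFi order to count as followed; otherwise they are lost to
    follow-up.  Follow-up years run from the first TNFi order to the last
    encounter of any kind.
    """
    if patient_orders.empty:
        raise ValueError("classify_followup requires at least one surviving order")
    if switches is None:
        switches = detect_switches(
            patient_orders.sort_values("order_date", kind="mergesort")
        )
    patient = patient_orders["patient_id"].iloc[0]
    order_dates = pd.to_datetime(patient_orders["order_date"])
    enc_dates = pd.to_datetime(patient_encounters["date"]) if len(patient_encounters) else order_dates
    last_event = max(order_dates.max(), enc_dates.max() if len(enc_dates) else order_dates.max())
    followup_years = float((last_event - order_dates.min()).days) / DAYS_PER_YEAR
    n_switches = len(switches)
    if n_switches >= 1:
        status = STATUS_SWITCHER
    else:
        gap_ok = (enc_dates - order_dates.max()).dt.days >= horizon_days
        status = STATUS_NO_SWITCH if bool(gap_ok.any()) else STATUS_LOST
    return PatientStatus(patient, status, n_switches, followup_years)


@dataclass
class CohortConfig:
    horizon_days: int = DEFAULT_HORIZON_DAYS
    min_cell: int = 10


def build_cohort(
    orders: pd.DataFrame,
    encounters: pd.DataFrame,
    notes: pd.DataFrame,
    demographics: pd.DataFrame,
    lexicon: Optional[Lexicon] = None,
    config: Optional[CohortConfig] = None,
) -> Cohort:
    """Run the full attrition flow and return the assembled cohort.

    Stages execute in the fixed order documented in the module docstring;
    the attrition log chains exactly (each stage's output count is the next
    stage's input count).  Deterministic: identical inputs give identical
    outputs.
    """
    lexicon = lexicon or default_lexicon()
    config = config or CohortConfig()
    log = AttritionLog()

    orders = orders.copy()
    for col in ORDER_COLUMNS:
        if col not in orders.columns:
            raise ValueError(f"orders table missing column {col!r}")

    n0 = len(orders)
    orders, removed = normalize_orders(orders, lexicon)
    log.append("normalize_drug_names", n0, removed)

    known_patients = set(demographics["patient_id"]) if len(demographics) else set()
    keep = orders["patient_id"].isin(known_patients)
    log.append("drop_missing_demographics", len(orders), int((~keep).sum()))
    orders = orders[keep].reset_index(drop=True)

    orders, removed = deduplicate_orders(orders)
    log.append("deduplicate_orders", log.stages[-1].n_out, removed)

    orders, note_map, removed = attach_last_note(orders, notes)
    log.append("drop_orders_without_notes", log.stages[-1].n_out, removed)

    orders, removed = drop_multi_tnfi_encounters(orders)
    log.append("drop_multi_tnfi_encounters", log.stages[-1].n_out, removed)
    surviving = set(orders["encounter_id"])
    note_map = {e: n for e, n in note_map.items() if e in surviving}
    log.validate()

    encounters = encounters.copy()
    if len(encounters):
        encounters["date"] = pd.to_datetime(encounters["date"])
        enc_by_patient = dict(tuple(encounters.groupby("patient_id", sort=False)))
    else:
        enc_by_patient = {}
    empty_enc = encounters.iloc[0:0]

    switches: list[SwitchEvent] = []
    statuses: list[PatientStatus] = []
    for patient, timeline in orders.sort_values(
        ["patient_id", "order_date"], kind="mergesort"
    ).groupby("patient_id", sort=True):
        evs = detect_switches(timeline, note_map)
        switches.extend(evs)
        pe = enc_by_patient.get(patient, empty_enc)
        statuses.append(
            classify_followup(timeline, pe, evs, horizon_days=config.horizon_days)
        )

    status_df = pd.DataFrame(
        [asdict(s) for s in statuses],
        columns=["patient_id", "status", "n_switches", "followup_years"],
    )
    return Cohort(orders=orders, note_map=note_map, switches=switches,
                  statuses=status_df, attrition=log)


# ---------------------------------------------------------------------------
# tabulation (Table-1-style summaries)


def status_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of patients in each status category, of the pre-follow-up
    total (switchers + followed non-switchers + lost to follow-up)."""
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def switch_band_table(
    band_counts: Mapping[str, int], n_switchers: int, n_total: int
) -> pd.DataFrame:
    """Percentages for the number-of-switches bands.

    Band percentages are reported twice, as the convention in demographic
    tables: of the switcher stratum (``pct_of_switchers``) and of the full
    followed cohort (``pct_of_total``).
    """
    rows = []
    for band, count in band_counts.items():
        rows.append(
            {
                "band": band,
                "count": int(count),
                "pct_of_switchers": 100.0 * count / n_switchers if n_switchers else np.nan,
                "pct_of_total": 100.0 * count / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _band_label(n: int) -> str:
    if n <= 2:
        return str(n)
    return ">2"

SWITCH_BANDS = ("0", "1", "2", ">2")


@dataclass
class DemographicsSummary:
    """Stratified cohort summary (followed patients only, lost excluded)."""

    n_total: int
    n_switch: int
    n_no_switch: int
    continuous: pd.DataFrame     # variable x (stratum mean, sd)
    categorical: pd.DataFrame    # variable, level, per-stratum count & pct
    switch_bands: pd.DataFrame
    missing: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_total": self.n_total,
                "n_switch": self.n_switch,
                "n_no_switch": self.n_no_switch,
                "continuous": self.continuous.to_dict(orient="records"),
                "categorical": self.categorical.to_dict(orient="records"),
                "switch_bands": self.switch_bands.to_dict(orient="records"),
                "missing": self.missing,
            },
            indent=2,
        )


def tabulate_demographics(
    cohort: Cohort, demographics: pd.DataFrame, min_cell: int = 10
) -> DemographicsSummary:
    """Build a Table-1-style stratified summary of the followed cohort.

    Lost-to-follow-up patients are excluded.  Continuous variables (age,
    follow-up years) are summarised as mean (SD) per stratum; categorical
    variables (sex, race, first TNFi, primary diagnosis) as count (%) with
    per-variable missing counts.  Primary-diagnosis categories with fewer
    than ``min_cell`` switchers are consolidated into "Other" (a
    de-identification small-cell rule).
    """
    st = cohort.statuses
    followed = st[st["status"] != STATUS_LOST].copy()
    followed["is_switch"] = followed["status"] == STATUS_SWITCHER
    n_total = len(followed)
    n_switch = int(followed["is_switch"].sum())
    n_no = n_total - n_switch

    demo = demographics.set_index("patient_id") if len(demographics) else pd.DataFrame()
    merged = followed.merge(
        demo, left_on="patient_id", right_index=True, how="left"
    )
    merged["first_tnfi"] = merged["patient_id"].map(cohort.first_drug())

    missing: dict[str, int] = {}

    cont_rows = []
    for var in ("age", "followup_years"):
        if var not in merged.columns:
            continue
        vals = merged[var]
        missing[var] = int(vals.isna().sum())
        for label, mask in (
            ("total", np.ones(len(merged), bool)),
            ("no_switch", ~merged["is_switch"].to_numpy()),
            ("switch", merged["is_switch"].to_numpy()),
        ):
            v = vals[mask].dropna()
            cont_rows.append(
                {"variable": var, "stratum": label, "n": len(v),
                 "mean": float(v.mean()) if len(v) else np.nan,
                 "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan}
            )
    continuous = pd.DataFrame(cont_rows)

    cat_rows = []
    for var in ("sex", "race", "first_tnfi", "primary_diagnosis"):
        if var not in merged.columns:
            continue
        vals = merged[var].copy()
        missing[var] = int(vals.isna().sum())
        if var == "primary_diagnosis":
            switch_counts = vals[merged["is_switch"]].value_counts()
            small = {lvl for lvl, c in switch_counts.items() if c < min_cell}
            small |= set(vals.dropna().unique()) - set(switch_counts.index)
            vals = vals.where(~vals.isin(small), "Other")
        present = vals.notna()
        denom = {
            "total": int(present.sum()),
            "no_switch": int((present & ~merged["is_switch"]).sum()),
            "switch": int((present & merged["is_switch"]).sum()),
        }
        for level in sorted(vals.dropna().unique()):
            sel = vals == level
            for label, mask in (
                ("total", np.ones(len(merged), bool)),
                ("no_switch", ~merged["is_switch"].to_numpy()),
                ("switch", merged["is_switch"].to_numpy()),
            ):
                count = int((sel & mask).sum())
                cat_rows.append(
                    {"variable": var, "level": level, "stratum": label,
                     "count": count,
                     "pct": 100.0 * count / denom[label] if denom[label] else np.nan}
                )
    categorical = pd.DataFrame(cat_rows)

    bands = followed["n_switches"].map(_band_label)
    band_counts = {b: int((bands == b).sum()) for b in SWITCH_BANDS}
    switch_bands = switch_band_table(
        {b: c for b, c in band_counts.items() if b != "0"}, n_switch, n_total
    )
    zero = pd.DataFrame(
        [{"band": "0", "count": band_counts["0"],
          "pct_of_switchers": np.nan,
          "pct_of_total": 100.0 * band_counts["0"] / n_total if n_total else np.nan}]
    )
    switch_bands = pd.concat([zero, switch_bands], ignore_index=True)

    return DemographicsSummary(
        n_total=n_total, n_switch=n_switch, n_no_switch=n_no,
        continuous=continuous, categorical=categorical,
        switch_bands=switch_bands, missing=missing,
    )


def group_comparison_tests(
    cohort: Cohort, demographics: pd.DataFrame
) -> dict[str, float]:
    """Per-variable p-values comparing switchers with followed non-switchers.

    Pearson chi-square (no continuity correction) on the status-by-category
    contingency table for categorical variables; Welch two-sided t-test for
    continuous variables.  Degenerate inputs (a zero-variance stratum, an
    empty table) report NaN rather than raising.
    """
    st = cohort.statuses
    followed = st[st["status"] != STATUS_LOST].copy()
    followed["is_switch"] = followed["status"] == STATUS_SWITCHER
    demo = demographics.set_index("patient_id") if len(demographics) else pd.DataFrame()
    merged = followed.merge(demo, left_on="patient_id", right_index=True, how="left")
    merged["first_tnfi"] = merged["patient_id"].map(cohort.first_drug())

    out: dict[str, float] = {}
    for var in ("age", "followup_years"):
        if var not in merged.columns:
            continue
        a = merged.loc[merged["is_switch"], var].dropna()
        b = merged.loc[~merged["is_switch"], var].dropna()
        if len(a) < 2 or len(b) < 2 or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
            out[var] = float("nan")
            continue
        out[var] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    for var in ("sex", "race", "first_tnfi", "primary_diagnosis"):
        if var not in merged.columns:
            continue
        tab = pd.crosstab(merged["is_switch"], merged[var])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            out[var] = float("nan")
            continue
        out[var] = float(chi_square_test(tab.to_numpy()).pvalue)
    return out


def chi_square_test(table: np.ndarray):
    """Pearson chi-square on a contingency table, without Yates correction."""
    return stats.chi2_contingency(np.asarray(table), correction=False)
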