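"""Switch-trajectory summaries: per-patient drug sequences, Sankey-style
flow tables, and switching-reason distributions by switch ordinal.

A patient's sequence is their first documented canonical TNFi followed by the
destination drug of each switch in ordinal order.  The flow table counts
stage-wise transitions (stage 1 = first drug to second drug, …) with a
terminal "no further switch" node absorbing patients whose sequence ends, so
flow is conserved at every node.  Reason-by-ordinal tables band switches into
first / second / third-or-more and report the share of each reason category,
by default among notes with a documented (non-na) reason only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, SwitchEvent
from .extraction import NA, ExtractionRecord, REASON_CATEGORIES

TERMINAL = "no further switch"

ORDINAL_BANDS = ("first", "second", "third_plus")


def build_sequences(cohort: Cohort) -> dict[str, list[str]]:
    """Ordered canonical drug sequence per patient (length 1 + n switches)."""
    first = cohort.first_drug()
    by_patient = cohort.switches_by_patient()
    sequences: dict[str, list[str]] = {}
    for patient in cohort.statuses["patient_id"]:
        seq = [first[patient]]
        for ev in by_patient.get(patient, []):
            seq.append(ev.to_drug)
        sequences[patient] = seq
    return sequences


@dataclass
class FlowTable:
    """Stage-wise patient flows: (stage, source drug, target drug-or-terminal,
    count).  Stage s counts the transition from the s-th to the (s+1)-th drug
    in a sequence; a sequence ending at the s-th drug flows to the terminal
    node at stage s."""

    flows: pd.DataFrame   # columns: stage, source, target, count

    def validate_conservation(self) -> None:
        """Inflow of every non-terminal node must equal its outflow at the
        next stage (within the table's depth)."""
        f = self.flows
        if f.empty:
            return
        max_stage = int(f["stage"].max())
        for stage in range(1, max_stage):
            into = (
                f[(f["stage"] == stage) & (f["target"] != TERMINAL)]
                .groupby("target")["count"].sum()
            )
            out = f[f["stage"] == stage + 1].groupby("source")["count"].sum()
            for node in set(into.index) | set(out.index):
                if int(into.get(node, 0)) != int(out.get(node, 0)):
                    raise ValueError(
                        f"flow not conserved at stage {stage} node {node!r}: "
                        f"in {int(into.get(node, 0))} != out {int(out.get(node, 0))}"
                    )

    def stage_total(self, stage: int) -> int:
        return int(self.flows.loc[self.flows["stage"] == stage, "count"].sum())


def sankey_flow_table(
    sequences: Mapping[str, Sequence[str]], max_depth: int = 3
) -> FlowTable:
    """Count stage-wise drug transitions up to ``max_depth`` stages.

    Every patient contributes exactly one flow per stage until their sequence
    ends (terminal flow) or the depth is reached, so the stage-1 total equals
    the cohort size and conservation holds at every intermediate node.
    """
    counts: dict[tuple[int, str, str], int] = {}
    for seq in sequences.values():
        if not seq:
            continue
        for stage in range(1, max_depth + 1):
            if stage < len(seq):
                key = (stage, seq[stage - 1], seq[stage])
            elif stage == len(seq):
                key = (stage, seq[stage - 1], TERMINAL)
            else:
                break
            counts[key] = counts.get(key, 0) + 1
    flows = pd.DataFrame(
        [{"stage": k[0], "source": k[1], "target": k[2], "count": v}
         for k, v in sorted(counts.items())],
        columns=["stage", "source", "target", "count"],
    )
    table = FlowTable(flows)
    table.validate_conservation()
    return table


def _band(ordinal: int) -> str:
    if ordinal == 1:
        return "first"
    if ordinal == 2:
        return "second"
    return "third_plus"


def reason_by_switch_ordinal(
    switches: Iterable[SwitchEvent],
    records: Iterable[ExtractionRecord],
    include_na: bool = False,
) -> pd.DataFrame:
    """Reason-category proportions per switch-ordinal band.

    Switch events are joined to extraction records by note id; ordinals map
    to bands first / second / third_plus.  By default records with reason
    "na" (no documented reason) are excluded from a band's denominator,
    mirroring reporting of reason shares among notes with an extractable
    reason; with ``include_na`` the "na" column is kept and proportions span
    all seven categories.

    Returns a DataFrame indexed by band with one proportion column per
    included category plus an ``n`` denominator column; bands with no
    records are reported with n = 0 and NaN proportions.
    """
    by_note = {}
    for rec in records:
        by_note[rec.note_id] = rec
    cats = list(REASON_CATEGORIES) if include_na else [c for c in REASON_CATEGORIES if c != NA]
    tallies = {band: {c: 0 for c in cats} for band in ORDINAL_BANDS}
    for ev in switches:
        if ev.note_id is None or ev.note_id not in by_note:
            continue
        reason = by_note[ev.note_id].reason
        if reason == NA and not include_na:
            continue
        tallies[_band(ev.ordinal)][reason] += 1
    rows = []
    for band in ORDINAL_BANDS:
        n = sum(tallies[band].values())
        row = {"band": band, "n": n}
        for c in cats:
            row[c] = tallies[band][c] / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("band")


# ---------------------------------------------------------------------------
# plotting (optional; matplotlib)


def plot_reason_by_ordinal(table: pd.DataFrame, ax=None):
    """Stacked-bar chart of reason shares per switch-ordinal band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cats = [c for c in table.columns if c != "n"]
    bottom = np.zeros(len(table))
    for c in cats:
        vals = table[c].fillna(0.0).to_numpy()
        ax.bar(table.index, vals, bottom=bottom, label=c)
        bottom += vals
    ax.set_ylabel("proportion of switches")
    ax.set_xlabel("switch ordinal")
    ax.legend(fontsize=8, bbox_to_anchor=(1.02, 1), loc="upper left")
    ax.figure.tight_layout()
    return ax


def plot_flow_table(table: FlowTable, ax=None):
    """Grouped-bar rendering of the stage-wise transition counts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    f = table.flows
    if f.empty:
        return ax
    labels = [f"{r.source}→{r.target}" for r in f.itertuples()]
    ax.barh(np.arange(len(f)), f["count"].to_numpy())
    ax.set_yticks(np.arange(len(f)), labels, fontsize=7)
    ax.set_xlabel("patients")
    for stage, grp in f.groupby("stage"):
        ax.axhline(grp.index.max() + 0.5, color="grey", lw=0.5)
    ax.figure.tight_layout()
    return ax
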