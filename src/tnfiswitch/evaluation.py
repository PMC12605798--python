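"""Evaluation framework for TNFi switching extraction.

Implements the two label sources and the comparison statistics used to
benchmark extraction backends:

* **silver labels** — stopped/started drug labels derived automatically from
  structured medication orders (the switch events); no reason labels exist in
  structured data;
* **gold labels** — human-annotated stopped/started drugs and reason;
* **micro-F1** with two null policies: score every labeled note
  (``all_values``, an "na" prediction counting as no positive prediction), or
  first drop notes whose record reports no switching reason
  (``null_dropped``, self-filtering on the evaluated backend's own output);
* **pairwise win/loss/tie rates** between backends (win = correct where the
  other is not; tie = both correct or both incorrect), per-model mean win
  rate with SD across opponents, and win-minus-loss against a designated
  baseline;
* **concordance** — per-field agreement between two backends irrespective of
  truth, with mean and SD across fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import SwitchEvent
from .extraction import NA, ExtractionRecord

DRUG_FIELDS = ("last_tnfi", "new_tnfi")
ALL_FIELDS = ("last_tnfi", "new_tnfi", "reason")
NULL_POLICIES = ("all_values", "null_dropped")


# ---------------------------------------------------------------------------
# labels


@dataclass
class LabelSet:
    """Per-note truth labels from one source ("silver" or "gold").

    ``labels`` is indexed by note_id with one column per labeled field.
    Silver sets carry drug fields only: a switching reason is not observable
    in structured order data, so silver reason labels are absent (never "na").
    """

    source: str
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.source not in ("silver", "gold"):
            raise ValueError("source must be 'silver' or 'gold'")
        if self.source == "silver" and "reason" in self.labels.columns:
            raise ValueError("silver labels cannot carry a reason field")

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_FIELDS if c in self.labels.columns)

    @property
    def note_ids(self) -> pd.Index:
        return self.labels.index

    def __len__(self) -> int:
        return len(self.labels)


def derive_silver_labels(switches: Sequence[SwitchEvent]) -> LabelSet:
    """Drug labels from structured orders: the note attached to a switch's
    destination encounter is labeled (last = drug before, new = drug after).

    A note linked to more than one switch event violates the cohort's
    one-note-per-destination-encounter invariant and raises.
    """
    rows = {}
    for ev in switches:
        if ev.note_id is None:
            continue
        if ev.note_id in rows:
            raise ValueError(f"note {ev.note_id} linked to multiple switch events")
        rows[ev.note_id] = {"last_tnfi": ev.from_drug, "new_tnfi": ev.to_drug}
    labels = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=["last_tnfi", "new_tnfi"])
    labels.index.name = "note_id"
    return LabelSet("silver", labels)


def load_gold_labels(path: str | Path) -> LabelSet:
    """Gold annotations from a CSV with columns note_id,last_tnfi,new_tnfi,reason."""
    df = pd.read_csv(path, dtype=str).set_index("note_id")
    return LabelSet("gold", df[["last_tnfi", "new_tnfi", "reason"]])


def split_validation_test(
    note_patient: Mapping[str, str],
    fraction: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Patient-level validation/test split of a note set.

    All notes of one patient land on the same side, so no patient leaks
    between prompt selection and final scoring.  The validation side holds
    ``round(fraction * n_patients)`` patients, drawn uniformly with the given
    seed; an empty side raises.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    patients = sorted(set(note_patient.values()))
    n_val = round(fraction * len(patients))
    if n_val == 0 or n_val == len(patients):
        raise ValueError(
            f"{len(patients)} patients at fraction {fraction} leaves an empty side"
        )
    rng = np.random.default_rng(seed)
    val_patients = set(rng.choice(patients, size=n_val, replace=False))
    val_ids = sorted(n for n, p in note_patient.items() if p in val_patients)
    test_ids = sorted(n for n, p in note_patient.items() if p not in val_patients)
    return val_ids, test_ids


# ---------------------------------------------------------------------------
# micro-F1


@dataclass(frozen=True)
class EvalResult:
    backend_id: str
    field: str
    label_source: str
    null_policy: str
    micro_f1: float          # NaN when undefined (zero evaluable notes)
    n_evaluated: int

    def __post_init__(self) -> None:
        if not math.isnan(self.micro_f1) and not 0.0 <= self.micro_f1 <= 1.0:
            raise ValueError("micro_f1 out of [0, 1]")


def _records_by_note(records: Iterable[ExtractionRecord]) -> dict[str, ExtractionRecord]:
    out = {}
    for rec in records:
        if rec.note_id in out:
            raise ValueError(f"duplicate record for note {rec.note_id}")
        out[rec.note_id] = rec
    return out


def micro_f1(
    records: Iterable[ExtractionRecord],
    labels: LabelSet,
    field: str,
    null_policy: str = "all_values",
) -> EvalResult:
    """Micro-averaged F1 of one field against a label set.

    Positives are pooled over the substantive (non-na) classes: an "na"
    prediction makes no positive prediction (costing recall when the label is
    substantive), and an "na" label contributes no positive truth.  Under
    ``null_dropped``, notes whose record reports reason = "na" (no switching
    reason found by the backend itself) are excluded before scoring.
    """
    if field not in labels.fields:
        raise ValueError(f"field {field!r} not labeled in {labels.source} labels")
    if null_policy not in NULL_POLICIES:
        raise ValueError(f"unknown null policy {null_policy!r}")
    by_note = _records_by_note(records)
    missing = [n for n in labels.note_ids if n not in by_note]
    if missing:
        raise ValueError(f"records missing for {len(missing)} labeled notes")

    note_ids = list(labels.note_ids)
    if null_policy == "null_dropped":
        note_ids = [n for n in note_ids if by_note[n].reason != NA]

    tp = fp = fn = 0
    for n in note_ids:
        gold = labels.labels.loc[n, field]
        gold = NA if pd.isna(gold) else str(gold)
        pred = getattr(by_note[n], field)
        if pred != NA and gold != NA:
            if pred == gold:
                tp += 1
            else:
                fp += 1
                fn += 1
        elif pred != NA:   # gold is na
            fp += 1
        elif gold != NA:   # pred is na
            fn += 1
    denom = 2 * tp + fp + fn
    score = 2 * tp / denom if denom else float("nan")
    return EvalResult(
        backend_id=next(iter(by_note.values())).backend_id if by_note else "",
        field=field, label_source=labels.source, null_policy=null_policy,
        micro_f1=score, n_evaluated=len(note_ids),
    )


# ---------------------------------------------------------------------------
# pairwise win rates


@dataclass
class WinRateMatrix:
    """Pairwise win/loss/tie fractions over a shared note set.

    For an ordered pair (A, B): win = fraction of notes where A is correct
    and B is not, loss = the reverse, tie = the rest (both correct or both
    incorrect), so win + loss + tie = 1 and win(A, B) = loss(B, A).  The
    mean win rate of a model averages its win rate over all opponents, with
    a population SD across opponents.
    """

    models: list[str]
    win: pd.DataFrame
    loss: pd.DataFrame
    tie: pd.DataFrame
    n_notes: int

    def mean_win_rates(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            opponents = [o for o in self.models if o != m]
            w = self.win.loc[m, opponents].to_numpy(dtype=float)
            rows.append({"model": m, "mean_win_rate": float(w.mean()),
                         "sd": float(w.std(ddof=0))})
        return pd.DataFrame(rows).set_index("model")

    def mean_tie_rates(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            opponents = [o for o in self.models if o != m]
            t = self.tie.loc[m, opponents].to_numpy(dtype=float)
            rows.append({"model": m, "mean_tie_rate": float(t.mean()),
                         "sd": float(t.std(ddof=0))})
        return pd.DataFrame(rows).set_index("model")


def pairwise_win_rates(correct: Mapping[str, Sequence[bool]]) -> WinRateMatrix:
    """Win/loss/tie matrix from per-model correctness vectors.

    All vectors must cover the same notes in the same order; at least two
    models are required.
    """
    models = list(correct)
    if len(models) < 2:
        raise ValueError("need at least two models")
    arrays = {m: np.asarray(v, dtype=bool) for m, v in correct.items()}
    n = len(arrays[models[0]])
    if any(len(a) != n for a in arrays.values()):
        raise ValueError("correctness vectors differ in length (mismatched note sets)")
    if n == 0:
        raise ValueError("empty note set")
    win = pd.DataFrame(0.0, index=models, columns=models)
    loss = pd.DataFrame(0.0, index=models, columns=models)
    for a in models:
        for b in models:
            if a == b:
                continue
            win.loc[a, b] = float(np.mean(arrays[a] & ~arrays[b]))
            loss.loc[a, b] = float(np.mean(arrays[b] & ~arrays[a]))
    tie = 1.0 - win - loss
    for m in models:
        tie.loc[m, m] = 1.0
        win.loc[m, m] = 0.0
        loss.loc[m, m] = 0.0
    return WinRateMatrix(models=models, win=win, loss=loss, tie=tie, n_notes=n)


def win_minus_loss_vs_baseline(
    matrix: WinRateMatrix, baseline_id: str
) -> dict[str, float]:
    """win(M, baseline) − loss(M, baseline) per model; positive means the
    model beats the baseline more often than it loses to it."""
    if baseline_id not in matrix.models:
        raise ValueError(f"baseline {baseline_id!r} not in matrix")
    out = {}
    for m in matrix.models:
        if m == baseline_id:
            out[m] = 0.0
        else:
            out[m] = float(matrix.win.loc[m, baseline_id] - matrix.loss.loc[m, baseline_id])
    return out


# ---------------------------------------------------------------------------
# concordance


@dataclass(frozen=True)
class ConcordanceResult:
    per_field: dict[str, float]   # percent agreement per field
    mean: float                   # mean percent across fields
    sd: float                     # population SD across fields
    n_notes: int


def concordance(
    records_a: Iterable[ExtractionRecord],
    records_b: Iterable[ExtractionRecord],
    fields: Sequence[str] = ALL_FIELDS,
) -> ConcordanceResult:
    """Agreement between two backends' normalized outputs, truth-free.

    Per field, the fraction of shared notes where both backends emit the
    same value ("na" agreeing with "na" counts); reported in percent with
    mean and population SD across fields.
    """
    a = _records_by_note(records_a)
    b = _records_by_note(records_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("record sets cover disjoint notes")
    per_field = {}
    for f in fields:
        agree = sum(getattr(a[n], f) == getattr(b[n], f) for n in shared)
        per_field[f] = 100.0 * agree / len(shared)
    vals = np.array(list(per_field.values()))
    return ConcordanceResult(per_field=per_field, mean=float(vals.mean()),
                             sd=float(vals.std(ddof=0)), n_notes=len(shared))


# ---------------------------------------------------------------------------
# suite


def correctness_vector(
    records: Iterable[ExtractionRecord],
    labels: LabelSet,
    fields: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Per-note correctness: every labeled field matches its truth value.

    Missing (NaN) gold values count as "na" truth.
    """
    fields = tuple(fields) if fields is not None else labels.fields
    by_note = _records_by_note(records)
    out = {}
    for n in labels.note_ids:
        if n not in by_note:
            raise ValueError(f"record missing for labeled note {n}")
        ok = True
        for f in fields:
            gold = labels.labels.loc[n, f]
            gold = NA if pd.isna(gold) else str(gold)
            if getattr(by_note[n], f) != gold:
                ok = False
                break
        out[n] = ok
    return pd.Series(out, name="correct")


@dataclass
class EvaluationReport:
    """Machine-readable bundle emitted by :func:`evaluate_suite`."""

    eval_results: list[EvalResult]
    win_matrix: WinRateMatrix
    win_minus_loss: dict[str, float]
    concordance_vs_baseline: dict[str, ConcordanceResult]
    baseline_id: str
    truth_source: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_id": self.baseline_id,
                "truth_source": self.truth_source,
                "eval_results": [asdict(r) for r in self.eval_results],
                "win": self.win_matrix.win.to_dict(),
                "loss": self.win_matrix.loss.to_dict(),
                "tie": self.win_matrix.tie.to_dict(),
                "mean_win_rates": self.win_matrix.mean_win_rates().to_dict(orient="index"),
                "win_minus_loss": self.win_minus_loss,
                "concordance_vs_baseline": {
                    m: asdict(c) for m, c in self.concordance_vs_baseline.items()
                },
            },
            indent=2, allow_nan=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def evaluate_suite(
    records_by_backend: Mapping[str, Sequence[ExtractionRecord]],
    silver: Optional[LabelSet],
    gold: Optional[LabelSet],
    baseline_id: str,
) -> EvaluationReport:
    """Full benchmark: micro-F1 (both policies, both label sources), the
    pairwise win/loss/tie matrix, win-minus-loss vs the baseline, and
    concordance of every backend with the baseline.

    Win-rate correctness is judged against gold labels when provided, else
    against the silver drug labels; the truth source used is recorded in the
    report.
    """
    if not records_by_backend:
        raise ValueError("no backends to evaluate")
    if baseline_id not in records_by_backend:
        raise ValueError(f"baseline {baseline_id!r} has no records")
    if silver is None and gold is None:
        raise ValueError("at least one label source is required")

    results: list[EvalResult] = []
    for backend_id, records in records_by_backend.items():
        for labels in (silver, gold):
            if labels is None or not len(labels):
                continue
            for f in labels.fields:
                for policy in NULL_POLICIES:
                    res = micro_f1(records, labels, f, policy)
                    results.append(
                        EvalResult(backend_id, f, labels.source, policy,
                                   res.micro_f1, res.n_evaluated)
                    )

    truth = gold if gold is not None and len(gold) else silver
    truth_source = truth.source
    correct = {
        backend_id: correctness_vector(records, truth).to_numpy()
        for backend_id, records in records_by_backend.items()
    }
    matrix = pairwise_win_rates(correct) if len(correct) >= 2 else None
    if matrix is None:
        # degenerate single-backend case: self-ties only
        only = next(iter(correct))
        matrix = pairwise_win_rates({only: correct[only], only + "(copy)": correct[only]})
        matrix.models = [only]
    wml = win_minus_loss_vs_baseline(matrix, baseline_id)

    base_records = records_by_backend[baseline_id]
    conc = {
        backend_id: concordance(records, base_records)
        for backend_id, records in records_by_backend.items()
    }
    return EvaluationReport(
        eval_results=results, win_matrix=matrix, win_minus_loss=wml,
        concordance_vs_baseline=conc, baseline_id=baseline_id,
        truth_source=truth_source,
    )
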