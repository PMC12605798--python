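"""Synthetic EHR-shaped data with planted ground truth.

Generates the four input tables the cohort pipeline consumes — medication
orders, encounters, clinical notes, demographics — plus gold annotations for
every switch note, with a :class:`GroundTruth` record of everything planted.
The generator emulates the statistical shape of a real TNFi order stream:

* multi-year per-patient timelines with maintenance visits between switches;
* brand/generic/biosimilar spelling variation with dose/route suffixes;
* duplicate orders, same-date multi-TNFi encounters, and note-less
  encounters injected at configured rates (at positions chosen so the
  planted switch structure is provably unaffected by their removal);
* switching reasons drawn from a categorical distribution and verbalized in
  a configurable fraction of switch notes (the rest omit any reason);
* loss to follow-up for a configured fraction of non-switching patients.

Default rates anchor to the published cohort shape (first-TNFi shares,
switch-count bands, reason shares, 41% reason documentation, 20.6% loss to
follow-up).  Notes are template-based — see :mod:`tnfiswitch.templates` —
so the rule-based reference extractor recovers planted fields exactly;
nothing about free clinical prose is emulated.

All randomness flows from one seed through spawned per-patient streams, so
output is byte-identical across runs and independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .lexicon import CANONICAL_DRUGS, Lexicon, default_lexicon
from .templates import (
    DISTRACTOR_SENTENCES,
    MAINTENANCE_TEMPLATES,
    REASON_PHRASES,
    REASON_SENTENCE,
    SWITCH_TEMPLATES,
)

NA = "na"

DOSE_SUFFIXES = (
    "",
    " 40 mg/0.8 mL syringe",
    " 50 mg injection",
    " 100 mg IV infusion",
    " 20 mg prefilled pen",
)

_EPOCH = pd.Timestamp("2012-01-01")


def _check_dist(name: str, dist: dict, tol: float = 1e-9) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {total})")
    if any(v < 0 for v in dist.values()):
        raise ValueError(f"{name} has negative probabilities")


class GeneratorConfig(BaseModel):
    """Tunable study conditions for the synthetic cohort.

    Categorical defaults follow the published cohort: first-TNFi shares and
    the switch-count bands from the demographics table, reason shares from
    the extracted-reason distribution (the two unreported categories split
    the remainder), 41% of switch notes verbalizing a reason, 20.6% of
    patients lost to follow-up, 3.4% of encounters with multiple TNFi.
    ``switch_count_weights`` are renormalized at draw time (the published
    band percentages sum to 97%).
    """

    n_patients: int = Field(500, gt=0)
    seed: int = 0

    first_drug_probs: dict[str, float] = {
        "adalimumab": 0.409,
        "infliximab-biooriginator": 0.263,
        "etanercept": 0.241,
        "certolizumab": 0.033,
        "infliximab-biosimilar": 0.031,
        "golimumab": 0.023,
    }
    p_switcher: float = Field(0.1825, ge=0, le=1)
    p_lost_to_followup: float = Field(0.206, ge=0, le=1)
    switch_count_weights: dict[int, float] = {1: 0.701, 2: 0.198, 3: 0.0497, 4: 0.0213}
    reason_probs: dict[str, float] = {
        "lack_of_efficacy": 0.569,
        "adverse_event": 0.135,
        "insurance_cost": 0.108,
        "patient_preference": 0.082,
        "drug_resistance": 0.053,
        "other": 0.053,
    }
    p_reason_documented: float = Field(0.41, ge=0, le=1)
    p_duplicate_order: float = Field(0.27, ge=0, le=1)
    p_multi_tnfi_encounter: float = Field(0.034, ge=0, le=1)
    p_missing_note: float = Field(0.087, ge=0, le=1)
    p_extra_note: float = Field(0.15, ge=0, le=1)
    p_missing_demographics: float = Field(0.001, ge=0, le=1)
    mean_extra_encounters: float = Field(3.0, ge=0)
    interval_gamma_shape: float = Field(2.0, gt=0)
    interval_gamma_scale: float = Field(60.0, gt=0)

    age_mean: float = 39.9
    age_sd: float = 19.0
    sex_probs: dict[str, float] = {"Female": 0.571, "Male": 0.429}
    race_probs: dict[str, float] = {
        "White": 0.602,
        "Hispanic": 0.139,
        "Other": 0.109,
        "Asian": 0.070,
        "Black or African American": 0.048,
        "Multi-Race/Ethnicity": 0.024,
        "Southwest Asian and North African": 0.008,
    }
    diagnosis_probs: dict[str, float] = {
        "Inflammatory Bowel Disease": 0.154,
        "Multiple": 0.074,
        "Rheumatoid Arthritis": 0.057,
        "Psoriasis": 0.034,
        "Juvenile Idiopathic Arthritis": 0.031,
        "SA": 0.023,
        "Hidradenitis": 0.017,
        "Psoriatic arthritis": 0.017,
        "Uveitis": 0.006,
        "Other": 0.013,
        "Unspecified": 0.574,
    }

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        _check_dist("first_drug_probs", self.first_drug_probs)
        _check_dist("reason_probs", self.reason_probs)
        _check_dist("sex_probs", self.sex_probs)
        _check_dist("race_probs", self.race_probs)
        _check_dist("diagnosis_probs", self.diagnosis_probs)
        if set(self.first_drug_probs) - set(CANONICAL_DRUGS):
            raise ValueError("first_drug_probs has unknown drugs")
        if self.p_switcher + self.p_lost_to_followup > 1.0:
            raise ValueError("p_switcher + p_lost_to_followup exceeds 1")
        if any(w < 0 for w in self.switch_count_weights.values()):
            raise ValueError("negative switch_count_weights")
        if sum(self.switch_count_weights.values()) <= 0:
            raise ValueError("switch_count_weights sum to zero")
        if any(k < 1 for k in self.switch_count_weights):
            raise ValueError("switch counts must be >= 1")
        return self


@dataclass(frozen=True)
class PlantedSwitch:
    patient_id: str
    ordinal: int
    from_drug: str
    to_drug: str
    reason: str               # substantive category (always planted)
    reason_documented: bool   # whether the note verbalizes it
    note_id: str

    @property
    def gold_reason(self) -> str:
        """What an annotator reading only the note would label."""
        return self.reason if self.reason_documented else NA


@dataclass
class GroundTruth:
    """Everything planted: the oracle for pipeline round-trip tests."""

    switches: list[PlantedSwitch]
    status_plan: pd.DataFrame          # patient_id, status, n_switches
    note_flags: pd.DataFrame           # note_id, reason_documented, drugs_mentioned
    n_duplicates: int = 0
    n_multi_encounters: int = 0
    n_noteless_orders: int = 0

    def switches_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.switches])


@dataclass
class SyntheticData:
    orders: pd.DataFrame
    encounters: pd.DataFrame
    notes: pd.DataFrame
    demographics: pd.DataFrame
    gold: pd.DataFrame                 # note_id, last_tnfi, new_tnfi, reason
    truth: GroundTruth
    config: GeneratorConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.orders.to_csv(out / "orders.csv", index=False)
        self.encounters.to_csv(out / "encounters.csv", index=False)
        self.notes.to_csv(out / "notes.csv", index=False)
        self.demographics.to_csv(out / "demographics.csv", index=False)
        self.gold.to_csv(out / "gold_labels.csv", index=False)
        with (out / "ground_truth.jsonl").open("w") as fh:
            for s in self.truth.switches:
                fh.write(json.dumps(asdict(s)) + "\n")
        (out / "generator_config.json").write_text(self.config.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# note text


def _spelling(canonical: str, rng: np.random.Generator, lexicon: Lexicon,
              with_dose: bool = True) -> str:
    pool = lexicon.synonyms(canonical)
    name = str(pool[rng.integers(len(pool))])
    if with_dose:
        name += str(DOSE_SUFFIXES[rng.integers(len(DOSE_SUFFIXES))])
    return name


def generate_note(
    rng: np.random.Generator,
    lexicon: Optional[Lexicon] = None,
    current_drug: Optional[str] = None,
    switch: Optional[tuple[str, str]] = None,
    reason_category: Optional[str] = None,
) -> str:
    """Compose one clinical note from the template library.

    A switch note verbalizes the stopped and started drug (random spelling,
    stopped first) and, when ``reason_category`` is given, one phrase from
    that category's bank; a maintenance note mentions only the continuing
    drug without causal language.  Distractor sentences (vitals, labs,
    non-TNFi medications) are always present.
    """
    lexicon = lexicon or default_lexicon()
    n_distract = int(rng.integers(2, 5))
    idx = rng.choice(len(DISTRACTOR_SENTENCES), size=n_distract, replace=False)
    distractors = [DISTRACTOR_SENTENCES[i] for i in idx]
    body: list[str] = [distractors[0]]
    if switch is not None:
        from_drug, to_drug = switch
        tmpl = SWITCH_TEMPLATES[rng.integers(len(SWITCH_TEMPLATES))]
        body.append(tmpl.format(last=_spelling(from_drug, rng, lexicon),
                                new=_spelling(to_drug, rng, lexicon)))
        if reason_category is not None:
            bank = REASON_PHRASES[reason_category]
            body.append(REASON_SENTENCE.format(phrase=bank[rng.integers(len(bank))]))
    elif current_drug is not None:
        tmpl = MAINTENANCE_TEMPLATES[rng.integers(len(MAINTENANCE_TEMPLATES))]
        body.append(tmpl.format(drug=_spelling(current_drug, rng, lexicon)))
    body.extend(distractors[1:])
    return " ".join(body)


# ---------------------------------------------------------------------------
# cohort generation


def _draw(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _generate_patient(
    pid: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    lexicon: Lexicon,
    excluded: bool,
):
    """Build one patient's rows.  Corruption injections (duplicates,
    multi-TNFi, missing notes) are restricted to encounters that are neither
    the first of a drug run nor the patient's final encounter, which
    guarantees their downstream removal cannot change the switch structure,
    the switch-note linkage, or the follow-up classification."""
    u = rng.random()
    if u < cfg.p_switcher:
        status = "switcher"
    elif u < cfg.p_switcher + cfg.p_lost_to_followup:
        status = "lost_to_followup"
    else:
        status = "no_switch_followed"
    if status == "switcher":
        k = int(_draw(rng, cfg.switch_count_weights))
    else:
        k = 0

    drugs = [str(_draw(rng, cfg.first_drug_probs))]
    for _ in range(k):
        others = [d for d in CANONICAL_DRUGS if d != drugs[-1]]
        drugs.append(str(others[rng.integers(len(others))]))

    n_runs = k + 1
    extra = int(rng.poisson(cfg.mean_extra_encounters))
    run_lengths = 1 + rng.multinomial(extra, np.full(n_runs, 1.0 / n_runs))

    # encounter plan: (run index, position in run, drug)
    plan: list[tuple[int, int, str]] = []
    for r, length in enumerate(run_lengths):
        for pos in range(int(length)):
            plan.append((r, pos, drugs[r]))
    n_enc = len(plan)

    start = _EPOCH + pd.Timedelta(days=int(rng.integers(0, 6 * 365)))
    dates = [start]
    for _ in range(n_enc - 1):
        gap = int(np.clip(rng.gamma(cfg.interval_gamma_shape,
                                    cfg.interval_gamma_scale), 14, 365))
        dates.append(dates[-1] + pd.Timedelta(days=gap))

    orders, encounters, notes, gold, flags = [], [], [], [], []
    switches: list[PlantedSwitch] = []
    n_dup = n_multi = n_noteless = 0

    for j, ((run, pos, drug), date) in enumerate(zip(plan, dates)):
        enc_id = f"E{pid}-{j:03d}"
        note_id = f"N{pid}-{j:03d}"
        encounters.append({"patient_id": pid, "encounter_id": enc_id,
                           "date": date.date().isoformat()})
        raw = _spelling(drug, rng, lexicon)
        orders.append({"patient_id": pid, "encounter_id": enc_id,
                       "order_date": date.date().isoformat(), "raw_name": raw})
        if not excluded and rng.random() < cfg.p_duplicate_order:
            orders.append({"patient_id": pid, "encounter_id": enc_id,
                           "order_date": date.date().isoformat(),
                           "raw_name": _spelling(drug, rng, lexicon)})
            n_dup += 1

        is_switch_dest = run >= 1 and pos == 0
        eligible = (not excluded) and pos >= 1 and j < n_enc - 1
        noteless = False
        if eligible:
            v = rng.random()
            if v < cfg.p_multi_tnfi_encounter:
                other = [d for d in CANONICAL_DRUGS if d != drug]
                orders.append({"patient_id": pid, "encounter_id": enc_id,
                               "order_date": date.date().isoformat(),
                               "raw_name": _spelling(str(other[rng.integers(len(other))]),
                                                     rng, lexicon)})
                n_multi += 1
            elif v < cfg.p_multi_tnfi_encounter + cfg.p_missing_note:
                noteless = True
                n_noteless += 1

        if noteless:
            continue

        if is_switch_dest:
            reason = str(_draw(rng, cfg.reason_probs))
            documented = bool(rng.random() < cfg.p_reason_documented)
            text = generate_note(rng, lexicon, switch=(drugs[run - 1], drug),
                                 reason_category=reason if documented else None)
            if not excluded:
                switches.append(PlantedSwitch(pid, run, drugs[run - 1], drug,
                                              reason, documented, note_id))
                gold.append({"note_id": note_id, "last_tnfi": drugs[run - 1],
                             "new_tnfi": drug,
                             "reason": reason if documented else NA})
            flags.append({"note_id": note_id, "reason_documented": documented,
                          "drugs_mentioned": True})
        else:
            text = generate_note(rng, lexicon, current_drug=drug)
            flags.append({"note_id": note_id, "reason_documented": False,
                          "drugs_mentioned": True})
        notes.append({"note_id": note_id, "encounter_id": enc_id,
                      "timestamp": f"{date.date().isoformat()}T16:00:00",
                      "text": text})
        if rng.random() < cfg.p_extra_note:
            # an earlier same-encounter draft: the last-note rule must skip it
            notes.append({"note_id": f"{note_id}d", "encounter_id": enc_id,
                          "timestamp": f"{date.date().isoformat()}T09:00:00",
                          "text": generate_note(rng, lexicon, current_drug=drug)})
            flags.append({"note_id": f"{note_id}d", "reason_documented": False,
                          "drugs_mentioned": True})

    last_date = dates[-1]
    if status == "lost_to_followup":
        if rng.random() < 0.7:
            d = last_date + pd.Timedelta(days=int(rng.integers(20, 150)))
            encounters.append({"patient_id": pid, "encounter_id": f"E{pid}-X",
                               "date": d.date().isoformat()})
    else:
        d = last_date + pd.Timedelta(days=int(rng.integers(200, 700)))
        encounters.append({"patient_id": pid, "encounter_id": f"E{pid}-FU",
                           "date": d.date().isoformat()})

    demo = None
    if not excluded:
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 2, 95))
        demo = {"patient_id": pid, "age": round(age, 1),
                "sex": str(_draw(rng, cfg.sex_probs)),
                "race": str(_draw(rng, cfg.race_probs)),
                "primary_diagnosis": str(_draw(rng, cfg.diagnosis_probs))}

    plan_row = {"patient_id": pid,
                "status": "excluded_no_demographics" if excluded else status,
                "n_switches": k}
    return orders, encounters, notes, demo, gold, flags, switches, plan_row, \
        (n_dup, n_multi, n_noteless)


def generate_cohort(config: Optional[GeneratorConfig] = None,
                    lexicon: Optional[Lexicon] = None) -> SyntheticData:
    """Generate a full synthetic cohort with planted ground truth.

    Fully reproducible from ``config.seed``; empirical category shares and
    corruption rates converge on the configured values as ``n_patients``
    grows (binomially, so within ~3 SE at any fixed n).
    """
    cfg = config or GeneratorConfig()
    lexicon = lexicon or default_lexicon()
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_patients)

    all_orders, all_enc, all_notes, all_demo, all_gold, all_flags = [], [], [], [], [], []
    all_switches: list[PlantedSwitch] = []
    plans = []
    n_dup = n_multi = n_noteless = 0
    for i in range(cfg.n_patients):
        rng = np.random.default_rng(streams[i])
        excluded = bool(rng.random() < cfg.p_missing_demographics)
        o, e, nt, demo, g, fl, sw, plan, counts = _generate_patient(
            f"P{i:05d}", cfg, rng, lexicon, excluded
        )
        all_orders += o
        all_enc += e
        all_notes += nt
        if demo is not None:
            all_demo.append(demo)
        all_gold += g
        all_flags += fl
        all_switches += sw
        plans.append(plan)
        n_dup += counts[0]
        n_multi += counts[1]
        n_noteless += counts[2]

    truth = GroundTruth(
        switches=all_switches,
        status_plan=pd.DataFrame(plans, columns=["patient_id", "status", "n_switches"]),
        note_flags=pd.DataFrame(all_flags,
                                columns=["note_id", "reason_documented", "drugs_mentioned"]),
        n_duplicates=n_dup, n_multi_encounters=n_multi, n_noteless_orders=n_noteless,
    )
    return SyntheticData(
        orders=pd.DataFrame(all_orders, columns=["patient_id", "encounter_id",
                                                 "order_date", "raw_name"]),
        encounters=pd.DataFrame(all_enc, columns=["patient_id", "encounter_id", "date"]),
        notes=pd.DataFrame(all_notes, columns=["note_id", "encounter_id",
                                               "timestamp", "text"]),
        demographics=pd.DataFrame(all_demo, columns=["patient_id", "age", "sex",
                                                     "race", "primary_diagnosis"]),
        gold=pd.DataFrame(all_gold, columns=["note_id", "last_tnfi", "new_tnfi", "reason"]),
        truth=truth,
        config=cfg,
    )


def generate_switch_notes(
    n: int,
    seed: int,
    p_reason_documented: float = 1.0,
    reason_probs: Optional[dict[str, float]] = None,
    lexicon: Optional[Lexicon] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A flat batch of switch notes with truth, for extractor calibration.

    Returns (notes, truth) frames; truth columns are note_id, last_tnfi,
    new_tnfi, reason (the documented category, or "na" when the note omits
    the reason).
    """
    lexicon = lexicon or default_lexicon()
    reason_probs = reason_probs or GeneratorConfig().reason_probs
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    notes, truth = [], []
    for i in range(n):
        from_drug = str(CANONICAL_DRUGS[rng.integers(len(CANONICAL_DRUGS))])
        others = [d for d in CANONICAL_DRUGS if d != from_drug]
        to_drug = str(others[rng.integers(len(others))])
        reason = str(_draw(rng, reason_probs))
        documented = bool(rng.random() < p_reason_documented)
        text = generate_note(rng, lexicon, switch=(from_drug, to_drug),
                             reason_category=reason if documented else None)
        note_id = f"S{i:05d}"
        notes.append({"note_id": note_id, "text": text})
        truth.append({"note_id": note_id, "last_tnfi": from_drug,
                      "new_tnfi": to_drug,
                      "reason": reason if documented else NA})
    return pd.DataFrame(notes), pd.DataFrame(truth)
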