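"""Zero-shot structured extraction of TNFi switching information from notes.

A backend is anything callable as ``raw_text = backend(prompt)`` with a
``backend_id`` attribute.  The pipeline renders one of four prompt variants
around a clinical note, calls the backend, and parses the response into a
fixed record: which TNFi was stopped, which was started, a categorical
switching reason, and the free-text rationale.  Two offline backends are
provided — a deterministic rule-based reference extractor co-designed with
the synthetic note templates, and a seeded noisy wrapper that corrupts its
fields at configurable rates — plus the contract under which an external
chat-model adapter can be plugged in.

Parsing is total: arbitrary response text degrades to a flagged record
(``parse_ok = False``) rather than raising, since real model output is not
guaranteed to be well-formed JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Protocol, Union

import numpy as np
import pandas as pd

from .lexicon import CANONICAL_DRUGS, Lexicon, default_lexicon
from .templates import REASON_PHRASES

logger = logging.getLogger(__name__)

NA = "na"

#: Closed switching-reason taxonomy (seven values including "na" = unknown /
#: no reason documented).
REASON_CATEGORIES: tuple[str, ...] = (
    "adverse_event",
    "drug_resistance",
    "insurance_cost",
    "lack_of_efficacy",
    "patient_preference",
    "other",
    NA,
)

#: Display forms used in prompts and in backend JSON answers.
REASON_DISPLAY: dict[str, str] = {
    "adverse_event": "Adverse event",
    "drug_resistance": "Drug resistance",
    "insurance_cost": "Insurance/Cost",
    "lack_of_efficacy": "Lack of efficacy",
    "patient_preference": "Patient preference",
    "other": "Other",
    NA: "NA",
}

PROMPT_VARIANTS = ("default", "drugs_provided", "reasons_provided", "all_values_provided")

_DRUG_HINT = (
    ' Choose from "adalimumab", "etanercept", "certolizumab", "golimumab", '
    '"infliximab-biooriginator", "infliximab-biosimilar".'
)
_REASON_HINT = (
    ' "Adverse event", "Drug resistance", "Insurance/Cost","Lack of efficacy",'
    '"Patient preference","Other", "NA"'
)

_BODY_TEMPLATE = (
    "Task: Tumor necrosis factor inhibitors (TNFis) are biologic drugs targeting "
    "TNF proteins. Using the clinical note provided, extract the following "
    "information into this JSON format: "
    '{"new_TNFi":"What new TNFi was prescribed or started?%(drugs)s If the patient '
    'is not starting a new TNFi, write "NA"","last_TNFi":"What was the last TNFi '
    'the patient used?%(drugs)s If none, write "NA"","Reason for Switching":'
    '"Which best describes why the last TNFi was stopped or planned to be '
    'stopped?%(reasons)s","full_reason_last_TNFi_stopped":"Provide a description '
    'for why the last TNFi was stopped or planned to be stopped?"} Answer:'
)

PROMPT_BODIES: dict[str, str] = {
    "default": _BODY_TEMPLATE % {"drugs": "", "reasons": ""},
    "drugs_provided": _BODY_TEMPLATE % {"drugs": _DRUG_HINT, "reasons": ""},
    "reasons_provided": _BODY_TEMPLATE % {"drugs": "", "reasons": _REASON_HINT},
    "all_values_provided": _BODY_TEMPLATE % {"drugs": _DRUG_HINT, "reasons": _REASON_HINT},
}

_NOTE_PREFIX = "Clinical note:\n"
_BODY_SENTINEL = "\n\nTask: Tumor necrosis factor inhibitors (TNFis)"


def render_prompt(
    variant: str,
    note_text: str,
    backend_tag: Optional[tuple[str, str]] = None,
) -> str:
    """Render a prompt variant around a clinical note.

    All variants share the four-key JSON output schema; "drugs_provided"
    enumerates the six canonical TNFi categories, "reasons_provided" the
    seven reason categories, "all_values_provided" both.  ``backend_tag``
    is an optional (prefix, suffix) pair of model-specific template tags
    wrapped around the prompt without altering its body.
    """
    if variant not in PROMPT_BODIES:
        raise ValueError(f"unknown prompt variant {variant!r}; expected one of {PROMPT_VARIANTS}")
    if not note_text:
        raise ValueError("note_text must be non-empty")
    prompt = f"{_NOTE_PREFIX}{note_text}\n\n{PROMPT_BODIES[variant]}"
    if backend_tag is not None:
        prefix, suffix = backend_tag
        prompt = f"{prefix}{prompt}{suffix}"
    return prompt


def note_from_prompt(prompt: str) -> str:
    """Recover the note text from a rendered prompt (used by offline backends)."""
    end = prompt.rfind(_BODY_SENTINEL)
    if end < 0:
        raise ValueError("prompt does not contain a task body")
    start = prompt.find(_NOTE_PREFIX)
    if start < 0 or start + len(_NOTE_PREFIX) > end:
        raise ValueError("prompt does not contain a clinical note block")
    return prompt[start + len(_NOTE_PREFIX): end]


# ---------------------------------------------------------------------------
# records and parsing


@dataclass(frozen=True)
class ExtractionRecord:
    note_id: str
    new_tnfi: str      # canonical drug or "na"
    last_tnfi: str     # canonical drug or "na"
    reason: str        # one of REASON_CATEGORIES
    full_reason: str
    parse_ok: bool
    backend_id: str

    def __post_init__(self) -> None:
        for f in ("new_tnfi", "last_tnfi"):
            v = getattr(self, f)
            if v != NA and v not in CANONICAL_DRUGS:
                raise ValueError(f"{f}={v!r} not a canonical drug or 'na'")
        if self.reason not in REASON_CATEGORIES:
            raise ValueError(f"reason={self.reason!r} not in the closed taxonomy")
        if not self.parse_ok and (
            self.new_tnfi != NA or self.last_tnfi != NA or self.reason != NA
        ):
            raise ValueError("parse_ok=False requires all categorical fields 'na'")


RECORD_KEYS = ("note_id", "new_tnfi", "last_tnfi", "reason", "full_reason",
               "parse_ok", "backend_id")


def _first_json_object(text: str) -> Optional[dict]:
    """First balanced, loadable JSON object in a text, or None.

    Code fences and surrounding prose are ignored; scanning is string-aware
    so braces inside quoted values do not unbalance the search.
    """
    text = re.sub(r"```[a-zA-Z]*", "", text)
    n = len(text)
    i = 0
    while i < n:
        if text[i] != "{":
            i += 1
            continue
        depth = 0
        in_str = False
        escape = False
        for j in range(i, n):
            c = text[j]
            if in_str:
                if escape:
                    escape = False
                elif c == "\\":
                    escape = True
                elif c == '"':
                    in_str = False
            elif c == '"':
                in_str = True
            elif c == "{":
                depth += 1
            elif c == "}":
                depth -= 1
                if depth == 0:
                    candidate = text[i: j + 1]
                    try:
                        obj = json.loads(candidate)
                    except (json.JSONDecodeError, ValueError):
                        break
                    if isinstance(obj, dict):
                        return obj
                    break
        i += 1
    return None


def _fold_key(key: str) -> str:
    return re.sub(r"[^a-z0-9]", "", key.lower())


_REASON_LOOKUP: dict[str, str] = {}
for _cat in REASON_CATEGORIES:
    _REASON_LOOKUP[re.sub(r"[^a-z0-9]+", " ", _cat.lower()).strip()] = _cat
    _REASON_LOOKUP[re.sub(r"[^a-z0-9]+", " ", REASON_DISPLAY[_cat].lower()).strip()] = _cat
_REASON_LOOKUP["unknown"] = NA
_REASON_LOOKUP[""] = NA


def _normalize_drug_answer(value, lexicon: Lexicon) -> str:
    if not isinstance(value, str):
        return NA
    v = value.strip()
    if v.lower() in {"na", "n/a", "none", "null", ""}:
        return NA
    canonical = lexicon.normalize(v)
    return canonical if canonical is not None else NA


def _normalize_reason_answer(value) -> tuple[str, bool]:
    """(category, matched) — unmatched non-empty text maps to 'other'."""
    if value is None:
        return NA, True
    if not isinstance(value, str):
        return NA, True
    folded = re.sub(r"[^a-z0-9]+", " ", value.lower()).strip()
    if folded in {"n a", "none", "null"}:
        return NA, True
    if folded in _REASON_LOOKUP:
        return _REASON_LOOKUP[folded], True
    return "other", False


def parse_extraction_output(
    raw_text: str,
    lexicon: Optional[Lexicon] = None,
    note_id: str = "",
    backend_id: str = "",
) -> ExtractionRecord:
    """Parse a backend's raw response into an :class:`ExtractionRecord`.

    Never raises: a response without a loadable JSON object yields a record
    with ``parse_ok=False`` and all categorical fields "na".  Drug answers
    are normalized through the lexicon; reason answers are matched
    case-insensitively with punctuation folding, and unmatched free-text
    reasons are binned as "other" with the text preserved in
    ``full_reason`` ("na" stays reserved for no-reason-documented).
    """
    lexicon = lexicon or default_lexicon()
    obj = _first_json_object(raw_text) if isinstance(raw_text, str) else None
    if obj is None:
        return ExtractionRecord(note_id, NA, NA, NA, "", False, backend_id)
    by_key = {_fold_key(k): v for k, v in obj.items()}
    new_tnfi = _normalize_drug_answer(by_key.get("newtnfi"), lexicon)
    last_tnfi = _normalize_drug_answer(by_key.get("lasttnfi"), lexicon)
    reason_raw = by_key.get("reasonforswitching")
    reason, matched = _normalize_reason_answer(reason_raw)
    full = by_key.get("fullreasonlasttnfistopped")
    full_reason = full.strip() if isinstance(full, str) else ""
    if full_reason.lower() in {"na", "n/a", "none", "null"}:
        full_reason = ""
    if not matched:
        logger.warning("note %s: unmatched reason text %r binned as 'other'",
                       note_id, reason_raw)
        if not full_reason and isinstance(reason_raw, str):
            full_reason = reason_raw.strip()
    return ExtractionRecord(note_id, new_tnfi, last_tnfi, reason, full_reason,
                            True, backend_id)


# ---------------------------------------------------------------------------
# rule-based reference extraction (co-designed with the note templates)


def extract_note_fields(
    note_text: str,
    lexicon: Optional[Lexicon] = None,
    reason_phrases: Optional[Mapping[str, Iterable[str]]] = None,
) -> tuple[str, str, str, str]:
    """(last_tnfi, new_tnfi, reason, full_reason) from a template-built note.

    Rules: distinct canonical TNFi in order of first mention give (stopped,
    started) — switch sentences always verbalize the stopped drug first; a
    single mentioned TNFi is the continuing drug (no new start); reason
    phrases are detected by case-insensitive bank lookup, absent phrase
    meaning no reason documented ("na").
    """
    lexicon = lexicon or default_lexicon()
    reason_phrases = reason_phrases if reason_phrases is not None else REASON_PHRASES
    seen: list[str] = []
    for _, canonical in lexicon.find_all(note_text):
        if canonical not in seen:
            seen.append(canonical)
    if len(seen) >= 2:
        last_tnfi, new_tnfi = seen[0], seen[1]
    elif len(seen) == 1:
        last_tnfi, new_tnfi = seen[0], NA
    else:
        last_tnfi, new_tnfi = NA, NA
    lowered = note_text.lower()
    reason, full_reason = NA, ""
    for category in REASON_CATEGORIES[:-1]:
        for phrase in reason_phrases.get(category, ()):
            if phrase.lower() in lowered:
                reason, full_reason = category, phrase
                break
        if reason != NA:
            break
    return last_tnfi, new_tnfi, reason, full_reason


def reference_extractor(
    note_text: str,
    note_id: str = "",
    lexicon: Optional[Lexicon] = None,
) -> ExtractionRecord:
    """Deterministic rule-based extraction of a template-built note."""
    last_tnfi, new_tnfi, reason, full_reason = extract_note_fields(note_text, lexicon)
    return ExtractionRecord(note_id, new_tnfi, last_tnfi, reason, full_reason,
                            True, "reference")


_SUBSTANTIVE_REASONS = REASON_CATEGORIES[:-1]
FIELD_POOLS: dict[str, tuple[str, ...]] = {
    "new_tnfi": CANONICAL_DRUGS,
    "last_tnfi": CANONICAL_DRUGS,
    "reason": _SUBSTANTIVE_REASONS,
}


def _note_rng(seed: int, note_text: str) -> np.random.Generator:
    h = int(hashlib.sha256(note_text.encode("utf-8")).hexdigest()[:8], 16)
    return np.random.default_rng([seed & 0x7FFFFFFF, h])


def _corrupt_fields(
    fields: dict[str, str],
    error_rates: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, str]:
    out = dict(fields)
    for name, pool in FIELD_POOLS.items():
        rate = float(error_rates.get(name, 0.0))
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"error rate for {name} must be in [0, 1]")
        if rate and rng.random() < rate:
            # uniform over the field's substantive values; may coincide with
            # the true value, giving per-field accuracy 1 - e + e/k
            out[name] = str(pool[rng.integers(len(pool))])
    return out


def noisy_extractor(
    note_text: str,
    error_rates: Union[float, Mapping[str, float]],
    seed: int,
    note_id: str = "",
    lexicon: Optional[Lexicon] = None,
    backend_id: str = "noisy",
) -> ExtractionRecord:
    """Reference extraction with seeded per-field corruption.

    Independently per field, with the configured probability, the true value
    is replaced by a uniform draw from that field's substantive values (six
    canonical drugs; six non-na reasons).  The per-note random stream is
    derived from (seed, note hash), so results are reproducible and
    independent of processing order.
    """
    if isinstance(error_rates, (int, float)):
        error_rates = {k: float(error_rates) for k in FIELD_POOLS}
    last_tnfi, new_tnfi, reason, full_reason = extract_note_fields(note_text, lexicon)
    fields = {"new_tnfi": new_tnfi, "last_tnfi": last_tnfi, "reason": reason}
    fields = _corrupt_fields(fields, error_rates, _note_rng(seed, note_text))
    if fields["reason"] != reason:
        full_reason = ""
    return ExtractionRecord(note_id, fields["new_tnfi"], fields["last_tnfi"],
                            fields["reason"], full_reason, True, backend_id)


# ---------------------------------------------------------------------------
# backends


class Backend(Protocol):
    """Contract for an extraction backend: prompt in, raw response out.

    External chat-model adapters implement the same contract; only the
    offline reference and noisy backends are exercised by the test suite.
    """

    backend_id: str

    def __call__(self, prompt: str) -> str: ...


def _answer_json(fields: dict[str, str], full_reason: str) -> str:
    return json.dumps(
        {
            "new_TNFi": fields["new_tnfi"] if fields["new_tnfi"] != NA else "NA",
            "last_TNFi": fields["last_tnfi"] if fields["last_tnfi"] != NA else "NA",
            "Reason for Switching": REASON_DISPLAY[fields["reason"]],
            "full_reason_last_TNFi_stopped": full_reason or "NA",
        }
    )


class ReferenceBackend:
    """Deterministic rule-based backend emitting schema-conformant JSON."""

    backend_id = "reference"

    def __init__(self, lexicon: Optional[Lexicon] = None):
        self.lexicon = lexicon or default_lexicon()

    def _fields(self, note_text: str) -> tuple[dict[str, str], str]:
        last_tnfi, new_tnfi, reason, full_reason = extract_note_fields(
            note_text, self.lexicon
        )
        return {"new_tnfi": new_tnfi, "last_tnfi": last_tnfi, "reason": reason}, full_reason

    def __call__(self, prompt: str) -> str:
        fields, full_reason = self._fields(note_from_prompt(prompt))
        return _answer_json(fields, full_reason)


class NoisyBackend(ReferenceBackend):
    """Reference backend with seeded per-field corruption (imperfect model)."""

    def __init__(
        self,
        error_rates: Union[float, Mapping[str, float]],
        seed: int,
        backend_id: Optional[str] = None,
        lexicon: Optional[Lexicon] = None,
    ):
        super().__init__(lexicon)
        if isinstance(error_rates, (int, float)):
            error_rates = {k: float(error_rates) for k in FIELD_POOLS}
        self.error_rates = dict(error_rates)
        self.seed = int(seed)
        rate_tag = "-".join(f"{k}{v:g}" for k, v in sorted(self.error_rates.items()))
        self.backend_id = backend_id or f"noisy[{rate_tag};seed{self.seed}]"

    def __call__(self, prompt: str) -> str:
        note_text = note_from_prompt(prompt)
        fields, full_reason = self._fields(note_text)
        true_reason = fields["reason"]
        fields = _corrupt_fields(fields, self.error_rates, _note_rng(self.seed, note_text))
        if fields["reason"] != true_reason:
            full_reason = ""
        return _answer_json(fields, full_reason)


# ---------------------------------------------------------------------------
# batch extraction with caching


def _cache_key(backend_id: str, variant: str, note_text: str) -> str:
    note_hash = hashlib.sha256(note_text.encode("utf-8")).hexdigest()
    return hashlib.sha256(f"{backend_id}|{variant}|{note_hash}".encode()).hexdigest()


def run_extraction(
    notes: Union[pd.DataFrame, Iterable[tuple[str, str]]],
    backend: Backend,
    variant: str = "reasons_provided",
    cache_dir: Optional[str | Path] = None,
    lexicon: Optional[Lexicon] = None,
) -> list[ExtractionRecord]:
    """Render, call and parse each note exactly once, with response caching.

    Responses are cached on (backend id, prompt variant, note hash); a rerun
    with a warm cache makes no backend calls and reproduces the records
    bit-identically.  A backend failure on one note yields a flagged record
    and the run continues.
    """
    if isinstance(notes, pd.DataFrame):
        pairs = list(zip(notes["note_id"].astype(str), notes["text"].astype(str)))
    else:
        pairs = [(str(i), str(t)) for i, t in notes]
    if not pairs:
        raise ValueError("no notes to extract")
    lexicon = lexicon or default_lexicon()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    records: list[ExtractionRecord] = []
    n_failures = 0
    for note_id, text in pairs:
        raw: Optional[str] = None
        cache_file = (
            cache / f"{_cache_key(backend.backend_id, variant, text)}.json"
            if cache is not None else None
        )
        if cache_file is not None and cache_file.exists():
            raw = json.loads(cache_file.read_text())["raw"]
        else:
            prompt = render_prompt(variant, text)
            try:
                raw = backend(prompt)
            except Exception as exc:  # noqa: BLE001 — error isolation per note
                logger.warning("backend %s failed on note %s: %s",
                               backend.backend_id, note_id, exc)
                n_failures += 1
                records.append(
                    ExtractionRecord(note_id, NA, NA, NA, "", False, backend.backend_id)
                )
                continue
            if cache_file is not None:
                cache_file.write_text(json.dumps({"raw": raw}))
        records.append(
            parse_extraction_output(raw, lexicon, note_id=note_id,
                                    backend_id=backend.backend_id)
        )
    if n_failures:
        logger.warning("extraction finished with %d backend failures", n_failures)
    return records


def write_records(records: Iterable[ExtractionRecord], path: str | Path) -> None:
    """Write records as JSON-lines with the fixed seven-key schema."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec)) + "\n")


def read_records(path: str | Path) -> list[ExtractionRecord]:
    records = []
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                records.append(ExtractionRecord(**json.loads(line)))
    return records
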