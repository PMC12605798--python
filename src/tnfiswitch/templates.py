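"""Note template library shared by the synthetic generator and the
rule-based reference extractor.

The generator writes notes only from these templates, and the reference
extractor detects switches and reasons only through them, so on noise-free
synthetic notes the extractor recovers the planted fields exactly.  Two
conventions make that possible:

* in every switch sentence the stopped drug is mentioned before the started
  drug, and distractor sentences never mention a TNFi, so the order of first
  appearance of distinct canonical drugs identifies (stopped, started);
* each switching-reason category has a bank of fixed phrases that appear in a
  note iff that reason is documented, and no phrase of one bank is a
  substring of another bank's phrase.
"""

from __future__ import annotations

#: Switch sentences; {last} is always verbalized before {new}.
SWITCH_TEMPLATES: tuple[str, ...] = (
    "Plan to stop {last} and start {new} at today's visit.",
    "We will discontinue {last}; the patient will be started on {new}.",
    "Switching from {last} to {new} as discussed with the patient.",
    "{last} was stopped. {new} was prescribed today.",
)

#: Continuation sentences for non-switch (maintenance) encounters.
MAINTENANCE_TEMPLATES: tuple[str, ...] = (
    "The patient continues {drug} with stable disease activity.",
    "Continue {drug} at the current dose; tolerating well.",
    "No change to therapy today; remains on {drug}.",
)

#: Reason phrase banks (>= 3 paraphrases per category).  The drug-resistance
#: bank uses anti-drug-antibody language, per the clinical definition of
#: resistance to a biologic.
REASON_PHRASES: dict[str, tuple[str, ...]] = {
    "adverse_event": (
        "after developing a rash attributed to the medication",
        "due to recurrent injection site reactions",
        "because of side effects including recurrent infections",
    ),
    "drug_resistance": (
        "as anti-drug antibodies were detected on recent labs",
        "given documented anti-drug antibody formation",
        "because high-titer antidrug antibody levels indicate immunogenicity",
    ),
    "insurance_cost": (
        "because insurance no longer covers this agent",
        "following a change in insurance coverage",
        "as the out-of-pocket cost was prohibitive",
        "after prior authorization was denied",
    ),
    "lack_of_efficacy": (
        "due to inadequate disease control despite dose optimization",
        "because of persistent symptoms indicating primary non-response",
        "given ongoing flares consistent with loss of efficacy",
    ),
    "patient_preference": (
        "as the patient prefers a different injection schedule",
        "at the patient's request for a change in therapy",
        "because the patient prefers an alternative administration route",
    ),
    "other": (
        "in the context of an upcoming elective surgery",
        "in the setting of planned pregnancy",
        "for reasons reviewed in detail at a prior visit",
    ),
}

#: Frame for embedding a reason phrase in a switch note.
REASON_SENTENCE = "The change is being made {phrase}."

#: Distractor sentences: vitals, labs and non-TNFi medications only.
DISTRACTOR_SENTENCES: tuple[str, ...] = (
    "Vitals: BP 118/76, HR 72, afebrile.",
    "Labs reviewed: CBC and CMP within normal limits.",
    "Continues lisinopril 10 mg daily for hypertension.",
    "Metformin 500 mg twice daily refilled.",
    "Vitamin D supplementation discussed.",
    "ESR and CRP trending down from prior visit.",
    "Follow-up in 3 months with repeat labs.",
    "Patient counseled on medication adherence.",
)


def _validate_banks() -> None:
    flat = [(cat, p.lower()) for cat, bank in REASON_PHRASES.items() for p in bank]
    for cat_a, a in flat:
        for cat_b, b in flat:
            if a != b and a in b:
                raise AssertionError(
                    f"reason phrase collision: {a!r} ({cat_a}) inside {b!r} ({cat_b})"
                )


_validate_banks()
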