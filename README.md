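# tnfiswitch

Pipelines for studying **switching between tumor necrosis factor inhibitors
(TNFi)** — adalimumab, etanercept, certolizumab, golimumab, infliximab and
its biosimilars — in longitudinal EHR data, and for **benchmarking
structured extraction of switch events and switching reasons from clinical
notes**.

It is aimed at clinical-NLP and pharmacoepidemiology researchers who need a
tested, offline-reproducible harness for three things:

1. **Cohort construction.** Free-text drug names are normalized to six
   canonical TNFi categories (the infliximab bio-originator and biosimilars
   are distinct); orders are deduplicated on (patient, date, drug); orders
   at note-less encounters and at encounters with ≥ 2 distinct TNFi on the
   same date are excluded; each surviving encounter is linked to its last
   (max-timestamp) note. A **switch** is a change in canonical TNFi between
   two consecutive TNFi-order encounters of one patient. Non-switchers with
   no encounter at least six months (183 days) after their last TNFi order
   are classified lost to follow-up. Every stage logs
   `(in, removed, out)` to an attrition log whose chaining is checked.

2. **Extraction.** Four zero-shot prompt variants around a fixed four-key
   JSON schema (`new_TNFi`, `last_TNFi`, `Reason for Switching`,
   `full_reason_last_TNFi_stopped`) with a closed seven-value reason
   taxonomy (adverse event, drug resistance — i.e. anti-drug antibodies,
   insurance/cost, lack of efficacy, patient preference, other, NA). Any
   callable `backend(prompt) -> text` can be plugged in; a total parser
   normalizes arbitrary responses into records. Two offline backends ship:
   a deterministic rule-based reference extractor and a seeded noisy
   wrapper with per-field corruption rates.

3. **Evaluation.** Silver labels (stopped/started drug derived from the
   structured orders) and gold labels (annotations); micro-F1 pooled over
   the substantive classes under two null policies — score everything
   (`all_values`, an NA prediction forfeits recall) or first drop notes
   whose record reports no reason (`null_dropped`); pairwise
   win/loss/tie rates between backends with per-model mean win rate ± SD
   across opponents and win-minus-loss against a baseline; and truth-free
   per-field concordance between backends.

Because real de-identified EHR data cannot be redistributed, the package
includes a **synthetic-data generator** that emits all input tables with
planted ground truth (switch events, reasons, injected duplicates,
multi-TNFi encounters, note-less encounters, loss to follow-up), so every
pipeline stage is testable offline. See `docs/methods.md` for the model,
parameter defaults and their provenance, and known limitations.

## Worked example

```python
import tnfiswitch as tw
from tnfiswitch.synthetic import GeneratorConfig, generate_cohort
from tnfiswitch.extraction import ReferenceBackend, NoisyBackend, run_extraction
from tnfiswitch.evaluation import LabelSet, derive_silver_labels, evaluate_suite

data = generate_cohort(GeneratorConfig(n_patients=500, seed=42))
cohort = tw.build_cohort(data.orders, data.encounters, data.notes, data.demographics)
print(cohort.attrition.to_frame().to_string(index=False))
```

```
                     stage  n_in  n_removed  n_out
      normalize_drug_names  2774          0   2774
 drop_missing_demographics  2774          4   2770
        deduplicate_orders  2770        618   2152
 drop_orders_without_notes  2152        115   2037
drop_multi_tnfi_encounters  2037         66   1971
```

The 2774 raw orders shrink to 1971: 618 duplicates, 115 orders at
encounters without a note and 66 orders (33 encounters × 2) with two TNFi
on the same date are removed — exactly the counts the generator planted.
The 499 patients with demographics split into 94 switchers, 292 followed
non-switchers and 113 lost to follow-up, and the switch-count bands
(count, % of switchers, % of followed cohort) come from
`tw.tabulate_demographics(cohort, data.demographics).switch_bands`:

```
band  count  pct_of_switchers  pct_of_total
   0    292               NaN          75.6
   1     73              77.7          18.9
   2     16              17.0           4.1
  >2      5               5.3           1.3
```

Benchmarking the reference extractor against a 30 %-corrupted copy of
itself on the gold-labeled switch notes:

```python
gold = LabelSet("gold", data.gold.set_index("note_id"))
notes = data.notes[data.notes.note_id.isin(set(gold.note_ids))][["note_id", "text"]]
records = {
    "reference": run_extraction(notes, ReferenceBackend()),
    "noisy30": run_extraction(notes, NoisyBackend(0.30, seed=1, backend_id="noisy30")),
}
report = evaluate_suite(records, derive_silver_labels(cohort.switches), gold, "reference")
```

yields micro-F1 = 1.0 on every field for the reference backend (the note
templates and extraction rules are co-designed, so noise-free extraction is
exact), while the corrupted backend scores 0.67–0.78 depending on field and
null policy; its mean win rate against the reference is 0.0 vs 0.49
(win-minus-loss −0.49), and its concordance with the reference is 78.7 %
(SD 1.8 % across the three fields).

The same pipeline is scriptable from the shell:

```bash
tnfiswitch generate --out data --n-patients 500 --seed 42
tnfiswitch build-cohort --orders data/orders.csv --encounters data/encounters.csv \
    --notes data/notes.csv --demographics data/demographics.csv --out cohort
tnfiswitch extract --notes notes.csv --backend reference --out records.jsonl
tnfiswitch evaluate --records records.jsonl --cohort-dir cohort \
    --gold data/gold_labels.csv --out report.json
tnfiswitch report --cohort-dir cohort --records records.jsonl --out traj --plots
```

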