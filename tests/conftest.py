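import pytest

import tnfiswitch as tw
from tnfiswitch.evaluation import LabelSet
from tnfiswitch.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def lexicon():
    return tw.default_lexicon()


@pytest.fixture(scope="session")
def synth():
    """Moderate synthetic cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def cohort(synth):
    return tw.build_cohort(
        synth.orders, synth.encounters, synth.notes, synth.demographics
    )


@pytest.fixture(scope="session")
def gold_labels(synth):
    return LabelSet("gold", synth.gold.set_index("note_id"))


@pytest.fixture(scope="session")
def switch_notes(synth, gold_labels):
    """The (note_id, text) frame for all gold-labeled switch notes."""
    mask = synth.notes["note_id"].isin(set(gold_labels.note_ids))
    return synth.notes.loc[mask, ["note_id", "text"]].reset_index(drop=True)
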