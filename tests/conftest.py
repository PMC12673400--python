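"""Shared fixtures: small trained models and synthetic corpora.

The session-scoped models use scaled-down widths and epoch counts so the
whole suite runs on one CPU in a few minutes; they are trained once and
reused by model, generator and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from pepfunnel.model import BiLSTMNextResidue
from pepfunnel.seqio import windows_from_records
from pepfunnel.synthetic import MotifCorpusSpec, deterministic_successor_corpus, motif_corpus

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def successor_data():
    """Corpus following a planted one-to-one successor map, plus windows."""
    records, succ = deterministic_successor_corpus(rng_seed=1, n=16, length=60)
    X, y = windows_from_records(records)
    return {"records": records, "succ": succ, "X": X, "y": y}


@pytest.fixture(scope="session")
def successor_model(successor_data):
    """Model trained to memorise the deterministic successor rule."""
    model = BiLSTMNextResidue(
        recurrent_units=24, dense_units=32, epochs_base=60, batch_base=30, rng_seed=0
    )
    model.fit(successor_data["X"], successor_data["y"])
    return model


@pytest.fixture(scope="session")
def motif_setup():
    """Small motif corpus (base + fine-tune) with a densely planted KLVFF."""
    spec = MotifCorpusSpec(
        n_base=4,
        base_len_range=(120, 200),
        n_finetune=6,
        finetune_len_range=(40, 100),
        motif="KLVFF",
        motif_rate=10.0,
        rng_seed=7,
    )
    base, finetune = motif_corpus(spec)
    return {"spec": spec, "base": base, "finetune": finetune}


@pytest.fixture(scope="session")
def motif_model(motif_setup):
    """Two-phase-trained model on the motif corpus."""
    Xb, yb = windows_from_records(motif_setup["base"])
    Xf, yf = windows_from_records(motif_setup["finetune"])
    model = BiLSTMNextResidue(
        recurrent_units=24,
        dense_units=32,
        epochs_base=25,
        epochs_finetune=10,
        batch_base=30,
        batch_finetune=62,
        rng_seed=0,
    )
    model.fit(Xb, yb)
    model.fine_tune(Xf, yf)
    return model


@pytest.fixture(scope="session")
def random_pool():
    """1000 random peptides of length 80..100 shaped like a generated pool."""
    from pepfunnel.alphabet import decode
    from pepfunnel.seqio import ProteinRecord

    rng = np.random.default_rng(123)
    return [
        ProteinRecord(
            id=f"GEN_{i + 1:04d}",
            sequence=decode(rng.integers(0, 20, size=int(rng.integers(80, 101)))),
            role="generated",
        )
        for i in range(1000)
    ]
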