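"""The package's desk-scale study configuration.

The full-scale workflow (hundreds of thousands of training molecules, a
3-layer 512-unit LSTM, 100 million samples) is far beyond a workstation;
this module pins the single scaled-down configuration used by the test
suite and the reproduction script: 2,000 fixture molecules, a 2-layer
64-unit LSTM trained on their canonical SMILES with early stopping, and
5,000 sampled strings.  Keeping it in one place guarantees the tests and
the reproduction script measure the same conditions.
"""

from __future__ import annotations

from .langmodel import LMConfig

N_FIXTURE_MOLECULES = 2000
N_SAMPLES = 5000
FIXTURE_SEED = 11


def desk_lm_config(seed: int = 7) -> LMConfig:
    return LMConfig(
        n_layers=2,
        hidden_dim=64,
        embedding_dim=64,
        batch_size=128,
        learning_rate=0.001,
        max_epochs=700,
        patience_minibatches=1500,
        eval_every_minibatches=250,
        max_sample_length=250,
        seed=seed,
    )
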