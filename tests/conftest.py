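"""Shared fixtures.

The expensive end-to-end computations (the temporal-scenario method
contrast and the learning-rate sweep) are session-scoped so every test that
asserts on them shares one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import eegverb as ev
import eegverb.dual_lstm as dl

SEED = 7


@pytest.fixture(scope="session")
def small_design() -> ev.ExperimentDesign:
    """2 subjects x 6 verbs x 10 trials — fast synthesis for unit tests."""
    return ev.ExperimentDesign(n_subjects=2, trials_per_class=10,
                               blocks=2, reps_per_block=5)


@pytest.fixture(scope="session")
def contrast_design() -> ev.ExperimentDesign:
    """6 subjects x 6 verbs x 20 trials — the scaled method-contrast design."""
    return ev.ExperimentDesign(n_subjects=6, trials_per_class=20,
                               blocks=2, reps_per_block=10)


@pytest.fixture(scope="session")
def spatial_ts(small_design) -> ev.TrialSet:
    sigs = ev.make_spatial_scenario(3.0, SEED,
                                    n_task_samples=small_design.n_task_samples)
    return ev.generate_dataset(small_design, sigs, ev.NoiseModel(), SEED,
                               dtype=np.float32)


@pytest.fixture(scope="session")
def temporal_ts(contrast_design) -> ev.TrialSet:
    sigs = ev.make_temporal_scenario(SEED,
                                     n_task_samples=contrast_design.n_task_samples)
    return ev.generate_dataset(contrast_design, sigs, ev.NoiseModel(), SEED,
                               dtype=np.float32)


@pytest.fixture(scope="session")
def temporal_contrast(temporal_ts):
    """Both decoders on the covariance-matched (temporal) scenario.

    The scenario carries no class information in the channel covariances,
    only in the envelope ordering: the static-spatial-filter baseline should
    sit at chance while the recurrent decoder separates the classes.
    """
    tr, te = ev.split_trials(temporal_ts, 2.0 / 3.0, SEED)
    csp = ev.CspSvmDecoder().fit(tr, seed=SEED)
    csp_acc = float((csp.predict(te) == te.labels).mean())

    cfg = ev.TrainConfig(lr_mode="line_search", batch_size=96,
                         max_epochs=14, seed=SEED)
    lstm = ev.LstmDecoder(config=cfg).fit(tr, seed=SEED)
    lstm_acc = float((lstm.predict(te) == te.labels).mean())
    return {"csp_acc": csp_acc, "lstm_acc": lstm_acc, "n_test": len(te)}


@pytest.fixture(scope="session")
def spatial_contrast(contrast_design):
    """CSP-SVM on the spatially separable scenario at high separation."""
    sigs = ev.make_spatial_scenario(3.0, SEED,
                                    n_task_samples=contrast_design.n_task_samples)
    ts = ev.generate_dataset(contrast_design, sigs, ev.NoiseModel(), SEED,
                             dtype=np.float32)
    tr, te = ev.split_trials(ts, 2.0 / 3.0, SEED)
    csp = ev.CspSvmDecoder().fit(tr, seed=SEED)
    return {"csp_acc": float((csp.predict(te) == te.labels).mean()),
            "n_test": len(te)}


@pytest.fixture(scope="session")
def lr_sweep():
    """Fixed-rate learning-rate sweep of the recurrent decoder.

    2 subjects x 6 x 20 trials from the temporal scenario; every rate shares
    the split, initialisation seed, batch size and epoch budget.
    """
    design = ev.ExperimentDesign(n_subjects=2, trials_per_class=20,
                                 blocks=2, reps_per_block=10)
    sigs = ev.make_temporal_scenario(SEED, n_task_samples=design.n_task_samples)
    ts = ev.generate_dataset(design, sigs, ev.NoiseModel(), SEED,
                             dtype=np.float32)

    def factory(lr):
        return ev.LstmDecoder(config=ev.TrainConfig(
            learning_rate=float(lr), batch_size=2, max_epochs=120, seed=SEED))

    return ev.lr_curve(ts, [0.0005, 0.005, 0.05], seed=SEED,
                       decoder_factory=factory)
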