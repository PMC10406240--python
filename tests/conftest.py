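import numpy as np
import pytest

import eegalign as ea

ALPHA = ea.BandSpec("alpha", 7.0, 13.0)


@pytest.fixture(scope="session")
def alpha_band():
    return ALPHA


@pytest.fixture(scope="session")
def planted_3comm():
    """3 communities of 10 channels, strong within / weak between weights."""
    labels = [i // 10 for i in range(30)]
    W = ea.planted_connectivity(30, labels, 0.8, 0.1, 0.05, seed=11)
    return W, np.asarray(labels)


@pytest.fixture(scope="session")
def delayed_pair_epochs():
    """Two sensors: one source and its quarter-cycle (25 ms) delayed copy at 10 Hz.

    fs = 400 Hz makes the 25 ms lag an exact 10-sample delay (lags are
    quantised to whole samples by the simulator).
    """
    lay = ea.SensorLayout(["a", "b"], [[0, 0, 0], [1000, 0, 0]])
    src = ea.SourceModel(
        2, (10.0, 10.0), ((0, 1, 25.0, 1.0),), amplitude=1.0, noise_sd=0.05
    )
    mix = ea.MixingModel(lay, np.array([[0, 0, 0], [1000, 0, 0]], float), spread_mm=10.0)
    return ea.simulate_epochs(src, mix, n_trials=100, trial_s=2.0, fs=400.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort_matrices():
    """Alpha iCOH matrices for a 10-subject control-like cohort, 32 channels."""
    src, mix = ea.coupled_oscillator_setup(32, (10.0,))
    spec = ea.CohortSpec(10, "control_like", 1.0, 0.05, seed=1)
    cohort = ea.generate_cohort(spec, src, mix, n_trials=40, trial_s=2.0, fs=128.0)
    conn = ea.SpectralConnectivity("icoh", bands=[ALPHA])
    return [conn.transform(e)["alpha"] for e in cohort]


def brute_force_alignment(W: np.ndarray, eig_indices=(2, 3, 4)) -> np.ndarray:
    """Independent reference EA: full eigendecomposition + explicit arccos loops."""
    vals, vecs = np.linalg.eigh(W)
    order = np.argsort(vals)[::-1]
    coords = np.column_stack([vecs[:, order[r - 1]] for r in eig_indices])
    n = W.shape[0]
    theta = np.zeros((n, n))  # self-angle is 0 by definition
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ri, rj = coords[i], coords[j]
            c = float(np.dot(ri, rj) / (np.linalg.norm(ri) * np.linalg.norm(rj)))
            theta[i, j] = np.degrees(np.arccos(min(1.0, max(-1.0, c))))
    return theta
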