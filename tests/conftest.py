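"""Shared fixtures: small pulse constructors and session-scoped simulated
data sets (simulation + feature extraction amortised across tests)."""

import numpy as np
import pandas as pd
import pytest

from pulsegerm import (
    AcquisitionSettings,
    PulseShape,
    extract_features,
    simulate_particle,
)
from pulsegerm.simulate import SimConfig


def make_pulse(samples, spacing=1.0, baseline=0.0):
    return PulseShape(np.asarray(samples, dtype=float),
                      sample_spacing=spacing, baseline=baseline)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture
def rect_pulse():
    """Rectangle of height 2 AU occupying indices 3..12 of 20, 1 μm spacing."""
    samples = np.zeros(20)
    samples[3:13] = 2.0
    return make_pulse(samples)


def simulate_labelled_features(
    config, seed, n_non=400, n_germ=400, n_inter=60, n_hypha=0,
    times=(25.0,),
):
    """Labelled feature table with artifact variants at configured rates.

    Sampling times are drawn per particle from ``times`` (a training set
    pooled over process time sees both small and swollen round spores).
    Hyphal outgrowths, when requested, carry the truth label
    ``germinated`` — they are germinated spores grown out.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls, label, n in (
        ("non_germinated", "non_germinated", n_non),
        ("germinated", "germinated", n_germ),
        ("germinating", "germinating", n_inter),
        ("hypha_unbranched", "germinated", n_hypha),
    ):
        for i in range(n):
            variant = None
            if cls == "germinated" and rng.random() < config.upright_fraction:
                variant = "upright"
            elif (
                cls == "non_germinated"
                and rng.random() < config.debris_attachment_fraction
            ):
                variant = "attached_debris"
            record = simulate_particle(
                cls, config, rng, time_h=float(rng.choice(times)),
                variant=variant, particle_id=i,
            )
            fv = extract_features(record, config.acquisition)
            row = fv.__dict__.copy()
            row["truth_label"] = label
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def labelled_features(sim_config):
    """Session-scoped mid-germination labelled feature table (860 rows)."""
    return simulate_labelled_features(sim_config, seed=1234)


@pytest.fixture(scope="session")
def default_calibration():
    from pulsegerm import default_gateset

    return default_gateset(seed=7)
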