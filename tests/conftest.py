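import warnings

import numpy as np
import pandas as pd
import pytest

import sparpaf as sp

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*zero-variance.*")


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free, wander-free record: ideal beats at 36 bpm, 180 s, 500 Hz."""
    spec = sp.CohortSpec(
        n_control=1,
        n_paf=0,
        record_len=180,
        wander_amp=0.0,
        hf_noise_snr=np.inf,
        artefact_rate_per_hour=0.0,
        rr_jitter_cv=0.02,
        seed=3,
    )
    tpl = sp.make_beat_template(polarity=1, delta=0.0, seed=3)
    return sp.generate_record(tpl, spec, "control", seed=3, subject_id="clean")


@pytest.fixture(scope="session")
def clean_substrip(clean_record):
    subs, excl = sp.preprocess_signal(clean_record)
    assert not excl
    return subs[0]


@pytest.fixture(scope="session")
def default_substrip():
    """One sub-strip under the default (noisy) study conditions."""
    spec = sp.CohortSpec(n_control=1, n_paf=0, record_len=180, seed=5)
    rec = sp.generate_cohort(spec)[0]
    subs, _ = sp.preprocess_signal(rec)
    return subs[0]


def make_gaussian_table(
    n_control=16, n_paf=4, n_features=4, effect=1.0, seed=0
) -> pd.DataFrame:
    """Synthetic per-sub-strip feature table with a class mean shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_control + n_paf):
        label = "paf" if si < n_paf else "control"
        mu = effect if label == "paf" else 0.0
        for k in range(9):
            row = {
                "subject_id": f"s{si:03d}",
                "strip_index": k // 3,
                "sub_index": k % 3,
                "label": label,
                "n_quality_flags": 0,
            }
            for f in range(n_features):
                row[f"g{f}"] = rng.normal(mu, 1.0)
            rows.append(row)
    return pd.DataFrame(rows)
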