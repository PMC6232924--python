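import numpy as np
import pytest

from morphconn import SimSpec, cohort_features, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def strong_cohort():
    """Two well-separated diagnostic groups (group shift of 8 noise SDs)."""
    return generate_cohort(SimSpec(n_per_group=(30, 30), n_r=12, n_v=4,
                                   separation=8.0, noise_sd=1.0, seed=7))


@pytest.fixture(scope="session")
def strong_features(strong_cohort):
    X, _ = cohort_features(strong_cohort, order="low")
    return X, strong_cohort.labels


@pytest.fixture(scope="session")
def strong_features_hon(strong_cohort):
    X, _ = cohort_features(strong_cohort, order="high")
    return X, strong_cohort.labels


@pytest.fixture
def long_csv(tmp_path):
    """Tiny hand-written long-format cohort: 2 subjects x 3 ROIs x 2 attributes."""
    rows = ["subject_id,hemisphere,label,roi,attribute,value"]
    vals = {
        ("s1", "precentral", "thickness"): 2.5,
        ("s1", "precentral", "sulc"): 1.1,
        ("s1", "insula", "thickness"): 3.0,
        ("s1", "insula", "sulc"): 1.4,
        ("s1", "cuneus", "thickness"): 2.1,
        ("s1", "cuneus", "sulc"): 0.9,
        ("s2", "precentral", "thickness"): 2.6,
        ("s2", "precentral", "sulc"): 1.0,
        ("s2", "insula", "thickness"): 2.8,
        ("s2", "insula", "sulc"): 1.6,
        ("s2", "cuneus", "thickness"): 2.0,
        ("s2", "cuneus", "sulc"): 1.0,
    }
    for (sid, roi, attr), v in vals.items():
        label = "ASD" if sid == "s1" else "NC"
        rows.append(f"{sid},left,{label},{roi},{attr},{v}")
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join(rows) + "\n")
    return path, vals
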