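import numpy as np
import pytest
from hypothesis import settings

from glyco.cgm_data import SegmentSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def toy_segments(n: int = 10, seed: int = 0, scale: float = 0.01,
                 minority_fraction: float = 0.0) -> SegmentSet:
    """Random gap-free segments in model units; optionally a leading block
    of hypoglycemic (target < 80 mg/dL) segments."""
    rng = np.random.default_rng(seed)
    inputs = rng.uniform(80, 200, (n, 7)) * scale
    targets = rng.uniform(85, 200, n) * scale
    n_min = int(round(minority_fraction * n))
    targets[:n_min] = rng.uniform(45, 79, n_min) * scale
    return SegmentSet(inputs=inputs, targets=targets, horizon_minutes=30,
                      patient_ids=np.array([f"p{i % 3}" for i in range(n)],
                                           dtype=object),
                      start_indices=np.arange(n, dtype=np.int64), scale=scale)


@pytest.fixture
def segments10() -> SegmentSet:
    return toy_segments(10, seed=1)


@pytest.fixture
def imbalanced_segments() -> SegmentSet:
    from glyco.cgm_data import assign_labels
    return assign_labels(toy_segments(100, seed=2, minority_fraction=0.1),
                         scheme="binary")


@pytest.fixture(scope="session")
def tiny_cohort():
    """5 short synthetic patients, segmented and binary-labeled."""
    from glyco.cgm_data import assign_labels, make_segments, rescale, smooth
    from glyco.synthetic_cgm import SyntheticCohortConfig, simulate_cohort

    cfg = SyntheticCohortConfig(n_patients=5, duration_hours=10.0, seed=7)
    cohort = {}
    for series in simulate_cohort(cfg):
        segs = make_segments(rescale(smooth(series), 0.01), horizon_minutes=30)
        cohort[series.patient_id] = assign_labels(segs, scheme="binary")
    return cohort
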