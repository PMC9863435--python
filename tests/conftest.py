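import numpy as np
import pytest

from dermivivc.ivivc import IVIVCPoint

# Published summary of the metronidazole cream study: five product/run points
# (reference measured in both IVRT runs, with one observed AUC).
SUMMARY_POINTS = [
    ("reference", "run1", 37.80, 77.46),
    ("T1", "run1", 32.89, 77.62),
    ("reference", "run2", 38.47, 77.46),
    ("T2", "run2", 27.42, 60.98),
    ("T3", "run2", 51.20, 96.78),
]


@pytest.fixture
def summary_points() -> list[IVIVCPoint]:
    return [IVIVCPoint(product_id=p, run_label=r, arc=arc, auc=auc)
            for p, r, arc, auc in SUMMARY_POINTS]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
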