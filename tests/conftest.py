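import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dystroquant import AnalysisConfig
from dystroquant.simulate import generate_section, preset_params

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def packed_section():
    """One packed dystrophic-preset section with ground truth (seeded)."""
    params = preset_params("dmd_trace", seed=1)
    return generate_section(params)


@pytest.fixture(scope="session")
def packed_pipeline(packed_section, config):
    """Label map, split fibers and QC flags for the packed section."""
    from dystroquant import qc_filter, segment_fibers, split_touching_membranes

    image, truth = packed_section
    label_map = segment_fibers(image, config)
    fibers = split_touching_membranes(label_map, image.spectrin, config)
    fibers = qc_filter(fibers, image, config)
    return image, truth, label_map, fibers


def match_recall(truth, labels, min_jaccard: float = 0.5) -> float:
    """Fraction of interior ground-truth fibers recovered by the label map."""
    matched = 0
    n_interior = 0
    for k in range(1, truth.n_fibers + 1):
        if truth.touches_border[k - 1]:
            continue
        n_interior += 1
        gt = truth.cell_labels == k
        vals, counts = np.unique(labels[gt], return_counts=True)
        vals, counts = vals[vals > 0], counts[vals > 0]
        if len(vals) == 0:
            continue
        best = vals[np.argmax(counts)]
        pred = labels == best
        if (gt & pred).sum() / (gt | pred).sum() >= min_jaccard:
            matched += 1
    return matched / n_interior if n_interior else float("nan")
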