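import numpy as np
import pytest

from cilms import chem
from cilms import pairpick as pp
from cilms.align import align, identify, normalize_ratios, presence_filter
from cilms.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def csf_config():
    """Default study design, CSF arm only (biofluids are processed
    independently; one arm exercises every stage)."""
    return CohortConfig(seed=7, biofluids=("CSF",))


@pytest.fixture(scope="session")
def csf_cohort(csf_config):
    return generate_cohort(csf_config)


@pytest.fixture(scope="session")
def csf_pairs(csf_cohort):
    """Calibrated, filtered peak pairs per run of the CSF cohort."""
    anchors = chem.default_calibrant_mzs()
    out = {}
    for sid, flist in csf_cohort.feature_lists.items():
        model = pp.calibrate(flist, anchors)
        calibrated = pp.apply_calibration(flist, model)
        out[sid] = pp.pair_level_filter(pp.detect_pairs(calibrated))
    return out


@pytest.fixture(scope="session")
def csf_table_raw(csf_cohort, csf_pairs):
    """Aligned, presence-filtered, identified table of raw ratios.

    Truth-recovery checks run on raw ratios: per-sample median
    normalization corrects run-level drift, but when many features are
    genuinely perturbed in a sample it also absorbs part of the
    biological signal, so it is not used when scoring against the
    injected ground truth."""
    table = align(csf_pairs, samples=csf_cohort.samples)
    table = presence_filter(table)
    return identify(table, csf_cohort.library)


@pytest.fixture(scope="session")
def csf_table(csf_cohort, csf_table_raw):
    """Median-normalized variant of the aligned table."""
    return identify(normalize_ratios(csf_table_raw), csf_cohort.library)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def make_grade_table():
    """Factory for small severity-graded ratio tables (t1 only): grade
    means ordered A > B > C with tunable effect size (log2 units) and
    log-normal noise."""
    import pandas as pd
    from cilms.align import FeatureTable
    from cilms.meta import SampleMeta

    def build(effect=1.0, noise=0.3, seed=0, shuffle=False,
              n_per_grade=(10, 12, 8), n_features=8):
        rng = np.random.default_rng(seed)
        grades = [g for g, n in zip("ABC", n_per_grade) for _ in range(n)]
        shift = {"A": 2 * effect, "B": effect, "C": 0.0}
        mat = np.empty((n_features, len(grades)))
        for j, g in enumerate(grades):
            mat[:, j] = 2.0 ** (shift[g] + rng.normal(0, noise, n_features))
        if shuffle:  # decouple labels from the injected effects
            grades = list(rng.permutation(grades))
        samples = [SampleMeta(f"s{i:02d}", f"p{i:02d}", g, "t1", "CSF")
                   for i, g in enumerate(grades)]
        vals = pd.DataFrame(mat, columns=[s.sample_id for s in samples])
        feats = pd.DataFrame({
            "feature_id": [f"F{i:05d}" for i in range(n_features)],
            "consensus_mz": np.linspace(300, 700, n_features),
            "rt_sec": np.linspace(100, 1000, n_features),
            "n_tags": 1, "charge": 1, "identity": [None] * n_features})
        return FeatureTable(vals, feats, samples)

    return build
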