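import warnings

import numpy as np
import pytest

import methylsift as ms


@pytest.fixture(autouse=True)
def _silence_expected_warnings():
    # generators and degenerate fixtures intentionally trigger warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_config():
    return ms.SimulationConfig(
        n_probes=400,
        n_genes=40,
        n_pairs_per_disease=10,
        chip_size=12,
        qc_per_chip=2,
        n_planted=20,
        effect_delta=2.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    truth = ms.generate_truth(small_config)
    sheet = ms.generate_pairs_and_chips(small_config)
    clean = ms.generate_intensities(small_config, truth, sheet)
    biased = ms.inject_chip_bias(clean, truth)
    return truth, sheet, clean, biased


@pytest.fixture(scope="session")
def normalized(small_cohort):
    truth, sheet, clean, biased = small_cohort
    ds, qc, report = ms.normalize_dataset(biased)
    return ds, qc, report


@pytest.fixture(scope="session")
def toy_ontology():
    return ms.generate_ontology_corpus(50, seed=2)


def make_intensity_dataset(M, I, sheet, probes=None):
    """Compose channels realizing exactly the requested M and I."""
    M = np.asarray(M, dtype=float)
    I = np.asarray(I, dtype=float)
    probes = probes or [f"cg{i:06d}" for i in range(M.shape[0])]
    return ms.simulate.IntensityDataset(
        probes=probes,
        samples=sheet.sample_ids,
        meth=np.exp2(I + 0.5 * M),
        unmeth=np.exp2(I - 0.5 * M),
        sheet=sheet,
    )
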