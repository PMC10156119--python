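import warnings

import pytest

import sbaval as sv
from sbaval.pipeline import RunConfig, run_stages


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic experiment, shared across tests."""
    return sv.generate_dataset(sv.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def run_result(dataset):
    """Full pipeline result on the shared dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_stages(
            dataset.matrix,
            dataset.coupling,
            dataset.antibodies,
            dataset.samples,
            dataset.library,
            RunConfig(seed=1),
        )


@pytest.fixture
def tiny_panel():
    """Hand-built minimal panel: 2 constructs, 1 antibody, mock samples."""
    library = [
        sv.GPCRRecord("GPR_A", "rhodopsin_alpha", "ACDEFGHIKLMNPQRSTVWY" * 5),
        sv.GPCRRecord("GPR_B", "rhodopsin_alpha", "YWVTSRQPNMLKIHGFEDCA" * 5),
    ]
    antibodies = [
        sv.AntibodyRecord("AB1", 101, "GPR_A", "rhodopsin_alpha", 5, 30),
        sv.AntibodyRecord("CTRL_FLAG", 900, "anti-FLAG", "rhodopsin_alpha"),
    ]
    samples = []
    for g in ("GPR_A", "GPR_B"):
        for b in (1, 2, 3, 4):
            samples.append(sv.SampleRecord(f"{g}.b{b}", g, b, 1, "rhodopsin_alpha"))
    for b in (1, 2):
        samples.append(sv.SampleRecord(f"MOCK.b{b}", "MOCK", b, 1, "rhodopsin_alpha"))
    return library, antibodies, samples
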