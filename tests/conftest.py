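import numpy as np
import pytest

from noseprint import (
    CohortSpec,
    GaborBankParams,
    Template,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_bank() -> GaborBankParams:
    return GaborBankParams()


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(subjects=tuple((f"S{i:02d}", 2) for i in range(4)), master_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec, tmp_path_factory):
    """A tiny generated cohort on disk: 4 subjects x 2 captures."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(small_spec, out)
    return manifest


def random_template(
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (4, 8, 8),
    subject_id: str = "S",
    capture_index: int = 0,
    fingerprint: int = 0xABCD,
) -> Template:
    return Template(
        subject_id=subject_id,
        capture_index=capture_index,
        bits=rng.integers(0, 2, size=shape).astype(np.uint8),
        sample_stride=2,
        origin=(0, 0),
        bank_fingerprint=fingerprint,
    )
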