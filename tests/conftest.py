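import pandas as pd
import pytest

import compostvision as cv
from compostvision.synthetic import iter_study_images, study_group_assignment

# Study conditions for the full synthetic run: the real study's design
# (3 favorable + 7 unfavorable experiments, 32 images each) at half
# resolution in each dimension.
STUDY_SEED = 1
STUDY_HEIGHT = 324
STUDY_WIDTH = 484


@pytest.fixture(scope="session")
def study_features() -> pd.DataFrame:
    """Feature table of a full default synthetic study (320 images)."""
    rows = []
    for exp_id, source_id, img in iter_study_images(
        images_per_experiment=32,
        seed=STUDY_SEED,
        height=STUDY_HEIGHT,
        width=STUDY_WIDTH,
    ):
        row = {"experiment_id": exp_id, "source_id": source_id}
        row.update(cv.extract_features(img))
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study_groups() -> dict[str, str]:
    return study_group_assignment()
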