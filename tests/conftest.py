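import numpy as np
import pandas as pd
import pytest

from lymphofoci.synthetic import (TABLE1_PARAMS, GroundTruth, RenderParams,
                                  compose_nucleus_truths)


@pytest.fixture(scope="session")
def render_params() -> RenderParams:
    return RenderParams()


@pytest.fixture(scope="session")
def small_render_params() -> RenderParams:
    return RenderParams(image_shape=(256, 256))


def single_nucleus_truth(cls: str, diameters_um) -> GroundTruth:
    """Ground truth for one nucleus of a given class with given foci."""
    nuclei = pd.DataFrame({"nucleus_id": [1], "true_class": [cls],
                           "true_focus_count": [len(diameters_um)],
                           "region_label": ["unassigned"]})
    foci = pd.DataFrame({"nucleus_id": [1] * len(diameters_um),
                         "diameter_um": list(diameters_um)})
    if not len(diameters_um):
        foci = pd.DataFrame(columns=["nucleus_id", "diameter_um"])
    return GroundTruth(case_id="single", nuclei=nuclei, foci=foci)


@pytest.fixture(scope="session")
def scored_mcl_case(render_params):
    """A 300-nucleus MCL-like case (true abnormal fraction 50%) rendered in
    six fields and scored end to end; reused by recovery tests."""
    from lymphofoci.pipeline import score_synthetic_if_case

    dfs = []
    for k in range(6):
        truth = compose_nucleus_truths("mcl", TABLE1_PARAMS["MCL"], 50.0, 50,
                                       seed=11 + k)
        dfs.append(score_synthetic_if_case(truth, render_params,
                                           seed=42 + k, nuclei_per_field=50))
    return pd.concat(dfs, ignore_index=True)


@pytest.fixture(scope="session")
def rendered_field_with_truth():
    """A 12-nucleus mixed field and its rendered truth (session cache)."""
    from lymphofoci.segmentation import ImageField
    from lymphofoci.synthetic import render_if_image

    rp = RenderParams(image_shape=(448, 448))
    truth = compose_nucleus_truths("mix", TABLE1_PARAMS["MCL"], 50.0, 12,
                                   seed=5)
    channels, rendered = render_if_image(truth, rp, seed=9)
    field = ImageField(channels, rp.pixel_size, "mix_f0")
    return field, rendered
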