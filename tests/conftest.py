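"""Shared fixtures: phantoms and a trained saliency model, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ttcseg import (
    PhantomSpec,
    extract_brains,
    make_compound_phantom,
    train_synthetic_model,
)


@pytest.fixture(scope="session")
def saliency_model():
    """Saliency classifier trained on 20 synthetic compound phantoms."""
    return train_synthetic_model(n_images=20, seed=7)


@pytest.fixture(scope="session")
def compound_run(saliency_model):
    """One held-out compound phantom pushed through the extraction pipeline."""
    img, truth = make_compound_phantom(PhantomSpec(seed=101))
    result = extract_brains(img, saliency_model)
    return img, truth, result


@pytest.fixture(scope="session")
def small_spec():
    """A compact two-slice phantom spec for fast pipeline-level tests."""
    return PhantomSpec(image_size=(240, 320), n_slices=2, seed=11)


def slice_mask_in_frame(sl, shape):
    """Paste an extracted BrainSlice mask back into compound-image coordinates."""
    full = np.zeros(shape, dtype=bool)
    r0, c0 = sl.offset
    h, w = sl.mask.shape
    rr = slice(max(r0, 0), min(r0 + h, shape[0]))
    cc = slice(max(c0, 0), min(c0 + w, shape[1]))
    full[rr, cc] = sl.mask[rr.start - r0 : rr.stop - r0, cc.start - c0 : cc.stop - c0]
    return full


@pytest.fixture(scope="session")
def extraction_suite(saliency_model):
    """Twenty seeded compound phantoms run end-to-end through extraction."""
    runs = []
    for seed in range(300, 320):
        img, truth = make_compound_phantom(PhantomSpec(seed=seed))
        result = extract_brains(img, saliency_model)
        runs.append((img, truth, result))
    return runs
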