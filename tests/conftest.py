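"""Shared fixtures: all synthetic, generated at session start.

The expensive full-scale reconstruction (5-region phantom, perturbed
sections, alignment, volume build) is computed once per session and
shared between the pipeline-level tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from histoatlas.pipeline import align_dataset, build_volume_from_dataset
from histoatlas.synthetic import make_phantom, slice_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """3-region 64³ phantom for cheap unit tests."""
    return make_phantom(n_regions=3, shape=(64, 64, 64), spacing=10.0, seed=3)


@pytest.fixture(scope="session")
def blob_phantom():
    """5-region 96³ phantom (3 shells + 2 blob nuclei)."""
    return make_phantom(n_regions=5, shape=(96, 96, 96), spacing=10.0, seed=2)


@pytest.fixture(scope="session")
def full_phantom():
    """5-region 128³ phantom at 10 µm — the study-scale specimen."""
    return make_phantom(n_regions=5, shape=(128, 128, 128), spacing=10.0, seed=1)


@pytest.fixture(scope="session")
def full_dataset(full_phantom):
    """Study-scale sectioning: 100 µm interval, ±7° / ±12 px perturbations."""
    return slice_phantom(full_phantom, slice_spacing=100.0, seed=2)


@pytest.fixture(scope="session")
def full_alignments(full_dataset):
    return align_dataset(full_dataset)


@pytest.fixture(scope="session")
def full_build(full_dataset, full_alignments):
    return build_volume_from_dataset(full_dataset, alignments=full_alignments)
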