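"""Shared fixtures: tiny grids, batches and the bundled study tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exocnv.fixtures import (
    cohort_records,
    known_regions_frame,
    table1_calls,
    table1_frame,
    toy_annotation_tables,
    toy_grid,
)
from exocnv.io_formats import CountMatrix, TargetGrid


@pytest.fixture(scope="session")
def study_tables():
    return toy_annotation_tables()


@pytest.fixture(scope="session")
def study_grid():
    return toy_grid()


@pytest.fixture(scope="session")
def study_calls(study_grid):
    return table1_calls(study_grid)


@pytest.fixture(scope="session")
def study_cnvs():
    return table1_frame()


@pytest.fixture(scope="session")
def known_regions():
    return known_regions_frame()


@pytest.fixture(scope="session")
def cohort():
    return cohort_records()


@pytest.fixture(scope="session")
def outdir(tmp_path_factory):
    """All bundled tables written to disk once per session."""
    from exocnv.fixtures import make_paper_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    make_paper_fixtures(out)
    return out


@pytest.fixture
def small_grid():
    """Ten 100-bp targets on one chromosome, two genes of five exons."""
    starts = np.arange(10) * 1000
    return TargetGrid(pd.DataFrame({
        "chrom": "1",
        "start": starts,
        "end": starts + 100,
        "gene": ["GENEA"] * 5 + ["GENEB"] * 5,
        "exon_index": list(range(1, 6)) * 2,
    }))


def make_call(first=2, last=4, copy_number=1, chrom="1", sample="S0",
              start=None, end=None, mean_ratio=None, quality=10.0,
              mosaic_fraction=None):
    from exocnv.depth_model import CnvCall

    if start is None:
        start = first * 1000
    if end is None:
        end = last * 1000 + 100
    if mean_ratio is None:
        mean_ratio = {0: 0.02, 1: 0.5, 3: 1.5, 4: 2.0}[copy_number]
    return CnvCall(sample=sample, chrom=chrom, first_target=first,
                   last_target=last, start=start, end=end,
                   copy_number=copy_number, n_targets=last - first + 1,
                   mean_ratio=mean_ratio, quality=quality,
                   mosaic_fraction=mosaic_fraction)


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture
def uniform_batch():
    """Deterministic 4-sample batch of near-identical profiles."""
    rng = np.random.default_rng(11)
    base = rng.integers(150, 250, size=10)
    counts = np.vstack([base + rng.integers(-5, 6, size=10) for _ in range(4)])
    return CountMatrix([f"S{i}" for i in range(4)], counts,
                       override_batch_size=True)
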