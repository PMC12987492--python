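from __future__ import annotations

import numpy as np
import pytest

from tsscall.model import (FORWARD, REVERSE, CoverageTrack, LibraryPair)
from tsscall.params import ParameterSet
from tsscall.synthetic import example_spec, generate_experiment


def make_track(values, strand=FORWARD, replicon="c1") -> CoverageTrack:
    return CoverageTrack(replicon, strand, np.asarray(values, dtype=float))


def make_pair(enriched, control=None, strand=FORWARD, condition="A",
              replicate="r1", replicon="c1") -> LibraryPair:
    if control is None:
        control = np.zeros(len(enriched))
    return LibraryPair(condition, replicate, strand,
                       make_track(enriched, strand, replicon),
                       make_track(control, strand, replicon))


@pytest.fixture(scope="session")
def absolute_params() -> ParameterSet:
    """Thresholds in absolute coverage units (no percentile scaling)."""
    return ParameterSet(step_height=5.0, step_factor=2.0,
                        enrichment_factor=2.0, window=0,
                        height_reduction=2.0, factor_reduction=0.5)


@pytest.fixture(scope="session")
def disk_experiment(tmp_path_factory):
    """A noiseless 2-condition x 2-replicate experiment written to disk."""
    spec = example_spec(n_conditions=2, n_replicates=2, noise=0.0, seed=3)
    directory = tmp_path_factory.mktemp("experiment")
    layout, truth = generate_experiment(spec, directory)
    return spec, layout, directory
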