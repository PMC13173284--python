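from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from srnadisc import synth


@pytest.fixture(scope="session")
def small_design() -> synth.SyntheticDesign:
    return synth.SyntheticDesign(
        seed=42, n_samples_per_group=2, n_reads=200, n_mirnas=12,
        n_ncrna_per_class=1, n_cdna=2, genome_min_length=3000,
    )


@pytest.fixture(scope="session")
def small_repo(small_design) -> synth.SyntheticRepository:
    return synth.make_reference_repository(small_design)


@pytest.fixture(scope="session")
def small_experiment(small_design, tmp_path_factory):
    out = tmp_path_factory.mktemp("experiment")
    return synth.make_experiment(small_design, out)
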