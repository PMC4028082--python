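"""Shared fixtures: one synthetic genome + ChIP/control BAM pair per session."""

import pathlib

import pytest

from metaplot.simulate import FixtureSpec, synth_annotation, synth_reads


@pytest.fixture(scope="session")
def spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> pathlib.Path:
    return tmp_path_factory.mktemp("fixture")


@pytest.fixture(scope="session")
def store(spec, fixture_dir):
    return synth_annotation(spec, fixture_dir / "store")


@pytest.fixture(scope="session")
def store_path(store, fixture_dir) -> pathlib.Path:
    return fixture_dir / "store"


@pytest.fixture(scope="session")
def chip_bam(spec, store, fixture_dir):
    path, n = synth_reads(spec, store, fixture_dir / "chip.bam")
    return path, n


@pytest.fixture(scope="session")
def control_bam(spec, store, fixture_dir):
    path, n = synth_reads(spec, store, fixture_dir / "control.bam", control=True)
    return path, n
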