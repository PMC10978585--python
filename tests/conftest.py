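import pytest

from utrneo.cli import RunConfig, run_scan
from utrneo.fixtures import make_builtin_toy, make_random_reference
from utrneo.refmodel import load_reference


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    return make_builtin_toy(tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def toy_transcripts(toy_bundle):
    return load_reference(toy_bundle.genome, toy_bundle.gtf, genome_build="toy")


@pytest.fixture(scope="session")
def t1(toy_transcripts):
    return toy_transcripts["T1"]


@pytest.fixture(scope="session")
def toy_scan(toy_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_out")
    return run_scan(
        toy_bundle.vcf,
        toy_bundle.genome,
        toy_bundle.gtf,
        toy_bundle.proteome,
        out,
        RunConfig(genome_build="toy"),
        sample=toy_bundle.sample,
    )


@pytest.fixture(scope="session")
def random_bundle(tmp_path_factory):
    return make_random_reference(
        seed=20240915, outdir=tmp_path_factory.mktemp("rand"), n_transcripts=15
    )
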