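import pytest

from noncneo.fixtures import build_planted_run, write_run

#: Study conditions of the standard synthetic run: ten planted SNVs,
#: three non-PASS, two coding decoys, full MS recall.
RUN_SEED = 1


@pytest.fixture(scope="session")
def planted_run():
    return build_planted_run(RUN_SEED)


@pytest.fixture(scope="session")
def planted_run_dir(planted_run, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixrun")
    write_run(planted_run, outdir)
    return outdir


@pytest.fixture()
def toy_genome():
    # one contig, hand-written so window arithmetic is checkable by eye
    return {"ctg": "AAAAACAAAAA"}
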