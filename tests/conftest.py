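import pytest

from vdjml.fixtures import default_meta, make_canonical_fixture


@pytest.fixture(scope="session")
def canonical():
    """(igblast_text, expected_document) for the worked-example read."""
    return make_canonical_fixture()


@pytest.fixture()
def meta():
    return default_meta()


def convert_text(text):
    """Run the IgBLAST converter on fixture text with the fixture metadata."""
    from vdjml.igblast import convert

    m = default_meta()
    return convert(
        iter(text.splitlines(True)),
        aligner=m.aligners[0],
        db=m.germline_dbs[0],
        generator=m.generator,
    )
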