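import pytest

from navdiagram import (
    FixtureSpec,
    classify,
    default_style,
    layout,
    make_record,
    parse_flat_text,
)


@pytest.fixture(scope="session")
def canonical_record():
    """Flat text + ground-truth model of a canonical 4x6 Nav architecture."""
    return make_record(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def canonical_topology(canonical_record):
    text, _ = canonical_record
    return classify(parse_flat_text(text))


@pytest.fixture(scope="session")
def style():
    return default_style()


@pytest.fixture(scope="session")
def canonical_layout(canonical_topology, style):
    return layout(canonical_topology, style)
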