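import pytest

from drugrepo.synthetic import FixtureSpec, generate_fixture


def make_inchikey(i: int) -> str:
    """Deterministic shape-valid InChIKey for hand-built fixtures."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    body = "".join(letters[(i + k) % 26] for k in range(14))
    mid = "".join(letters[(i * 3 + k) % 26] for k in range(10))
    return f"{body}-{mid}-N"


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """One default synthetic dataset shared across the suite."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(seed=7), out)


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small TSV file with a header row; returns its path."""

    def _write(name, header, rows):
        path = tmp_path / name
        lines = ["\t".join(header)] + ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
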