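import pytest

from rbcskit.io_core import SequenceRecord


@pytest.fixture
def two_leaf_tree():
    from rbcskit.io_core import read_newick

    return read_newick("(a:0.3,b:0.3);")


def make_alignment(rows: dict[str, str]) -> list[SequenceRecord]:
    """Alignment fixture from id → aligned row."""
    return [SequenceRecord(id=k, sequence=v) for k, v in rows.items()]


@pytest.fixture
def grass_c3c4_alignment():
    """Protein alignment encoding the screened C3/C4 residue distributions.

    Column 2 plays the role of reference position 59: C in 3 of 6 C4
    species (the maize-like third), G in the remaining C4 and in all 10 C3
    species.  Column 4 plays position 83: Y in all 6 C4 species and in
    exactly one C3 species, L or I in every other C3 species.

    Returns (alignment, c4_species, c3_species).
    """
    rows = {}
    for i in range(1, 7):
        pos59 = "C" if i <= 3 else "G"
        rows[f"c4_{i}"] = f"M{pos59}AYD"
    for i in range(1, 11):
        pos83 = "Y" if i == 1 else ("L" if i % 2 else "I")
        rows[f"c3_{i}"] = f"MGA{pos83}D"
    return (
        make_alignment(rows),
        {f"c4_{i}" for i in range(1, 7)},
        {f"c3_{i}" for i in range(1, 11)},
    )
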