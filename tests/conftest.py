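import numpy as np
import pytest

from morphoclade.characters import CharacterMatrix


def make_matrix(columns, taxa=None, n_states=None):
    """Build a CharacterMatrix from per-character lists of state sets.

    Each column is a list (one entry per taxon) of ints, sets of ints, or
    None for missing.
    """
    n = len(columns[0])
    taxa = taxa or [f"t{i}" for i in range(n)]
    if n_states is None:
        n_states = 1 + max(
            (s if isinstance(s, int) else max(s))
            for col in columns for s in col if s is not None)
    full = (1 << n_states) - 1
    masks = np.empty((n, len(columns)), dtype=np.uint32)
    for j, col in enumerate(columns):
        for i, cell in enumerate(col):
            if cell is None:
                masks[i, j] = full
            elif isinstance(cell, int):
                masks[i, j] = 1 << cell
            else:
                masks[i, j] = sum(1 << s for s in cell)
    return CharacterMatrix(tuple(taxa), masks, n_states,
                           np.ones(len(columns)),
                           np.zeros(len(columns), dtype=bool),
                           tuple(range(1, len(columns) + 1)))


@pytest.fixture
def quartet_trees():
    """The three unrooted topologies on taxa 0..3 (AB|CD, AC|BD, AD|BC)."""
    return {
        "AB|CD": {0: [4], 1: [4], 4: [0, 1, 5], 5: [4, 2, 3], 2: [5], 3: [5]},
        "AC|BD": {0: [4], 2: [4], 4: [0, 2, 5], 5: [4, 1, 3], 1: [5], 3: [5]},
        "AD|BC": {0: [4], 3: [4], 4: [0, 3, 5], 5: [4, 1, 2], 1: [5], 2: [5]},
    }
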