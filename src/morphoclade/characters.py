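"""Discrete morphological character matrices.

Cells are state sets encoded as bitmasks over integer states 0-9:
a singleton bit for a scored state, several bits for a polymorphism, and
the full set for missing ('?') or inapplicable ('-') data.  NEXUS input
goes through dendropy; TNT ``xread`` and a plain CSV layout are parsed
directly.  Characters can be excluded by their original 1-based indices
(the mechanism behind "all characters except nnn" analyses).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np

__all__ = ["CharacterMatrix", "read_matrix"]


@dataclasses.dataclass(frozen=True)
class CharacterMatrix:
    taxa: tuple
    masks: np.ndarray          # (n, c) uint32 bitmasks
    n_states: int
    weights: np.ndarray        # (c,)
    ordered_flags: np.ndarray  # (c,) bool
    orig_indices: tuple        # 1-based indices into the source matrix

    def __post_init__(self):
        masks = np.asarray(self.masks, dtype=np.uint32)
        n, c = masks.shape
        if len(self.taxa) != n:
            raise ValueError("taxon count mismatch")
        if np.any(masks == 0):
            raise ValueError("empty state set in matrix")
        full = np.uint32((1 << self.n_states) - 1)
        if np.any(masks & ~full):
            raise ValueError("state exceeds alphabet size")
        if np.any(np.asarray(self.weights) <= 0):
            raise ValueError("weights must be positive")
        if np.all(masks == full, axis=1).any():
            raise ValueError("a taxon has no scored characters")
        object.__setattr__(self, "masks", masks)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "weights",
                           np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "ordered_flags",
                           np.asarray(self.ordered_flags, dtype=bool))
        object.__setattr__(self, "orig_indices", tuple(self.orig_indices))

    @property
    def n_taxa(self) -> int:
        return self.masks.shape[0]

    @property
    def n_characters(self) -> int:
        return self.masks.shape[1]

    @property
    def full_mask(self) -> int:
        return (1 << self.n_states) - 1

    def exclude(self, indices_1based) -> "CharacterMatrix":
        """Drop characters by original 1-based index; metadata keeps the
        surviving original indices."""
        drop = set(int(i) for i in indices_1based)
        keep = [k for k, oi in enumerate(self.orig_indices) if oi not in drop]
        if len(keep) == len(self.orig_indices):
            missing = drop - set(self.orig_indices)
            if missing == drop and drop:
                raise ValueError(f"indices not present: {sorted(drop)}")
        return CharacterMatrix(
            self.taxa, self.masks[:, keep], self.n_states,
            self.weights[keep], self.ordered_flags[keep],
            tuple(self.orig_indices[k] for k in keep))

    def is_missing(self) -> np.ndarray:
        return self.masks == np.uint32(self.full_mask)


def _matrix_from_cells(taxa, cells, n_states=None, orig_indices=None):
    """cells: list (per taxon) of lists of state-int-sets (None = missing)."""
    c = len(cells[0])
    if n_states is None:
        observed = {s for row in cells for cell in row if cell for s in cell}
        n_states = max(observed) + 1 if observed else 1
    full = (1 << n_states) - 1
    masks = np.empty((len(taxa), c), dtype=np.uint32)
    for i, row in enumerate(cells):
        if len(row) != c:
            raise ValueError(f"{taxa[i]}: character count mismatch")
        for j, cell in enumerate(row):
            masks[i, j] = full if not cell else sum(1 << s for s in set(cell))
    return CharacterMatrix(tuple(taxa), masks, n_states,
                           np.ones(c), np.zeros(c, dtype=bool),
                           orig_indices or tuple(range(1, c + 1)))


def _read_nexus(path) -> CharacterMatrix:
    import dendropy

    m = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    taxa, cells = [], []
    for tax in m:
        taxa.append(tax.label)
        row = []
        for st in m[tax]:
            if st.symbol in ("?", "-"):
                row.append(None)
            elif st.member_states:
                vals = [int(x.symbol) for x in st.member_states
                        if x.symbol not in ("?", "-")]
                row.append(set(vals) if vals else None)
            else:
                row.append({int(st.symbol)})
        cells.append(row)
    return _matrix_from_cells(taxa, cells)


_TNT_CELL = re.compile(r"\[([0-9]+)\]|\{([0-9]+)\}|\(([0-9]+)\)|([0-9?\-])")


def _parse_state_string(s: str):
    out = []
    for m in _TNT_CELL.finditer(s):
        grp = m.group(1) or m.group(2) or m.group(3)
        if grp is not None:
            out.append({int(ch) for ch in grp})
        elif m.group(4) in ("?", "-"):
            out.append(None)
        else:
            out.append({int(m.group(4))})
    return out


def _read_tnt(path) -> CharacterMatrix:
    text = Path(path).read_text()
    # strip quoted titles and locate the xread data block
    text = re.sub(r"'[^']*'", " ", text)
    m = re.search(r"xread\s+(\d+)\s+(\d+)(.*?);", text, re.S | re.I)
    if not m:
        raise ValueError("no xread block found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    taxa, cells = [], []
    for line in m.group(3).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        name, states = line.split(None, 1)
        row = _parse_state_string(states.replace(" ", ""))
        if len(row) != nchar:
            raise ValueError(f"{name}: expected {nchar} characters, "
                             f"got {len(row)}")
        taxa.append(name)
        cells.append(row)
    if len(taxa) != ntax:
        raise ValueError(f"expected {ntax} taxa, got {len(taxa)}")
    return _matrix_from_cells(taxa, cells)


def _read_csv(path) -> CharacterMatrix:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, index_col=0)
    taxa = [str(t) for t in df.index]

    def cell(v):
        v = str(v).strip().strip("{}()[]")
        if v in ("?", "-", "nan", ""):
            return None
        return {int(ch) for ch in v}

    cells = [[cell(v) for v in df.loc[t]] for t in df.index]
    return _matrix_from_cells(taxa, cells)


def read_matrix(path, format: str | None = None,
                exclude=()) -> CharacterMatrix:
    """Read a NEXUS, TNT xread, or CSV character matrix.

    ``exclude`` lists 1-based character indices to drop (applied after
    parsing, so indices refer to the published matrix).
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {"": "nexus", ".nex": "nexus", ".nexus": "nexus",
                  ".tnt": "tnt", ".ss": "tnt", ".csv": "csv"}.get(suffix)
        if format is None:
            head = Path(path).read_text()[:200].lower()
            format = "nexus" if "#nexus" in head else "tnt"
    reader = {"nexus": _read_nexus, "tnt": _read_tnt, "csv": _read_csv}
    if format not in reader:
        raise ValueError(f"unknown matrix format: {format}")
    mat = reader[format](path)
    if exclude:
        mat = mat.exclude(exclude)
    return mat
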