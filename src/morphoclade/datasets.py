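"""Bundled small datasets.

``humerus_lengths`` is a printed measurement table (hadrosaurid humeral
lengths in mm; the single estimated entry is flagged by the ``estimated``
column).  The lambeosaurine tree and area table are a transcription of a
published figure's topology and tip distributions — figure-derived, so
suitable only for qualitative checks, not as a numeric reference.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["humerus_lengths", "lambeosaurine_tree_newick",
           "lambeosaurine_areas"]


def _path(name: str):
    return resources.files("morphoclade.data").joinpath(name)


def humerus_lengths() -> pd.DataFrame:
    """Humeral lengths (mm) for a sample of hadrosaurid species."""
    with resources.as_file(_path("humerus_lengths_mm.csv")) as p:
        return pd.read_csv(p)


def lambeosaurine_tree_newick() -> str:
    """Figure-derived lambeosaurine topology (rooted newick)."""
    return _path("lambeosaurinae_fig_tree.nwk").read_text().strip()


def lambeosaurine_areas() -> dict:
    """Figure-derived four-area tip ranges (E, AS, NNA, SNA)."""
    from .biogeo import read_area_table
    with resources.as_file(_path("lambeosaurinae_areas.csv")) as p:
        return read_area_table(p)
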