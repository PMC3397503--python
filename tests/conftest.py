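"""Shared fixtures: small library specs and deterministic clone sets."""

import numpy as np
import pytest

from biasscan.library_model import (
    CHAIN_VH,
    CHAIN_VL_KAPPA,
    DegenerateCodon,
    LibrarySpec,
    OligoDesign,
    SubLibrarySpec,
)
from biasscan.repertoire_io import CloneRecord


def nnk_design(length: int) -> OligoDesign:
    return OligoDesign(tuple(DegenerateCodon("NNK") for _ in range(length)))


@pytest.fixture
def nnk_vh13() -> SubLibrarySpec:
    return SubLibrarySpec(chain=CHAIN_VH, length_class=13, weight=1.0, design=nnk_design(13))


@pytest.fixture
def small_library() -> LibrarySpec:
    """One VH length-13 and one VL length-9 sub-library, all NNK."""
    return LibrarySpec(
        sublibraries=[
            SubLibrarySpec(chain=CHAIN_VH, length_class=13, weight=1.0, design=nnk_design(13)),
            SubLibrarySpec(chain=CHAIN_VL_KAPPA, length_class=9, weight=1.0, design=nnk_design(9)),
        ],
        invariant_prefix="VR",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_clone(cid: str, vh: str = None, vl: str = None, fraction: str = "F1",
               rnd: int = 2) -> CloneRecord:
    return CloneRecord(clone_id=cid, fraction=fraction, round=rnd, vh_cdr3=vh, vl_cdr3=vl)
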