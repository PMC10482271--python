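import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from nterm_atlas import ProteinRecord, ProteomeSet
from nterm_atlas.annotations import GOAnnotationSet

#: residues used to encode digits into unique, valid sequence suffixes
_DIGIT_RESIDUES = "ACDEFGHIKL"


def encode_suffix(i: int, width: int = 8) -> str:
    """Deterministic unique residue string from an integer."""
    return "".join(_DIGIT_RESIDUES[int(d)] for d in f"{i:0{width}d}")


def make_protein(index: int, residue2: str, tail: str = "") -> ProteinRecord:
    """Protein with a chosen position-2 residue and a unique 10-prefix."""
    acc = f"P{index:04d}"
    return ProteinRecord(accession=acc,
                         sequence="M" + residue2 + encode_suffix(index) + tail)


@pytest.fixture
def toy_proteome() -> ProteomeSet:
    records = [
        ProteinRecord("P1", "MSTAAA"),
        ProteinRecord("P2", "MLRTPT"),
        ProteinRecord("P3", "MDELSQ"),
    ]
    return ProteomeSet(records)


def make_annotation_set(term_members: dict[str, set[str]],
                        domain: str = "component") -> GOAnnotationSet:
    ann = GOAnnotationSet(domain=domain)
    for term, members in term_members.items():
        ann.terms[term] = set(members)
    return ann
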