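"""Mitochondrial targeting sequence (MTS) analyses.

MTS-bearing precursors are imported through the presequence pathway: a
cleavable, arginine-rich amphipathic N-terminal helix.  The analyses here
profile the residue composition of that region (positions 1-20/30), the
residue-2 signature that defines potential N-terminal acetyltransferase
substrates, and the conservation of both across related species via
ortholog groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotations import OrthologGroups
from .bias import positional_hgt_matrix
from .proteome import ProteinRecord, ProteomeSet, position_profile

logger = logging.getLogger(__name__)

__all__ = [
    "NTERM_CLASSES", "NtermClass", "classify_nterm", "class_fractions",
    "mts_positional_bias", "mts_position2_table", "cross_species_mts_bias",
]

#: Residue-2 classes determined by the N-terminal processing machinery:
#: NatC acetylates retained iMet followed by a bulky hydrophobic residue;
#: MetAP cleaves iMet before small-gyration residues (exposing NatA
#: substrates); NatB acetylates retained iMet before acidic/amide residues.
NTERM_CLASSES: dict[str, frozenset[str]] = {
    "natc_type": frozenset("LFIW"),
    "metap_type": frozenset("ACGPSTV"),
    "natb_type": frozenset("DENQ"),
    "other": frozenset("HKMRY"),
}
_CLASS_OF: dict[str, str] = {aa: cls for cls, residues in
                             NTERM_CLASSES.items() for aa in residues}


@dataclass(frozen=True)
class NtermClass:
    """Processing class implied by a protein's residue at position 2."""

    residue2: str
    class_name: str
    imet_retained: bool


def classify_nterm(sequence: str) -> NtermClass:
    """Classify an N-terminus by its residue at position 2.

    iMet is retained unless position 2 carries a small-gyration (MetAP
    substrate) residue.  Ambiguity codes map to class ``"other"``.
    """
    if len(sequence) < 2:
        raise ValueError("sequence shorter than 2 residues has no position 2")
    aa = sequence[1]
    cls = _CLASS_OF.get(aa, "other")
    return NtermClass(residue2=aa, class_name=cls,
                      imet_retained=cls != "metap_type")


def class_fractions(proteins: Sequence[ProteinRecord]) -> pd.Series:
    """Fraction of proteins in each residue-2 class (length-1 proteins are
    skipped)."""
    counts = dict.fromkeys(NTERM_CLASSES, 0)
    total = 0
    for rec in proteins:
        if len(rec.sequence) < 2:
            continue
        counts[classify_nterm(rec.sequence).class_name] += 1
        total += 1
    if total == 0:
        raise ValueError("no protein long enough to classify")
    return pd.Series({c: counts[c] / total for c in NTERM_CLASSES},
                     name="fraction")


def mts_positional_bias(mts_set: Sequence[ProteinRecord],
                        non_mts_mito_set: Sequence[ProteinRecord],
                        proteome: Sequence[ProteinRecord],
                        positions: Sequence[int] = range(1, 21),
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residue x position HGT matrices for MTS-bearing and MTS-less
    mitochondrial precursors against the whole-proteome reference.

    The two cohorts must be disjoint; both matrices share the same
    per-position proteome urn, so they are directly comparable.
    """
    overlap = {r.accession for r in mts_set} & \
        {r.accession for r in non_mts_mito_set}
    if overlap:
        raise ValueError(f"cohorts overlap: {sorted(overlap)[:5]}")
    with_mts = positional_hgt_matrix(mts_set, proteome, positions)
    without_mts = positional_hgt_matrix(non_mts_mito_set, proteome,
                                        positions)
    return with_mts, without_mts


def mts_position2_table(mts_set: Sequence[ProteinRecord],
                        proteome: Sequence[ProteinRecord],
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-residue position-2 bias of MTS-bearing precursors versus the
    proteome, plus the cohort's residue-2 class fractions.

    Returns ``(table, fractions)`` where ``table`` is indexed by residue
    with columns ``f_obs`` (MTS cohort), ``f_ref`` (proteome position 2)
    and ``hgt``.
    """
    if not mts_set:
        raise ValueError("empty MTS set")
    matrix = positional_hgt_matrix(mts_set, proteome, positions=[1, 2])
    sub = position_profile(mts_set, max_position=2)
    ref = position_profile(proteome, max_position=2)
    table = pd.DataFrame({
        "f_obs": sub.to_frame().loc[2],
        "f_ref": ref.to_frame().loc[2],
        "hgt": matrix[2],
    })
    return table, class_fractions(mts_set)


def cross_species_mts_bias(groups: OrthologGroups,
                           species_proteomes: Mapping[str, ProteomeSet],
                           sc_mts_ids: Sequence[str],
                           max_position: int = 30,
                           ) -> dict[str, dict[str, pd.Series]]:
    """Conservation of the MTS position-2 signature across species.

    For each species, the MTS cohort is the set of orthologs of the
    S. cerevisiae MTS-bearing genes (MTS status is inherited from the
    S. cerevisiae member; missing orthologs are skipped and counted).  Each
    cohort is scored against its own full proteome: per-residue signed HGT
    at position 2, and the maximum HGT over positions 3..``max_position``.

    Returns ``{species: {"pos2": Series, "max_3_onwards": Series,
    "n_orthologs": int}}``-like mapping (the count is stored as a 1-element
    Series attribute-free int).
    """
    missing_species = [sp for sp in groups.species
                       if sp not in species_proteomes]
    if missing_species:
        raise ValueError(
            f"no proteome loaded for species: {missing_species}")
    results: dict[str, dict[str, pd.Series]] = {}
    for sp in groups.species:
        proteome = species_proteomes[sp]
        cohort: list[ProteinRecord] = []
        n_missing = 0
        for sc_acc in sc_mts_ids:
            ortholog = groups.groups.get(sc_acc, {}).get(sp)
            if ortholog is None or ortholog not in proteome:
                n_missing += 1
                continue
            cohort.append(proteome[ortholog])
        if n_missing:
            logger.info("%s: %d of %d MTS genes without a usable ortholog",
                        sp, n_missing, len(sc_mts_ids))
        if not cohort:
            raise ValueError(f"species {sp} has no MTS orthologs")
        matrix = positional_hgt_matrix(
            cohort, proteome.analyzable, range(1, max_position + 1))
        results[sp] = {
            "pos2": matrix[2],
            "max_3_onwards": matrix.loc[:, 3:].max(axis=1),
            "n_orthologs": len(cohort),  # type: ignore[dict-item]
        }
    return results
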