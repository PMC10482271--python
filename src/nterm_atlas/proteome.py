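"""Proteome containers and positional residue-frequency profiles.

Positions are 1-based throughout the package: the initiator methionine is
position 1 and "position 2" is the residue immediately following it — the
position that determines iMet cleavage by methionine aminopeptidases and
targeting by the N-terminal acetyltransferases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet, alphabetical one-letter codes.
RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_RESIDUE_INDEX: dict[str, int] = {r: i for i, r in enumerate(RESIDUES)}
#: Ambiguity / non-standard codes tolerated in sequences but excluded from
#: all residue counts and denominators.
AMBIGUITY_CODES: frozenset[str] = frozenset("BJOUXZ*")
_VALID_CHARS = frozenset(RESIDUES) | AMBIGUITY_CODES


@dataclass
class ProteinRecord:
    """One protein sequence with identity and exclusion metadata."""

    accession: str
    sequence: str
    gene_name: str | None = None
    is_excluded: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.accession}")

    def nterm_key(self, prefix_len: int = 10) -> str:
        """Dedup key: the first ``prefix_len`` residues (whole sequence if
        shorter)."""
        return self.sequence[:prefix_len]

    def residue_at(self, position: int) -> str | None:
        """Residue at a 1-based position; None beyond the sequence end or
        for an ambiguity code."""
        if position < 1 or position > len(self.sequence):
            return None
        aa = self.sequence[position - 1]
        return aa if aa in _RESIDUE_INDEX else None


class ProteomeSet:
    """A collection of unique-accession protein records.

    ``dedup_map`` groups non-excluded proteins sharing the same N-terminal
    prefix under one representative (the lexicographically smallest
    accession), so that N-terminally identical paralogs are counted once in
    every bias analysis.
    """

    def __init__(self, records: Iterable[ProteinRecord],
                 species_tag: str = "", dedup_prefix_len: int = 10) -> None:
        self.records: list[ProteinRecord] = sorted(
            records, key=lambda r: r.accession)
        self.species_tag = species_tag
        self.dedup_prefix_len = dedup_prefix_len
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession: {rec.accession}")
            seen.add(rec.accession)
        self._by_accession = {r.accession: r for r in self.records}
        self.dedup_map: dict[str, str] = nterm_dedup(self, dedup_prefix_len)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    @property
    def analyzable(self) -> list[ProteinRecord]:
        """Non-excluded records, in accession order."""
        return [r for r in self.records if not r.is_excluded]

    def representative(self, accession: str) -> str:
        """Dedup representative accession for a protein."""
        rec = self._by_accession[accession]
        return self.dedup_map[rec.nterm_key(self.dedup_prefix_len)]

    def dedup_groups(self) -> dict[str, list[str]]:
        """Representative accession -> member accessions."""
        groups: dict[str, list[str]] = {}
        for rec in self.analyzable:
            rep = self.representative(rec.accession)
            groups.setdefault(rep, []).append(rec.accession)
        return groups


def nterm_dedup(proteome: ProteomeSet | Iterable[ProteinRecord],
                prefix_len: int = 10) -> dict[str, str]:
    """Map each N-terminal prefix key to its representative accession.

    The representative is the lexicographically smallest accession among
    non-excluded proteins sharing the prefix, which makes every downstream
    dedup-based count deterministic and independent of input order.
    """
    if prefix_len < 1:
        raise ValueError("prefix_len must be >= 1")
    records = proteome.records if isinstance(proteome, ProteomeSet) else list(proteome)
    mapping: dict[str, str] = {}
    for rec in records:
        if rec.is_excluded:
            continue
        key = rec.nterm_key(prefix_len)
        if key not in mapping or rec.accession < mapping[key]:
            mapping[key] = rec.accession
    return mapping


def _parse_header(header: str) -> tuple[str, str | None]:
    """Accession and gene name from a UniProt-style or bare FASTA header."""
    token = header.split()[0]
    if token.count("|") >= 2:  # sp|ACC|NAME_SPECIES
        parts = token.split("|")
        return parts[1], parts[2] or None
    return token, None


def read_fasta_proteome(path: str | Path,
                        exclusion_ids: Iterable[str] | None = None,
                        species_tag: str = "",
                        dedup_prefix_len: int = 10) -> ProteomeSet:
    """Read a proteome FASTA into a :class:`ProteomeSet`.

    Headers may be UniProt-style (``sp|ACC|NAME ...``) or bare identifiers.
    Accessions listed in ``exclusion_ids`` (e.g. transposon-encoded
    proteins) are kept in the set but flagged ``is_excluded`` and ignored by
    every counting operation.

    Raises
    ------
    ValueError
        If the file contains no sequences, a duplicate accession, or a
        character outside the amino-acid alphabet (reported with its
        record's accession).
    """
    excluded = set(exclusion_ids or ())
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, gene = _parse_header(entry.description)
        seq = str(entry.seq).upper().rstrip("*")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"non-amino-acid character(s) {sorted(bad)} in record "
                f"{accession} of {path}")
        records.append(ProteinRecord(
            accession=accession, sequence=seq, gene_name=gene,
            is_excluded=accession in excluded))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    n_excluded = sum(r.is_excluded for r in records)
    logger.info("read %d proteins from %s (%d excluded)",
                len(records), path, n_excluded)
    return ProteomeSet(records, species_tag=species_tag,
                       dedup_prefix_len=dedup_prefix_len)


@dataclass
class PositionProfile:
    """Residue counts and frequencies over the first positions of a protein
    collection.

    ``counts[p-1, i]`` is the number of proteins with canonical residue
    ``RESIDUES[i]`` at 1-based position ``p``; ``n_at_position[p-1]`` counts
    proteins long enough to contribute a canonical residue there (ambiguity
    codes are excluded from both numerator and denominator).
    """

    max_position: int
    counts: np.ndarray          # (max_position, 20) int64
    n_at_position: np.ndarray   # (max_position,) int64

    @property
    def freq(self) -> np.ndarray:
        """Row-normalised frequencies; rows with no eligible protein are NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.n_at_position[:, None]

    def count_at(self, position: int, residue: str) -> int:
        return int(self.counts[position - 1, _RESIDUE_INDEX[residue]])

    def freq_at(self, position: int, residue: str) -> float:
        n = self.n_at_position[position - 1]
        if n == 0:
            return float("nan")
        return self.count_at(position, residue) / n

    def to_frame(self) -> pd.DataFrame:
        """Frequencies as a positions x residues DataFrame."""
        return pd.DataFrame(self.freq, index=range(1, self.max_position + 1),
                            columns=list(RESIDUES))


def position_profile(proteins: Sequence[ProteinRecord],
                     max_position: int) -> PositionProfile:
    """Count residues at positions 1..max_position over a protein collection.

    Only proteins of length >= position contribute at each position, and
    ambiguity codes are dropped from counts and denominators alike.
    """
    proteins = [p for p in proteins if not p.is_excluded]
    if not proteins:
        raise ValueError("no (non-excluded) proteins to profile")
    if max_position < 2:
        raise ValueError("max_position must be >= 2")
    counts = np.zeros((max_position, len(RESIDUES)), dtype=np.int64)
    n_at = np.zeros(max_position, dtype=np.int64)
    for rec in proteins:
        limit = min(len(rec.sequence), max_position)
        for pos in range(1, limit + 1):
            aa = rec.sequence[pos - 1]
            idx = _RESIDUE_INDEX.get(aa)
            if idx is not None:
                counts[pos - 1, idx] += 1
                n_at[pos - 1] += 1
    return PositionProfile(max_position=max_position, counts=counts,
                           n_at_position=n_at)


@dataclass
class BackgroundFrequencies:
    """Proteome-wide residue usage: counts pooled over every position of
    every non-excluded protein.  ``freq`` is the Fmean reference used by all
    position-2 bias tests."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freq(self) -> dict[str, float]:
        tot = self.total
        return {r: self.counts[r] / tot for r in RESIDUES}

    def __getitem__(self, residue: str) -> float:
        return self.freq[residue]


def background_frequencies(
        proteins: Sequence[ProteinRecord]) -> BackgroundFrequencies:
    """Pooled residue frequencies over all positions of all non-excluded
    proteins (the average-usage reference, Fmean)."""
    proteins = [p for p in proteins if not p.is_excluded]
    if not proteins:
        raise ValueError("no (non-excluded) proteins for the background")
    counts = dict.fromkeys(RESIDUES, 0)
    for rec in proteins:
        for aa in rec.sequence:
            if aa in _RESIDUE_INDEX:
                counts[aa] += 1
    return BackgroundFrequencies(counts=counts)
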