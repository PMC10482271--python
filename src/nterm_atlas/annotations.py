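"""Readers for GO annotations (GAF 2.x), curated mitochondrial/MTS tables,
and cross-species ortholog group tables."""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Mapping

import pandas as pd
from Bio.UniProt.GOA import gafiterator

from .proteome import ProteomeSet

logger = logging.getLogger(__name__)

#: GAF aspect column -> GO domain name.
ASPECTS = {"C": "component", "P": "process", "F": "function"}
_GAF_MIN_COLUMNS = 15  # GAF 1.0; 2.x files carry 17


@dataclass
class GOAnnotationSet:
    """GO term -> protein accessions for one GO domain.

    Accessions absent from the companion proteome are dropped at read time;
    ``n_unknown`` records how many annotation rows were lost that way.
    """

    domain: str
    terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)
    n_unknown: int = 0

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> set[str]:
        return self.terms[term_id]


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


class _ValidatingHandle:
    """File-like wrapper that checks the GAF column count line by line
    (Biopython's iterator needs ``readline`` for the version header)."""

    def __init__(self, handle: IO[str], path: str | Path) -> None:
        self._it = self._validated(handle, path)

    @staticmethod
    def _validated(handle: IO[str], path: str | Path) -> Iterator[str]:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("!") or not line.strip():
                yield line
                continue
            n_cols = line.rstrip("\n").count("\t") + 1
            if n_cols < _GAF_MIN_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_GAF_MIN_COLUMNS} "
                    f"tab-separated columns, found {n_cols}")
            yield line

    def readline(self) -> str:
        return next(self._it, "")

    def __iter__(self) -> Iterator[str]:
        return self._it


def read_gaf(path: str | Path,
             proteome: ProteomeSet) -> dict[str, GOAnnotationSet]:
    """Read a GAF 2.x file into one :class:`GOAnnotationSet` per GO domain.

    Rows with a NOT qualifier are dropped (they assert the absence of the
    annotation), duplicate (term, protein) pairs collapse, and annotations
    for accessions missing from ``proteome`` are discarded with a count.

    Returns a dict keyed by ``"component"``, ``"process"``, ``"function"``.
    """
    sets = {domain: GOAnnotationSet(domain=domain)
            for domain in ASPECTS.values()}
    n_rows = 0
    with _open_maybe_gzip(path) as handle:
        for rec in gafiterator(_ValidatingHandle(handle, path)):
            if "NOT" in rec["Qualifier"]:
                continue
            aspect = rec["Aspect"]
            domain = ASPECTS.get(aspect)
            if domain is None:
                continue
            n_rows += 1
            acc = rec["DB_Object_ID"]
            ann = sets[domain]
            if acc not in proteome:
                ann.n_unknown += 1
                continue
            term = rec["GO_ID"]
            ann.terms.setdefault(term, set()).add(acc)
            if rec.get("DB_Object_Symbol"):
                ann.term_names.setdefault(term, "")
    if n_rows == 0:
        raise ValueError(f"no usable annotation rows in {path}")
    for domain, ann in sets.items():
        if ann.n_unknown:
            logger.warning("%s: dropped %d annotations with unknown "
                           "accessions (%s domain)", path, ann.n_unknown,
                           domain)
    return sets


@dataclass
class MitoAnnotation:
    """Curation status of one protein: mitochondrial with high confidence,
    MTS-bearing, and optional sub-compartment label."""

    accession: str
    is_mito_curated: bool
    has_mts: bool
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.has_mts and not self.is_mito_curated:
            raise ValueError(
                f"{self.accession}: has_mts requires is_mito_curated")


def read_mts_table(path: str | Path) -> dict[str, MitoAnnotation]:
    """Read a curated mitochondrial/MTS table.

    Expected TSV columns: ``accession``, ``is_mito``, ``has_mts`` and an
    optional ``compartment``.  Boolean columns accept 0/1 or true/false.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "is_mito", "has_mts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    def as_bool(v: str) -> bool:
        return str(v).strip().lower() in {"1", "true", "yes"}

    table: dict[str, MitoAnnotation] = {}
    for row in df.itertuples(index=False):
        acc = row.accession
        if acc in table:
            raise ValueError(f"{path}: duplicate accession {acc}")
        compartment = getattr(row, "compartment", None)
        if pd.isna(compartment):
            compartment = None
        table[acc] = MitoAnnotation(
            accession=acc,
            is_mito_curated=as_bool(row.is_mito),
            has_mts=as_bool(row.has_mts),
            compartment=compartment)
    return table


@dataclass
class OrthologGroups:
    """Per-gene ortholog identifiers across a panel of species.

    ``groups[sc_accession][species_tag]`` is the ortholog accession in that
    species (absent key = no ortholog).  ``has_mts`` flags inherit from the
    S. cerevisiae member's annotation when supplied at read time.
    """

    species: list[str]
    groups: dict[str, dict[str, str]]
    has_mts: dict[str, bool] = field(default_factory=dict)
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.groups)

    def coverage(self) -> dict[str, int]:
        """Per-group number of species with an ortholog."""
        return {acc: len(m) for acc, m in self.groups.items()}

    def species_counts(self) -> dict[str, int]:
        """Per-species number of groups with an ortholog."""
        return {sp: sum(1 for m in self.groups.values() if sp in m)
                for sp in self.species}


def read_ortholog_groups(path: str | Path) -> OrthologGroups:
    """Read an ortholog-group TSV: first column the S. cerevisiae accession,
    remaining columns one per species; empty cells mean no ortholog, and a
    cell listing several comma-separated orthologs keeps the first (the
    multiplicity is recorded)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sc_col = df.columns[0]
    meta_cols = {"has_mts"}
    species = [c for c in df.columns[1:] if c not in meta_cols]
    if df[sc_col].duplicated().any():
        dupes = df.loc[df[sc_col].duplicated(), sc_col].tolist()
        raise ValueError(f"{path}: duplicated gene row(s): {dupes}")
    groups: dict[str, dict[str, str]] = {}
    has_mts: dict[str, bool] = {}
    multiplicity: dict[str, int] = {}
    for _, row in df.iterrows():
        acc = row[sc_col]
        members: dict[str, str] = {}
        for sp in species:
            cell = row[sp]
            if pd.isna(cell) or not str(cell).strip():
                continue
            orthologs = [x.strip() for x in str(cell).split(",") if x.strip()]
            members[sp] = orthologs[0]
            if len(orthologs) > 1:
                multiplicity[acc] = multiplicity.get(acc, 0) + len(orthologs) - 1
        groups[acc] = members
        if not members:
            logger.warning("%s: group %s has no orthologs", path, acc)
        if "has_mts" in df.columns:
            has_mts[acc] = str(row["has_mts"]).strip().lower() in {
                "1", "true", "yes"}
    return OrthologGroups(species=species, groups=groups, has_mts=has_mts,
                          multiplicity=multiplicity)
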