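"""Seeded generators for synthetic proteomes, MTS cohorts, pseudo-species
ortholog panels, and sel-TRAP enrichment tables.

Every generator takes an explicit seed, uses a single private RNG stream,
and returns a machine-readable ground truth alongside the data, so recovery
tests can compare what the analyses find with what was planted.  The
generators emulate the statistical structure the analyses assume — residue-2
composition biases inside annotated groups, Arg-rich MTS bodies, log2-shifted
enrichment for a chosen N-terminus class — not real evolutionary processes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import MitoAnnotation, OrthologGroups
from .proteome import RESIDUES, ProteinRecord, ProteomeSet

__all__ = [
    "YEAST_BACKGROUND", "PlantedBias", "FixtureTruth",
    "simulate_proteome", "simulate_mts_cohort", "simulate_seltrap",
    "write_fasta", "write_gaf", "write_mts_table",
]

#: Approximate residue usage of a budding-yeast proteome, used as the
#: default background for all generators (normalised at import time).
_YEAST_RAW = {
    "A": 0.0551, "C": 0.0132, "D": 0.0585, "E": 0.0656, "F": 0.0441,
    "G": 0.0498, "H": 0.0217, "I": 0.0657, "K": 0.0734, "L": 0.0957,
    "M": 0.0207, "N": 0.0613, "P": 0.0438, "Q": 0.0393, "R": 0.0444,
    "S": 0.0905, "T": 0.0591, "V": 0.0556, "W": 0.0104, "Y": 0.0337,
}
_total = sum(_YEAST_RAW.values())
YEAST_BACKGROUND: dict[str, float] = {r: v / _total
                                      for r, v in _YEAST_RAW.items()}

#: Default residue-2 distribution of a simulated MTS cohort: dominated by
#: bulky hydrophobics (leucine above all), with small-gyration residues
#: depleted to ~20% of the cohort.
MTS_POS2_MIX: dict[str, float] = {
    "L": 0.36, "F": 0.12, "I": 0.05, "W": 0.04,           # natc_type 0.57
    "A": 0.04, "C": 0.01, "G": 0.02, "P": 0.02, "S": 0.05,
    "T": 0.03, "V": 0.03,                                  # metap_type 0.20
    "D": 0.02, "E": 0.02, "N": 0.03, "Q": 0.03,            # natb_type 0.10
    "H": 0.02, "K": 0.04, "M": 0.03, "R": 0.03, "Y": 0.01,  # other 0.13
}
assert abs(sum(MTS_POS2_MIX.values()) - 1.0) < 1e-9


@dataclass
class PlantedBias:
    """A position-2 residue bias planted inside one annotated group."""

    term_id: str
    residue: str
    prob: float          # planted P(residue at position 2) within the group
    n_members: int


@dataclass
class FixtureTruth:
    """Ground truth emitted next to each synthetic dataset."""

    seed: int
    background: dict[str, float]
    planted: list[dict] = field(default_factory=list)
    realized: dict[str, object] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _freq_vector(background: Mapping[str, float]) -> np.ndarray:
    v = np.array([background[r] for r in RESIDUES], dtype=float)
    if not np.isclose(v.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    return v / v.sum()


def _lengths(rng: np.random.Generator, n: int, mean_length: int,
             min_length: int) -> np.ndarray:
    # geometric tail on top of a hard minimum; mean equals mean_length
    return min_length + rng.geometric(1.0 / (mean_length - min_length), n) - 1


def _random_body(rng: np.random.Generator, length: int,
                 probs: np.ndarray) -> str:
    return "".join(np.array(RESIDUES)[rng.choice(20, size=length, p=probs)])


def simulate_proteome(n_proteins: int = 1000,
                      mean_length: int = 450,
                      min_length: int = 30,
                      background: Mapping[str, float] | None = None,
                      planted_go_biases: Sequence[PlantedBias] = (),
                      n_decoy_terms: int = 0,
                      decoy_term_size: int = 30,
                      domain_aspect: str = "C",
                      seed: int = 0,
                      ) -> tuple[ProteomeSet, list[dict], FixtureTruth]:
    """Simulate a proteome with optional planted GO-group position-2 biases.

    Every protein starts with M; residues from position 2 onward are i.i.d.
    from ``background``, except position 2 of planted-group members, which
    is the planted residue with probability ``prob`` (background draw
    otherwise).  Planted groups occupy disjoint leading blocks of the
    accession space; decoy terms are random samples with no planted bias.

    Returns ``(proteome, gaf_rows, truth)`` where each GAF row is a dict
    with keys ``accession``, ``term_id``, ``aspect``.
    """
    rng = np.random.default_rng(seed)
    probs = _freq_vector(background or YEAST_BACKGROUND)
    needed = sum(b.n_members for b in planted_go_biases)
    if needed > n_proteins:
        raise ValueError("planted groups need more proteins than simulated")
    for bias in planted_go_biases:
        if not 0 <= bias.prob <= 1:
            raise ValueError(f"invalid planted probability {bias.prob}")
    lengths = _lengths(rng, n_proteins, mean_length, min_length)
    width = len(str(n_proteins))
    accessions = [f"P{i:0{width}d}" for i in range(n_proteins)]
    records: list[ProteinRecord] = []
    gaf_rows: list[dict] = []
    truth = FixtureTruth(seed=seed,
                         background=dict(zip(RESIDUES, probs)))
    cursor = 0
    planted_of: dict[int, PlantedBias] = {}
    for bias in planted_go_biases:
        members = range(cursor, cursor + bias.n_members)
        for i in members:
            planted_of[i] = bias
            gaf_rows.append({"accession": accessions[i],
                             "term_id": bias.term_id,
                             "aspect": domain_aspect})
        truth.planted.append({
            "term_id": bias.term_id, "residue": bias.residue,
            "prob": bias.prob, "members": [accessions[i] for i in members]})
        cursor += bias.n_members
    for i in range(n_proteins):
        body = _random_body(rng, int(lengths[i]) - 1, probs)
        bias = planted_of.get(i)
        if bias is not None and rng.random() < bias.prob:
            body = bias.residue + body[1:]
        records.append(ProteinRecord(accession=accessions[i],
                                     sequence="M" + body))
    for d in range(n_decoy_terms):
        term = f"GO:D{d:06d}"
        members = rng.choice(n_proteins, size=min(decoy_term_size,
                                                  n_proteins),
                             replace=False)
        for i in sorted(members):
            gaf_rows.append({"accession": accessions[i], "term_id": term,
                             "aspect": domain_aspect})
    proteome = ProteomeSet(records)
    for entry in truth.planted:
        realized = sum(1 for acc in entry["members"]
                       if proteome[acc].sequence[1] == entry["residue"])
        truth.realized[entry["term_id"]] = realized
    return proteome, gaf_rows, truth


def simulate_mts_cohort(n_mts: int = 361,
                        n_mito_no_mts: int = 365,
                        n_other: int = 1274,
                        pos2_mix: Mapping[str, float] | None = None,
                        arg_prob: float = 0.20,
                        arg_positions: tuple[int, int] = (3, 20),
                        n_species: int = 3,
                        retention_prob: float = 0.9,
                        substitution_prob: float = 0.1,
                        background: Mapping[str, float] | None = None,
                        mean_length: int = 450,
                        min_length: int = 30,
                        seed: int = 0,
                        ) -> tuple[ProteomeSet, dict[str, MitoAnnotation],
                                   dict[str, ProteomeSet], OrthologGroups,
                                   FixtureTruth]:
    """Simulate a proteome with an MTS cohort plus pseudo-species orthologs.

    MTS members draw their position-2 residue from ``pos2_mix`` (bulky
    hydrophobics dominant by default) and are arginine-enriched at
    ``arg_positions``; all other proteins are plain background draws.
    Pseudo-species orthologs copy each protein, mutating every position
    with ``substitution_prob`` (background draws) but re-imposing the
    source's position-2 residue with ``retention_prob``.

    Returns ``(proteome, mito_table, species_proteomes, groups, truth)``.
    """
    if n_species < 1:
        raise ValueError("need at least one pseudo-species")
    rng = np.random.default_rng(seed)
    probs = _freq_vector(background or YEAST_BACKGROUND)
    mix = pos2_mix or MTS_POS2_MIX
    mix_vec = np.array([mix.get(r, 0.0) for r in RESIDUES])
    if not np.isclose(mix_vec.sum(), 1.0):
        raise ValueError("pos2_mix must sum to 1")
    lo, hi = arg_positions
    arg_idx = RESIDUES.index("R")
    n_total = n_mts + n_mito_no_mts + n_other
    lengths = _lengths(rng, n_total, mean_length, min_length)
    width = len(str(n_total))
    records: list[ProteinRecord] = []
    mito_table: dict[str, MitoAnnotation] = {}
    mts_ids: list[str] = []
    for i in range(n_total):
        acc = f"P{i:0{width}d}"
        length = int(lengths[i])
        body = list(_random_body(rng, length - 1, probs))
        is_mts = i < n_mts
        is_mito = i < n_mts + n_mito_no_mts
        if is_mts:
            body[0] = RESIDUES[rng.choice(20, p=mix_vec)]
            for pos in range(lo, min(hi, length) + 1):
                if rng.random() < arg_prob:
                    body[pos - 2] = "R"
            mts_ids.append(acc)
        records.append(ProteinRecord(accession=acc,
                                     sequence="M" + "".join(body)))
        compartment = ("matrix" if is_mts else
                       "outer_membrane" if is_mito else None)
        mito_table[acc] = MitoAnnotation(
            accession=acc, is_mito_curated=is_mito, has_mts=is_mts,
            compartment=compartment)
    proteome = ProteomeSet(records, species_tag="source")

    species_proteomes: dict[str, ProteomeSet] = {}
    species_tags = [f"species{s + 1:02d}" for s in range(n_species)]
    groups_map: dict[str, dict[str, str]] = {r.accession: {}
                                             for r in records}
    for tag in species_tags:
        sp_records = []
        for rec in records:
            seq = np.array(list(rec.sequence))
            mutate = rng.random(len(seq)) < substitution_prob
            mutate[0] = False  # iMet fixed
            if mutate.any():
                seq[mutate] = np.array(RESIDUES)[
                    rng.choice(20, size=int(mutate.sum()), p=probs)]
            if len(seq) > 1:
                if rng.random() < retention_prob:
                    seq[1] = rec.sequence[1]
            ortholog_acc = f"{tag}_{rec.accession}"
            sp_records.append(ProteinRecord(accession=ortholog_acc,
                                            sequence="".join(seq)))
            groups_map[rec.accession][tag] = ortholog_acc
        species_proteomes[tag] = ProteomeSet(sp_records, species_tag=tag)
    groups = OrthologGroups(
        species=species_tags, groups=groups_map,
        has_mts={acc: acc in set(mts_ids) for acc in groups_map})

    truth = FixtureTruth(seed=seed, background=dict(zip(RESIDUES, probs)))
    truth.planted.append({
        "cohort": "mts", "pos2_mix": {r: mix.get(r, 0.0) for r in RESIDUES},
        "arg_prob": arg_prob, "arg_positions": [lo, hi],
        "members": mts_ids,
        "retention_prob": retention_prob,
        "substitution_prob": substitution_prob})
    truth.realized["n_mts"] = len(mts_ids)
    truth.realized["n_mito_curated"] = n_mts + n_mito_no_mts
    truth.realized["mts_pos2_counts"] = {
        r: sum(1 for acc in mts_ids if proteome[acc].sequence[1] == r)
        for r in RESIDUES}
    return proteome, mito_table, species_proteomes, groups, truth


def simulate_seltrap(n_genes: int = 1000,
                     class_labels: Sequence[str] | None = None,
                     planted_class: str = "natc_type",
                     planted_fraction: float = 0.05,
                     shift: float = 1.5,
                     noise_sd: float = 0.5,
                     n_replicates: int = 2,
                     reference_sd: float = 0.1,
                     seed: int = 0,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, FixtureTruth]:
    """Simulate bait and reference sel-TRAP enrichment tables.

    When ``class_labels`` is omitted, ``planted_fraction`` of the genes are
    labelled ``planted_class`` and the rest ``"background"``.  Per
    replicate, the bait's corrected-scale log2 ratio is ``shift`` for
    planted-class genes plus N(0, noise_sd) noise for everyone; the
    reference table is pure N(0, reference_sd) noise (the emitted bait
    table is the sum of both, so subtracting the reference recovers the
    planted signal).

    Returns ``(bait, reference, truth)``, both gene-indexed frames with
    one column per replicate.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    if class_labels is None:
        n_planted = round(planted_fraction * n_genes)
        labels = [planted_class] * n_planted + \
            ["background"] * (n_genes - n_planted)
    else:
        labels = list(class_labels)
        if len(labels) != n_genes:
            raise ValueError("one class label per gene required")
    if planted_class not in labels:
        raise ValueError(f"planted class {planted_class!r} absent from "
                         "labels")
    is_planted = np.array([lab == planted_class for lab in labels])
    cols = [f"rep{j + 1}" for j in range(n_replicates)]
    signal = shift * is_planted[:, None] + \
        rng.normal(0.0, noise_sd, size=(n_genes, n_replicates))
    reference = rng.normal(0.0, reference_sd, size=(n_genes, n_replicates))
    bait = pd.DataFrame(signal + reference, index=genes, columns=cols)
    ref = pd.DataFrame(reference, index=genes, columns=cols)
    truth = FixtureTruth(seed=seed, background={})
    truth.planted.append({
        "planted_class": planted_class, "shift": shift,
        "noise_sd": noise_sd, "reference_sd": reference_sd,
        "genes": [g for g, p in zip(genes, is_planted) if p],
        "labels": labels})
    truth.realized["n_planted"] = int(is_planted.sum())
    return bait, ref, truth


# ---------------------------------------------------------------------------
# plain-text writers for the simulated inputs

def write_fasta(proteome: ProteomeSet, path: str | Path) -> None:
    """Write a proteome as UniProt-dialect FASTA (deterministic order)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence),
                  id=f"sp|{rec.accession}|{rec.gene_name or rec.accession}",
                  description="")
        for rec in proteome.records]
    SeqIO.write(seq_records, str(path), "fasta")


def write_gaf(gaf_rows: Sequence[Mapping[str, str]], path: str | Path,
              db: str = "SIM") -> None:
    """Write annotation rows as a minimal GAF 2.2 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for row in gaf_rows:
            cols = [""] * 17
            cols[0] = db
            cols[1] = row["accession"]
            cols[2] = row["accession"]
            cols[3] = "located_in"
            cols[4] = row["term_id"]
            cols[5] = "SIM_REF:0"
            cols[6] = "IDA"
            cols[8] = row["aspect"]
            cols[11] = "protein"
            cols[12] = "taxon:0"
            cols[13] = "20200101"
            cols[14] = db
            fh.write("\t".join(cols) + "\n")


def write_mts_table(mito_table: Mapping[str, MitoAnnotation],
                    path: str | Path) -> None:
    """Write a curated mitochondrial/MTS annotation TSV."""
    rows = [{"accession": ann.accession,
             "is_mito": int(ann.is_mito_curated),
             "has_mts": int(ann.has_mts),
             "compartment": ann.compartment or ""}
            for ann in mito_table.values()]
    pd.DataFrame(rows).sort_values("accession").to_csv(
        path, sep="\t", index=False)
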