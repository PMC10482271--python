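"""Downstream analysis of selective translating-ribosome affinity
purification (sel-TRAP) enrichment data.

Inputs are gene-level log2(IP/input) ratios for a bait immunoprecipitation
(e.g. a tagged N-terminal acetyltransferase subunit) and for a reference
immunoprecipitation of a canonical ribosomal protein.  Subtracting the
reference removes the generic translating-ribosome signal; the residual is
the bait-specific enrichment.  Target calling is preceded by a
threshold-independent sweep: at every enrichment cutoff the proportion of
each N-terminus class among retained genes is scored against the array
background by a signed hypergeometric (HGT) score, so the choice of the
final cutoff can be read off the HGT maxima rather than imposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import MitoAnnotation
from .config import DEFAULT_CONFIG, AnalysisConfig
from .hypergeom import hgt_score
from .mts import classify_nterm
from .proteome import ProteomeSet

logger = logging.getLogger(__name__)

__all__ = [
    "correct_enrichment", "combine_replicates", "sweep_grid",
    "threshold_sweep", "call_targets", "composition_report",
    "filter_ms_partners",
]


def correct_enrichment(bait: pd.DataFrame,
                       reference: pd.DataFrame) -> pd.DataFrame:
    """Subtract the reference-bait log2(IP/input) from the bait's, per gene
    and per replicate.

    Both frames are gene-indexed with one column per replicate.  Genes
    absent from either table are dropped (logged); an empty intersection is
    an error.
    """
    common = bait.index.intersection(reference.index)
    if common.empty:
        raise ValueError("bait and reference tables share no genes")
    n_dropped = len(bait.index.union(reference.index)) - len(common)
    if n_dropped:
        logger.info("correct_enrichment: dropped %d genes missing from one "
                    "table", n_dropped)
    ref = reference.loc[common]
    if list(bait.columns) != list(reference.columns):
        # replicate-matched by position when labels differ
        ref = ref.set_axis(bait.columns, axis=1)
    return bait.loc[common] - ref


def combine_replicates(corrected: pd.DataFrame,
                       proteome: ProteomeSet | None = None,
                       mts_table: Mapping[str, MitoAnnotation] | None = None,
                       ) -> pd.DataFrame:
    """Average corrected enrichment over replicates and join annotations.

    A gene is kept only when measured in every replicate.  When a proteome
    is supplied, the residue-2 class (``nterm_class``) and residue are
    joined; when an MTS table is supplied, ``is_mito``, ``has_mts`` and
    ``compartment`` are joined (genes absent from the table are treated as
    non-mitochondrial).

    Returns a gene-indexed frame with the replicate columns plus
    ``mean_enrichment`` and any joined annotation columns.
    """
    complete = corrected.dropna()
    n_dropped = len(corrected) - len(complete)
    if n_dropped:
        logger.info("combine_replicates: dropped %d genes absent from some "
                    "replicate", n_dropped)
    out = complete.copy()
    out["mean_enrichment"] = complete.mean(axis=1)
    if proteome is not None:
        classes = {}
        residues = {}
        for gene in out.index:
            if gene in proteome and len(proteome[gene].sequence) >= 2:
                nc = classify_nterm(proteome[gene].sequence)
                classes[gene] = nc.class_name
                residues[gene] = nc.residue2
        out["nterm_class"] = pd.Series(classes)
        out["residue2"] = pd.Series(residues)
    if mts_table is not None:
        out["is_mito"] = [gene in mts_table
                          and mts_table[gene].is_mito_curated
                          for gene in out.index]
        out["has_mts"] = [gene in mts_table and mts_table[gene].has_mts
                          for gene in out.index]
        out["compartment"] = [
            mts_table[gene].compartment if gene in mts_table else None
            for gene in out.index]
    return out


def sweep_grid(config: AnalysisConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Enrichment-threshold grid, generated by integer steps to avoid
    floating-point accumulation (endpoints inclusive)."""
    scale = round(1.0 / config.sweep_step)
    lo = round(config.sweep_min * scale)
    hi = round(config.sweep_max * scale)
    return np.arange(lo, hi + 1) / scale


def threshold_sweep(records: pd.DataFrame,
                    class_fn: str | Callable[[str], str] = "nterm_class",
                    config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Proportion and HGT score of every N-terminus class above each
    enrichment threshold.

    ``class_fn`` is either a column name of ``records`` or a callable
    mapping gene id to class label.  For each threshold t, the retained set
    S(t) = {mean_enrichment >= t}; for each class c the proportion
    |S(t) ∩ c| / |S(t)| and the signed HGT of that count against the class's
    share of the full table are reported.  Rows where S(t) is empty carry
    NaN proportions.
    """
    if records.empty:
        raise ValueError("no enrichment records")
    if callable(class_fn):
        labels = pd.Series({g: class_fn(g) for g in records.index})
    else:
        labels = records[class_fn]
    labels = labels.dropna()
    means = records.loc[labels.index, "mean_enrichment"]
    N = len(labels)
    class_sizes = labels.value_counts()
    rows = []
    for t in sweep_grid(config):
        selected = means >= t
        n = int(selected.sum())
        for cls, K in class_sizes.items():
            k = int((selected & (labels == cls)).sum())
            if n == 0:
                proportion, score = np.nan, np.nan
            else:
                proportion = k / n
                score = hgt_score(k, int(K), n, N)
            rows.append({"threshold": t, "class": cls, "n": n, "k": k,
                         "proportion": proportion, "hgt": score})
    return pd.DataFrame(rows)


def call_targets(records: pd.DataFrame,
                 threshold: float = DEFAULT_CONFIG.target_threshold,
                 per_replicate: bool = False) -> set[str]:
    """Genes called as putative co-translational targets.

    Default rule: mean corrected enrichment >= ``threshold`` (inclusive).
    With ``per_replicate=True`` the cutoff must hold in every replicate
    column individually (the strict variant).
    """
    if per_replicate:
        replicate_cols = [c for c in records.columns
                          if pd.api.types.is_numeric_dtype(records[c])
                          and c != "mean_enrichment"]
        mask = (records[replicate_cols] >= threshold).all(axis=1)
    else:
        mask = records["mean_enrichment"] >= threshold
    return set(records.index[mask])


def _category_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Categorical labels per gene for the composition report."""
    cats = pd.DataFrame(index=records.index)
    if "compartment" in records:
        cats["compartment"] = records["compartment"]
    if "has_mts" in records and "is_mito" in records:
        status = np.where(records["has_mts"], "mts",
                          np.where(records["is_mito"], "mito_no_mts",
                                   "non_mito"))
        cats["mito_status"] = status
    if "nterm_class" in records:
        cats["nterm_class"] = records["nterm_class"]
    return cats


def composition_report(targets: set[str],
                       records: pd.DataFrame) -> pd.DataFrame:
    """Fractions and signed HGT scores of annotation categories among the
    called targets, against the full enrichment table as background.

    Categories: sub-cellular compartment, MTS status (MTS-bearing /
    mitochondrial without MTS / non-mitochondrial), residue-2 class, and —
    among MTS-bearing targets — the residue at position 2.
    """
    unknown = targets - set(records.index)
    if unknown:
        raise ValueError(f"targets absent from records: "
                         f"{sorted(unknown)[:5]}")
    cats = _category_frame(records)
    target_mask = records.index.isin(targets)
    N = len(records)
    n = int(target_mask.sum())
    rows = []
    for category in cats.columns:
        labels = cats[category]
        for label in sorted(labels.dropna().unique()):
            in_label = (labels == label).to_numpy()
            K = int(in_label.sum())
            k = int((in_label & target_mask).sum())
            rows.append({
                "category": category, "label": label,
                "frac_targets": k / n if n else np.nan,
                "frac_background": K / N,
                "hgt": hgt_score(k, K, n, N) if n else np.nan,
            })
    # residue-2 composition restricted to MTS-bearing proteins
    if "has_mts" in records and "residue2" in records:
        mts_mask = records["has_mts"].to_numpy(dtype=bool)
        sub = records[mts_mask]
        sub_targets = sub.index.isin(targets)
        N_m = len(sub)
        n_m = int(sub_targets.sum())
        for residue in sorted(sub["residue2"].dropna().unique()):
            in_res = (sub["residue2"] == residue).to_numpy()
            K = int(in_res.sum())
            k = int((in_res & sub_targets).sum())
            rows.append({
                "category": "mts_residue2", "label": residue,
                "frac_targets": k / n_m if n_m else np.nan,
                "frac_background": K / N_m if N_m else np.nan,
                "hgt": hgt_score(k, K, n_m, N_m) if n_m and N_m else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class MsPartnerRecord:
    """Verdict for one candidate protein partner from the mass-spec
    filtering of an immunoprecipitation."""

    protein_id: str
    bait: str
    scores: tuple[float, ...]
    control_score: float
    verdict: str                    # kept / below_cutoff / excluded_control
    #                               # / excluded_ratio
    specific_to: str | None = None  # bait label, when >= 5x every other


def filter_ms_partners(tagged_scores: Mapping[str, Sequence[Mapping[str, float]]],
                       control_scores: Mapping[str, float],
                       config: AnalysisConfig = DEFAULT_CONFIG,
                       ) -> list[MsPartnerRecord]:
    """Filter mass-spec partner candidates and assign cross-bait
    specificity.

    ``tagged_scores`` maps each bait label to its per-replicate
    protein -> Mascot score tables; ``control_scores`` is the untagged
    control.  A protein is kept for a bait when, in every replicate, its
    score exceeds the cutoff, the control score stays at or below the
    cutoff, and the tagged/control ratio is at least the minimum (a protein
    missing from the control scores 0, i.e. absent from the mock IP).
    A kept protein whose best score is at least ``mascot_specificity_fold``
    times its best score in every other bait is assigned specific to that
    bait; kept proteins without such a margin are shared.
    """
    cutoff = config.mascot_cutoff
    records: list[MsPartnerRecord] = []
    kept_scores: dict[str, dict[str, float]] = {}  # protein -> bait -> max
    for bait, replicates in tagged_scores.items():
        proteins = sorted(set().union(*[set(r) for r in replicates]))
        for protein in proteins:
            scores = tuple(rep.get(protein, 0.0) for rep in replicates)
            control = control_scores.get(protein, 0.0)
            if any(s <= cutoff for s in scores):
                verdict = "below_cutoff"
            elif control > cutoff:
                verdict = "excluded_control"
            elif control > 0 and any(s < config.mascot_ratio_min * control
                                     for s in scores):
                verdict = "excluded_ratio"
            else:
                verdict = "kept"
                kept_scores.setdefault(protein, {})[bait] = max(scores)
            records.append(MsPartnerRecord(
                protein_id=protein, bait=bait, scores=scores,
                control_score=control, verdict=verdict))
    fold = config.mascot_specificity_fold
    for rec in records:
        if rec.verdict != "kept":
            continue
        own = kept_scores[rec.protein_id][rec.bait]
        others = [max(rep.get(rec.protein_id, 0.0)
                      for rep in tagged_scores[b])
                  for b in tagged_scores if b != rec.bait]
        if all(own >= fold * max(o, 1.0) for o in others):
            rec.specific_to = rec.bait
    return records
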