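"""GO-term scanning for position-2 usage biases and greedy redundancy
reduction of the hit list.

The scan tests every (GO term, residue) pair for over-representation of the
residue at position 2 among the term's proteins, relative to the whole
proteome.  Counting is done on N-terminal dedup identifiers so that families
of proteins sharing their first residues (e.g. near-identical paralogs)
contribute once.

The redundancy reduction follows a two-stage greedy set selection:

* **BestN** terms — the large, mutually low-overlapping terms that together
  cover the greatest number of bias-carrying proteins;
* **BestF** terms — smaller terms nested inside one BestN (containment >=
  40%) with a markedly stronger frequency bias (>= 1.3x the parent's), kept
  only while mutually low-overlapping (< 30%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .annotations import GOAnnotationSet
from .bias import positional_hgt_matrix
from .config import DEFAULT_CONFIG, AnalysisConfig
from .hypergeom import hgt_score
from .proteome import RESIDUES, ProteinRecord, ProteomeSet

__all__ = [
    "GOTermBias", "GOContingency", "SelectionReport",
    "build_go_contingency", "screen_go_terms", "filter_generic_terms",
    "select_best_terms", "positional_specificity_check",
]


@dataclass
class GOTermBias:
    """One scored (GO term, residue) position-2 bias."""

    term_id: str
    term_name: str
    domain: str
    residue: str
    k: int              # dedup proteins in term with the residue at pos 2
    n: int              # dedup term size
    K: int              # dedup proteome count of the residue at pos 2
    N: int              # dedup proteome size
    fold_change: float
    hgt: float
    status: str = "screened"
    parent_bestN: str | None = None
    bias_proteins: frozenset[str] = frozenset()
    term_proteins: frozenset[str] = frozenset()


@dataclass
class GOContingency:
    """Dedup position-2 residue counts per GO term, plus proteome margins."""

    domain: str
    term_members: dict[str, frozenset[str]]          # term -> dedup ids
    term_residue_sets: dict[str, dict[str, frozenset[str]]]
    term_names: Mapping[str, str]
    margins: dict[str, int]                          # residue -> K
    universe_size: int                               # N

    def counts(self, term_id: str) -> dict[str, int]:
        return {r: len(s)
                for r, s in self.term_residue_sets[term_id].items()}


def build_go_contingency(annotations: GOAnnotationSet,
                         proteome: ProteomeSet) -> GOContingency:
    """Count, per GO term, the dedup proteins with each residue at
    position 2.

    The universe is the set of dedup representatives of non-excluded
    proteins with a canonical residue at position 2; term membership maps
    each annotated accession to its representative, so N-terminally
    identical proteins count once.
    """
    if not annotations.terms:
        raise ValueError("empty annotation set")
    # dedup universe and its position-2 residues
    residue_of: dict[str, str] = {}
    for rep in proteome.dedup_groups():
        aa = proteome[rep].residue_at(2)
        if aa is not None:
            residue_of[rep] = aa
    margins = {r: 0 for r in RESIDUES}
    for aa in residue_of.values():
        margins[aa] += 1
    term_members: dict[str, frozenset[str]] = {}
    term_residue_sets: dict[str, dict[str, frozenset[str]]] = {}
    for term_id, accessions in annotations.terms.items():
        reps = {proteome.representative(acc) for acc in accessions
                if acc in proteome and not proteome[acc].is_excluded}
        reps = frozenset(rep for rep in reps if rep in residue_of)
        term_members[term_id] = reps
        by_residue: dict[str, set[str]] = {}
        for rep in reps:
            by_residue.setdefault(residue_of[rep], set()).add(rep)
        term_residue_sets[term_id] = {r: frozenset(s)
                                      for r, s in by_residue.items()}
    return GOContingency(
        domain=annotations.domain, term_members=term_members,
        term_residue_sets=term_residue_sets,
        term_names=annotations.term_names, margins=margins,
        universe_size=len(residue_of))


def screen_go_terms(contingency: GOContingency,
                    config: AnalysisConfig = DEFAULT_CONFIG
                    ) -> list[GOTermBias]:
    """All (term, residue) pairs whose position-2 over-representation
    exceeds the HGT screening threshold (strict ``> hgt_screen_min``)."""
    N = contingency.universe_size
    results: list[GOTermBias] = []
    for term_id in sorted(contingency.term_members):
        members = contingency.term_members[term_id]
        n = len(members)
        if n == 0:
            continue
        for residue, subset in sorted(
                contingency.term_residue_sets[term_id].items()):
            k = len(subset)
            K = contingency.margins[residue]
            score = hgt_score(k, K, n, N)
            if score > config.hgt_screen_min:
                fold = (k / n) / (K / N) if K else float("inf")
                results.append(GOTermBias(
                    term_id=term_id,
                    term_name=contingency.term_names.get(term_id, ""),
                    domain=contingency.domain, residue=residue,
                    k=k, n=n, K=K, N=N, fold_change=fold, hgt=score,
                    bias_proteins=subset, term_proteins=members))
    return results


def filter_generic_terms(screened: Sequence[GOTermBias],
                         config: AnalysisConfig = DEFAULT_CONFIG
                         ) -> list[GOTermBias]:
    """Mark low-bias entries (fold change below the cutoff, boundary kept)
    as ``removed_low_bias``; these are typically very large generic terms
    whose enrichment is significant but weak."""
    out = []
    for entry in screened:
        if entry.fold_change < config.fold_change_min:
            out.append(replace(entry, status="removed_low_bias"))
        else:
            out.append(entry)
    return out


@dataclass
class _TermView:
    """Aggregated per-term view over the (term, residue) entries."""

    term_id: str
    proteins: frozenset[str]
    bias_proteins: frozenset[str]
    residues: tuple[str, ...]
    max_hgt: float
    max_fold: float

    @property
    def n(self) -> int:
        return len(self.proteins)


def _aggregate_terms(entries: Sequence[GOTermBias]) -> dict[str, _TermView]:
    views: dict[str, _TermView] = {}
    by_term: dict[str, list[GOTermBias]] = {}
    for e in entries:
        by_term.setdefault(e.term_id, []).append(e)
    for term_id, group in by_term.items():
        bias: set[str] = set()
        for e in group:
            bias |= e.bias_proteins
        views[term_id] = _TermView(
            term_id=term_id, proteins=group[0].term_proteins,
            bias_proteins=frozenset(bias),
            residues=tuple(sorted({e.residue for e in group})),
            max_hgt=max(e.hgt for e in group),
            max_fold=max(e.fold_change for e in group))
    return views


def _overlap(a: frozenset[str], b: frozenset[str]) -> float:
    """Protein-set overlap: shared fraction of the smaller set."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def _containment(small: frozenset[str], big: frozenset[str]) -> float:
    if not small:
        return 0.0
    return len(small & big) / len(small)


@dataclass
class SelectionReport:
    """Outcome of the BestN/BestF greedy reduction for one GO domain."""

    domain: str
    entries: list[GOTermBias]
    best_n: list[str]
    best_f: list[str]
    parents: dict[str, str]           # BestF term -> its BestN parent
    coverage: float

    def by_status(self, status: str) -> list[GOTermBias]:
        return [e for e in self.entries if e.status == status]

    def to_frame(self) -> pd.DataFrame:
        rows = [{k: v for k, v in vars(e).items()
                 if k not in ("bias_proteins", "term_proteins")}
                for e in self.entries]
        return pd.DataFrame(rows)


def select_best_terms(filtered: Sequence[GOTermBias],
                      config: AnalysisConfig = DEFAULT_CONFIG
                      ) -> SelectionReport:
    """Greedy BestN/BestF reduction of the filtered (term, residue) list.

    BestN: repeatedly select the admissible term covering the most
    not-yet-covered bias proteins; a candidate is admissible while its
    overlap with every selected BestN stays below ``bestN_overlap_max``.
    Ties break on higher HGT, then smaller term, then term id.  Selection
    stops when no admissible candidate contributes a new bias protein.

    BestF: non-BestN terms contained (>= ``bestF_containment_min``) in
    their max-containment BestN parent with a fold change at least
    ``bestF_bias_gain`` times the parent's best fold are accepted in
    decreasing-fold order; a candidate conflicting (overlap >=
    ``bestF_overlap_max``) with accepted BestF terms replaces them only if
    it is preferable (more distinct biased residues, then higher fold, then
    term id).
    """
    if not filtered:
        raise ValueError("no filtered terms to select from")
    passing = [e for e in filtered if e.status != "removed_low_bias"]
    domain = filtered[0].domain
    if not passing:
        return SelectionReport(domain=domain, entries=list(filtered),
                               best_n=[], best_f=[], parents={},
                               coverage=0.0)
    views = _aggregate_terms(passing)

    # ---- BestN greedy cover ----
    best_n: list[str] = []
    covered: set[str] = set()
    while True:
        best_key = None
        best_term = None
        for term_id in sorted(views):
            if term_id in best_n:
                continue
            view = views[term_id]
            if any(_overlap(view.proteins, views[b].proteins)
                   >= config.bestN_overlap_max for b in best_n):
                continue
            gain = len(view.bias_proteins - covered)
            if gain < 1:
                continue
            key = (gain, view.max_hgt, -view.n, _ReversedStr(term_id))
            if best_key is None or key > best_key:
                best_key = key
                best_term = term_id
        if best_term is None:
            break
        best_n.append(best_term)
        covered |= views[best_term].bias_proteins

    # ---- BestF nested high-fold terms ----
    candidates = []
    parents: dict[str, str] = {}
    for term_id in sorted(views):
        if term_id in best_n:
            continue
        view = views[term_id]
        best_parent = None
        best_cont = 0.0
        for b in best_n:
            cont = _containment(view.proteins, views[b].proteins)
            if cont > best_cont or (cont == best_cont and best_parent
                                    and b < best_parent):
                best_cont = cont
                best_parent = b
        if best_parent is None or best_cont < config.bestF_containment_min:
            continue
        if view.max_fold < config.bestF_bias_gain * views[best_parent].max_fold:
            continue
        candidates.append(term_id)
        parents[term_id] = best_parent

    def _pref_key(term_id: str):
        v = views[term_id]
        return (len(v.residues), v.max_fold, _ReversedStr(term_id))

    accepted: list[str] = []
    rejected: set[str] = set()
    for term_id in sorted(candidates,
                          key=lambda t: (-views[t].max_fold, t)):
        conflicts = [a for a in accepted
                     if _overlap(views[term_id].proteins, views[a].proteins)
                     >= config.bestF_overlap_max]
        if not conflicts:
            accepted.append(term_id)
        elif all(_pref_key(term_id) > _pref_key(a) for a in conflicts):
            for a in conflicts:
                accepted.remove(a)
                rejected.add(a)
            accepted.append(term_id)
        else:
            rejected.add(term_id)
    best_f = sorted(accepted)

    # ---- statuses, invariants, coverage ----
    entries: list[GOTermBias] = []
    for e in filtered:
        if e.status == "removed_low_bias":
            entries.append(e)
        elif e.term_id in best_n:
            entries.append(replace(e, status="bestN"))
        elif e.term_id in best_f:
            entries.append(replace(e, status="bestF",
                                   parent_bestN=parents[e.term_id]))
        elif e.term_id in rejected:
            entries.append(replace(e, status="redundant"))
        else:
            entries.append(e)

    for i, a in enumerate(best_n):
        for b in best_n[i + 1:]:
            assert _overlap(views[a].proteins, views[b].proteins) \
                < config.bestN_overlap_max
    for f in best_f:
        assert _containment(views[f].proteins,
                            views[parents[f]].proteins) \
            >= config.bestF_containment_min

    all_bias: set[str] = set()
    for v in views.values():
        all_bias |= v.bias_proteins
    selected_bias: set[str] = set()
    for t in best_n + best_f:
        selected_bias |= views[t].bias_proteins
    coverage = len(selected_bias) / len(all_bias) if all_bias else 0.0
    return SelectionReport(domain=domain, entries=entries, best_n=best_n,
                           best_f=best_f, parents=parents,
                           coverage=coverage)


class _ReversedStr(str):
    """String whose ordering is reversed, for 'then lexicographically
    smallest' tie-breaks inside max-keys."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def positional_specificity_check(term_proteins: Sequence[ProteinRecord],
                                 reference: Sequence[ProteinRecord],
                                 residue: str,
                                 positions: Sequence[int] = range(1, 101),
                                 ) -> tuple[pd.Series, bool]:
    """Check that a term's residue bias is specific to position 2.

    Computes the signed HGT profile of ``residue`` for the term's proteins
    against the reference over ``positions`` and raises the non-specificity
    flag when any other position matches or exceeds the position-2 score.

    Returns ``(profile, non_specific)``.
    """
    matrix = positional_hgt_matrix(term_proteins, reference, positions)
    profile = matrix.loc[residue]
    if 2 not in profile.index:
        raise ValueError("positions must include position 2")
    pos2 = profile[2]
    others = profile.drop(index=2).dropna()
    if pos2 <= 0:
        # no positive bias at position 2: flag only genuine elsewhere-bias
        non_specific = bool((others > 0).any())
    else:
        non_specific = bool((others >= pos2).any())
    return profile, non_specific
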