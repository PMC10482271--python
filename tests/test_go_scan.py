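"""GO-term scanning, generic-term filtering and BestN/BestF selection."""

import itertools
import random

import numpy as np
import pytest

from conftest import make_annotation_set, make_protein
from nterm_atlas import (PlantedBias, ProteinRecord, ProteomeSet,
                         build_go_contingency, filter_generic_terms,
                         positional_specificity_check, screen_go_terms,
                         select_best_terms, simulate_proteome)
from nterm_atlas.annotations import GOAnnotationSet
from nterm_atlas.go_scan import GOTermBias
from nterm_atlas.proteome import RESIDUES


class TestContingency:
    def test_toy_counts(self):
        proteome = ProteomeSet([ProteinRecord("P1", "MSTAAAAAAA"),
                                ProteinRecord("P2", "MLRTPTAAAA"),
                                ProteinRecord("P3", "MSQQQQQQQQ")])
        ann = make_annotation_set({"GO:1": {"P1", "P2", "P3"}})
        cont = build_go_contingency(ann, proteome)
        assert cont.counts("GO:1") == {"S": 2, "L": 1}
        assert len(cont.term_members["GO:1"]) == 3

    def test_shared_prefix_counted_once(self):
        proteome = ProteomeSet([ProteinRecord("P1", "MSTAAAAAAAXYZ"),
                                ProteinRecord("P3", "MSTAAAAAAAQQQ"),
                                ProteinRecord("P2", "MLRTPTAAAA")])
        ann = make_annotation_set({"GO:1": {"P1", "P2", "P3"}})
        cont = build_go_contingency(ann, proteome)
        assert cont.counts("GO:1") == {"S": 1, "L": 1}
        assert len(cont.term_members["GO:1"]) == 2

    def test_brute_force_recount(self):
        """Contingency tables equal a direct dedup recount on a simulated
        proteome + annotation set."""
        proteome, gaf_rows, _ = simulate_proteome(
            n_proteins=500, n_decoy_terms=25, decoy_term_size=20, seed=8)
        ann = GOAnnotationSet(domain="component")
        for row in gaf_rows:
            ann.terms.setdefault(row["term_id"], set()).add(row["accession"])
        cont = build_go_contingency(ann, proteome)
        for term, members in ann.terms.items():
            reps = {proteome.representative(a) for a in members}
            by_res: dict[str, int] = {}
            for rep in reps:
                aa = proteome[rep].residue_at(2)
                if aa is not None:
                    by_res[aa] = by_res.get(aa, 0) + 1
            assert cont.counts(term) == by_res

    def test_empty_annotations_rejected(self):
        proteome = ProteomeSet([ProteinRecord("P1", "MS")])
        with pytest.raises(ValueError):
            build_go_contingency(GOAnnotationSet(domain="component"),
                                 proteome)


def _abc_proteome_and_annotations():
    """Hand-built ontology: A (60 proteins, 30 S, fold 3.0), B inside A
    (20 proteins, 15 S, fold 4.5), C disjoint (40 proteins, 20 L,
    fold 3.0) over a 300-protein universe with 50 S and 50 L at
    position 2."""
    others = [r for r in RESIDUES if r not in ("S", "L")]
    other_cycle = itertools.cycle(others)
    residues = []
    # B: indices 0..19 -> 15 S; A\B: 20..59 -> 15 S; C: 60..99 -> 20 L
    for i in range(300):
        if i < 15 or 20 <= i < 35:
            residues.append("S")
        elif 60 <= i < 80:
            residues.append("L")
        elif 100 <= i < 120:
            residues.append("S")     # rest of the 50 proteome S
        elif 120 <= i < 150:
            residues.append("L")     # rest of the 50 proteome L
        else:
            residues.append(next(other_cycle))
    records = [make_protein(i, residues[i]) for i in range(300)]
    proteome = ProteomeSet(records)
    acc = [r.accession for r in proteome.records]
    ann = make_annotation_set({
        "GO:A": set(acc[:60]),
        "GO:B": set(acc[:20]),
        "GO:C": set(acc[60:100]),
    })
    return proteome, ann


class TestScreenAndFilter:
    def test_abc_screen_counts_and_folds(self):
        proteome, ann = _abc_proteome_and_annotations()
        cont = build_go_contingency(ann, proteome)
        screened = screen_go_terms(cont)
        pairs = {(e.term_id, e.residue): e for e in screened}
        assert set(pairs) == {("GO:A", "S"), ("GO:B", "S"), ("GO:C", "L")}
        assert pairs[("GO:A", "S")].fold_change == pytest.approx(3.0)
        assert pairs[("GO:B", "S")].fold_change == pytest.approx(4.5)
        assert pairs[("GO:C", "L")].fold_change == pytest.approx(3.0)

    def test_screen_threshold_is_strict(self):
        """Only pairs with HGT strictly above the threshold pass."""
        proteome, ann = _abc_proteome_and_annotations()
        cont = build_go_contingency(ann, proteome)
        from nterm_atlas import AnalysisConfig
        strict = screen_go_terms(cont, AnalysisConfig(hgt_screen_min=4.0))
        loose = screen_go_terms(cont, AnalysisConfig(hgt_screen_min=0.5))
        assert {e.hgt > 4.0 for e in strict} == {True}
        assert len(loose) >= len(strict)

    def test_fold_boundary_inclusive_at_cutoff(self):
        def entry(term, fold):
            return GOTermBias(term_id=term, term_name="", domain="component",
                              residue="S", k=10, n=20, K=50, N=300,
                              fold_change=fold, hgt=5.0)
        out = filter_generic_terms([entry("GO:X", 1.79),
                                    entry("GO:Y", 1.80),
                                    entry("GO:Z", 2.20)])
        statuses = {e.term_id: e.status for e in out}
        assert statuses == {"GO:X": "removed_low_bias",
                            "GO:Y": "screened", "GO:Z": "screened"}

    def test_term_kept_via_its_strong_residue(self):
        def entry(residue, fold):
            return GOTermBias(term_id="GO:T", term_name="",
                              domain="component", residue=residue, k=10,
                              n=20, K=50, N=300, fold_change=fold, hgt=5.0)
        out = filter_generic_terms([entry("S", 1.5), entry("L", 2.2)])
        assert [e.status for e in out] == ["removed_low_bias", "screened"]


class TestSelection:
    def test_abc_hand_trace(self):
        """Greedy trace: A first (30 bias proteins), B blocked (100%
        overlap with A), C added (disjoint); B becomes the single BestF
        under parent A (containment 100%, fold 4.5 >= 1.3 x 3.0)."""
        proteome, ann = _abc_proteome_and_annotations()
        cont = build_go_contingency(ann, proteome)
        screened = screen_go_terms(cont)
        report = select_best_terms(filter_generic_terms(screened))
        assert report.best_n == ["GO:A", "GO:C"]
        assert report.best_f == ["GO:B"]
        assert report.parents == {"GO:B": "GO:A"}
        statuses = {(e.term_id, e.residue): e.status for e in report.entries}
        assert statuses[("GO:A", "S")] == "bestN"
        assert statuses[("GO:B", "S")] == "bestF"
        assert statuses[("GO:C", "L")] == "bestN"
        assert report.coverage == pytest.approx(1.0)

    def test_single_term_is_sole_bestn(self):
        entry = GOTermBias(term_id="GO:T", term_name="", domain="component",
                           residue="S", k=10, n=20, K=50, N=300,
                           fold_change=3.0, hgt=6.0,
                           bias_proteins=frozenset({"a", "b"}),
                           term_proteins=frozenset({"a", "b", "c"}))
        report = select_best_terms([entry])
        assert report.best_n == ["GO:T"]
        assert report.best_f == []

    def test_input_order_invariance(self):
        proteome, ann = _abc_proteome_and_annotations()
        cont = build_go_contingency(ann, proteome)
        filtered = filter_generic_terms(screen_go_terms(cont))
        shuffled = filtered.copy()
        random.Random(0).shuffle(shuffled)
        a = select_best_terms(filtered)
        b = select_best_terms(shuffled)
        assert a.best_n == b.best_n
        assert a.best_f == b.best_f
        assert a.parents == b.parents
        assert a.coverage == b.coverage

    def test_planted_structure_recovered(self):
        """Three disjoint planted (term, residue) biases at fold >= 3 with
        n >= 40 are screened and all selected as BestN."""
        for seed in range(5):
            biases = [PlantedBias("GO:P1", "S", 0.45, 45),
                      PlantedBias("GO:P2", "L", 0.45, 45),
                      PlantedBias("GO:P3", "D", 0.45, 45)]
            proteome, gaf_rows, _ = simulate_proteome(
                n_proteins=700, planted_go_biases=biases,
                n_decoy_terms=30, seed=seed)
            ann = GOAnnotationSet(domain="component")
            for row in gaf_rows:
                ann.terms.setdefault(row["term_id"], set()).add(
                    row["accession"])
            cont = build_go_contingency(ann, proteome)
            report = select_best_terms(
                filter_generic_terms(screen_go_terms(cont)))
            assert {"GO:P1", "GO:P2", "GO:P3"} <= set(report.best_n), seed

    def test_bestn_overlap_invariant(self):
        proteome, ann = _abc_proteome_and_annotations()
        cont = build_go_contingency(ann, proteome)
        report = select_best_terms(
            filter_generic_terms(screen_go_terms(cont)))
        sets = {t: cont.term_members[t] for t in report.best_n}
        for a, b in itertools.combinations(report.best_n, 2):
            inter = len(sets[a] & sets[b])
            assert inter / min(len(sets[a]), len(sets[b])) < 0.40


class TestPositionalSpecificity:
    def test_subset_equal_reference_not_flagged(self):
        records = [make_protein(i, RESIDUES[i % 20]) for i in range(60)]
        profile, flag = positional_specificity_check(
            records, records, residue="S", positions=range(1, 11))
        assert not flag
        assert (profile.fillna(0.0) == 0.0).all()

    def test_bias_only_at_position_two_not_flagged(self):
        rng = np.random.default_rng(2)
        reference = []
        for i in range(1500):
            body = "".join(np.array(list(RESIDUES))[
                rng.integers(0, 20, size=30)])
            reference.append(ProteinRecord(f"P{i:04d}", "M" + body))
        subset = []
        for rec in reference[:150]:
            seq = list(rec.sequence)
            if rng.random() < 0.5:
                seq[1] = "S"
            subset.append(ProteinRecord(rec.accession, "".join(seq)))
        reference = subset + reference[150:]
        _, flag = positional_specificity_check(
            subset, reference, residue="S", positions=range(1, 31))
        assert not flag

    def test_broad_bias_flagged(self):
        rng = np.random.default_rng(3)
        reference = []
        for i in range(1500):
            body = "".join(np.array(list(RESIDUES))[
                rng.integers(0, 20, size=30)])
            reference.append(ProteinRecord(f"P{i:04d}", "M" + body))
        subset = []
        for rec in reference[:150]:
            seq = list(rec.sequence)
            for pos in range(2, 31):
                if rng.random() < 0.5:
                    seq[pos - 1] = "S"
            subset.append(ProteinRecord(rec.accession, "".join(seq)))
        reference = subset + reference[150:]
        _, flag = positional_specificity_check(
            subset, reference, residue="S", positions=range(1, 31))
        assert flag
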