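"""Region partition, HVR form/isoform assignment, neighbor-joining trees."""

import numpy as np
import pytest

from flagdiv.hvr_typing import (alignable, assign_hvr_forms, nj_tree,
                                partition_gene, score_distance_matrix)
from flagdiv.sequence_model import SequenceRecord
from oracles import newick_leaf_distances, random_additive_tree

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPartitionGene:
    def test_gene_partition_lengths(self):
        rng = np.random.default_rng(0)
        rec = SequenceRecord(id="g", residues=random_dna(rng, 1758),
                             kind="dna")
        part = partition_gene(rec)
        assert (len(part.conserved5), len(part.variable),
                len(part.conserved3)) == (570, 888, 300)
        assert part.restore() == rec.residues

    def test_minimal_variable_region(self):
        rng = np.random.default_rng(1)
        rec = SequenceRecord(id="g", residues=random_dna(rng, 871),
                             kind="dna")
        assert len(partition_gene(rec).variable) == 1

    def test_no_variable_region_is_error(self):
        rng = np.random.default_rng(2)
        rec = SequenceRecord(id="g", residues=random_dna(rng, 870),
                             kind="dna")
        with pytest.raises(ValueError, match="871"):
            partition_gene(rec)

    def test_protein_mode_boundaries(self):
        rng = np.random.default_rng(3)
        rec = SequenceRecord(id="p", residues=random_protein(rng, 450))
        part = partition_gene(rec)
        assert (len(part.conserved5), len(part.conserved3)) == (190, 100)
        assert part.boundaries == (190, 350)


class TestAlignable:
    def test_identical_regions(self):
        rng = np.random.default_rng(4)
        v = random_protein(rng, 120)
        assert alignable(v, v)

    def test_score_zero_pair(self):
        assert not alignable("G" * 50, "W" * 50)

    def test_empty_region_error(self):
        with pytest.raises(ValueError, match="empty"):
            alignable("", "MKF")

    def test_panel_dual_level_separation(self, panel):
        """Within-form SNP isoforms alignable; cross-form pairs are not."""
        truth = panel.truth
        focal = truth[truth.category == "flagellin"]
        sp = focal.species.iloc[0]
        focal = focal[focal.species == sp]
        recs = {r.id: r for r in panel.proteins}
        var = {row.record_id: recs[row.record_id].residues[
            row.var_start:row.var_end] for row in focal.itertuples()}
        by_form: dict[str, list[str]] = {}
        for row in focal.itertuples():
            by_form.setdefault(row.form_id, []).append(row.record_id)
        forms = sorted(by_form)
        # within-form pairs
        for form in forms[:6]:
            ids = by_form[form]
            for a, b in zip(ids, ids[1:]):
                assert alignable(var[a], var[b])
        # cross-form pairs
        for fa, fb in zip(forms, forms[1:]):
            assert not alignable(var[by_form[fa][0]], var[by_form[fb][0]])


class TestAssignForms:
    def test_non_alignable_regions_become_singletons(self):
        rng = np.random.default_rng(5)
        regions = {random_protein(rng, 100): [f"r{i}"] for i in range(6)}
        forms = assign_hvr_forms(regions)
        assert len(forms) == 6
        assert all(len(f.isoforms) == 1 for f in forms)

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(6)
        a = random_protein(rng, 100)
        c = random_protein(rng, 100)
        b = a[:50] + c[50:]  # alignable to both halves, a vs c unrelated
        assert alignable(a, b) and alignable(b, c) and not alignable(a, c)
        forms = assign_hvr_forms({a: ["ra"], b: ["rb"], c: ["rc"]})
        assert len(forms) == 1
        assert {i for f in forms for iso in f.isoforms
                for i in iso.member_ids} == {"ra", "rb", "rc"}

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        regions = {}
        for i in range(5):
            anc = random_protein(rng, 90)
            regions[anc] = [f"f{i}a"]
            snp = list(anc)
            snp[10] = "A" if snp[10] != "A" else "C"
            regions["".join(snp)] = [f"f{i}b"]
        forms1 = assign_hvr_forms(dict(regions))
        forms2 = assign_hvr_forms(dict(reversed(list(regions.items()))))
        as_sets = lambda forms: [(f.form_id,
                                  frozenset(iso.sequence
                                            for iso in f.isoforms))
                                 for f in forms]
        assert as_sets(forms1) == as_sets(forms2)

    def test_panel_form_and_isoform_truth(self, panel):
        truth = panel.truth
        focal_sp = truth[truth.category == "flagellin"] \
            .species.value_counts().idxmax()
        focal = truth[truth.species == focal_sp]
        recs = {r.id: r for r in panel.proteins}
        regions: dict[str, list[str]] = {}
        for row in focal.itertuples():
            v = recs[row.record_id].residues[row.var_start:row.var_end]
            regions.setdefault(v, []).append(row.record_id)
        forms = assign_hvr_forms(regions)
        assert len(forms) == 26
        truth_forms = {}
        truth_iso = {}
        for row in focal.itertuples():
            truth_forms.setdefault(row.form_id, set()).add(row.record_id)
            truth_iso.setdefault(row.isoform_id, set()).add(row.record_id)
        pred_forms = {frozenset(r for iso in f.isoforms
                                for r in iso.member_ids) for f in forms}
        pred_iso = {frozenset(iso.member_ids)
                    for f in forms for iso in f.isoforms}
        assert pred_forms == {frozenset(v) for v in truth_forms.values()}
        assert pred_iso == {frozenset(v) for v in truth_iso.values()}


class TestNjTree:
    def test_four_taxon_additive_recovery(self):
        # tree: (A:1,B:2):0.5 joined to (C:3,D:4)
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0.0, 3.0, 4.5, 5.5],
            [3.0, 0.0, 5.5, 6.5],
            [4.5, 5.5, 0.0, 7.0],
            [5.5, 6.5, 7.0, 0.0],
        ])
        newick = nj_tree(labels, d)
        got = newick_leaf_distances(newick)
        for i in range(4):
            for j in range(i + 1, 4):
                pair = frozenset((labels[i], labels[j]))
                assert got[pair] == pytest.approx(d[i, j], abs=1e-6)

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 2.0, 3.0],
                      [2.0, 0.0, 3.0],
                      [3.0, 3.0, 0.0]])
        newick = nj_tree(["A", "B", "C"], d)
        got = newick_leaf_distances(newick)
        assert got[frozenset(("A", "B"))] == pytest.approx(2.0, abs=1e-6)
        assert got[frozenset(("A", "C"))] == pytest.approx(3.0, abs=1e-6)

    def test_random_additive_trees_recovered(self):
        """NJ reproduces random additive trees up to n=8 exactly."""
        rng = np.random.default_rng(1234)
        for n in (4, 5, 6, 7, 8):
            for _ in range(3):
                labels, d = random_additive_tree(n, rng)
                got = newick_leaf_distances(nj_tree(labels, d))
                for i in range(n):
                    for j in range(i + 1, n):
                        pair = frozenset((labels[i], labels[j]))
                        assert got[pair] == pytest.approx(d[i, j], abs=1e-5)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(["A", "B"], np.zeros((2, 2)))

    def test_isoforms_group_within_forms(self, panel):
        """Score-derived distances cluster isoforms inside their form."""
        truth = panel.truth
        focal_sp = truth[truth.category == "flagellin"] \
            .species.value_counts().idxmax()
        focal = truth[truth.species == focal_sp]
        recs = {r.id: r for r in panel.proteins}
        # two isoforms from each of three forms
        chosen: dict[str, list] = {}
        for row in focal.itertuples():
            chosen.setdefault(row.form_id, []).append(row)
            if len(chosen) >= 3 and all(len(v) >= 2
                                        for v in list(chosen.values())[:3]):
                pass
        forms = [f for f, rows in chosen.items() if len(rows) >= 2][:3]
        seqs = {}
        form_of = {}
        for f in forms:
            for row in chosen[f][:2]:
                v = recs[row.record_id].residues[row.var_start:row.var_end]
                seqs[row.record_id] = v
                form_of[row.record_id] = f
        ids, dmat = score_distance_matrix(seqs)
        # within-form distances are far below cross-form distances
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                b = ids[j]
                if form_of[a] == form_of[b]:
                    assert dmat[i, j] < 0.3
                else:
                    assert dmat[i, j] > 0.7
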