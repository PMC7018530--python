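"""Domain scanning, flagellin/FlgL classification, fishing, and the funnel."""

import numpy as np
import pytest

from flagdiv.curation import (ARCHAEAL, BACTERIAL, FLGL_LIKE, NON_FLAGELLIN,
                              ARCH_FLAG, FLAG_C, FLAG_N, DomainHit,
                              DomainModel, classify_flagellin, classify_record,
                              curate, fish_homologs, read_pssm, scan_domains,
                              write_pssm)
from flagdiv.sequence_model import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="module")
def n_model(rng):
    consensus = random_protein(rng, 40)
    model = DomainModel.from_sequences(FLAG_N, [consensus],
                                       expected_terminus="N")
    model.min_score = 0.5 * model.consensus_score
    return model


class TestScanDomains:
    def test_consensus_scores_column_maxima_sum(self, n_model):
        protein = n_model.consensus + "A" * 60
        rec = SequenceRecord(id="x", residues=protein)
        hits = scan_domains(rec, [n_model])
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(n_model.consensus_score)
        assert (hits[0].start, hits[0].end) == (0, len(n_model))

    def test_short_protein_no_hit(self, n_model):
        rec = SequenceRecord(id="x", residues="MKFLV")
        assert scan_domains(rec, [n_model]) == []

    def test_wrong_terminus_rejected(self, n_model):
        # consensus placed in the C-terminal half of a long protein
        rec = SequenceRecord(id="x", residues="A" * 200 + n_model.consensus)
        assert scan_domains(rec, [n_model]) == []

    def test_random_proteins_rarely_hit(self, n_model):
        """Null distribution: random windows stay far below half-consensus."""
        trial_rng = np.random.default_rng(2024)
        hits = sum(
            bool(scan_domains(
                SequenceRecord(id=f"r{i}",
                               residues=random_protein(trial_rng, 100)),
                [n_model]))
            for i in range(200)
        )
        assert hits < 2  # no-hit probability > 0.99


class TestClassify:
    def _hit(self, domain_id):
        return DomainHit(domain_id, 50.0, 0, 10)

    @pytest.mark.parametrize("domains,flgl,flag,expected", [
        ([FLAG_N, FLAG_C], 10.0, 30.0, BACTERIAL),
        ([FLAG_N, FLAG_C], 30.0, 10.0, FLGL_LIKE),
        ([FLAG_N, FLAG_C], 30.0, 30.0, BACTERIAL),   # tie -> flagellin
        ([ARCH_FLAG], 0.0, 0.0, ARCHAEAL),
        ([FLAG_N], 0.0, 50.0, NON_FLAGELLIN),        # one domain is not enough
        ([FLAG_C], 0.0, 50.0, NON_FLAGELLIN),
        ([], 0.0, 0.0, NON_FLAGELLIN),
    ])
    def test_rules(self, domains, flgl, flag, expected):
        hits = [self._hit(d) for d in domains]
        assert classify_flagellin(hits, flgl_score=flgl,
                                  flagellin_score=flag) == expected

    def test_panel_truth_recovered(self, panel):
        expected = {"flagellin": BACTERIAL, "archaeal": ARCHAEAL,
                    "flgl_decoy": FLGL_LIKE, "random": NON_FLAGELLIN}
        truth = dict(zip(panel.truth.record_id, panel.truth.category))
        for rec in panel.proteins:
            assert classify_record(rec, panel.models) == \
                expected[truth[rec.id]], rec.id

    def test_low_divergence_panel_perfect_sensitivity_specificity(
            self, small_panel):
        truth = dict(zip(small_panel.truth.record_id,
                         small_panel.truth.category))
        tp = fp = fn = tn = 0
        for rec in small_panel.proteins:
            called = classify_record(rec, small_panel.models) in (BACTERIAL,
                                                                  ARCHAEAL)
            is_flag = truth[rec.id] in ("flagellin", "archaeal")
            tp += called and is_flag
            fp += called and not is_flag
            fn += (not called) and is_flag
            tn += (not called) and not is_flag
        assert fp == 0 and fn == 0
        assert tp > 0 and tn > 0


class TestFishing:
    def test_identical_to_seed_fished(self, rng):
        seed = SequenceRecord(id="s", residues=random_protein(rng, 80))
        twin = SequenceRecord(id="p", residues=seed.residues)
        assert fish_homologs([seed], [twin], min_bsr=0.99) == [twin]

    def test_no_alignment_not_fished(self):
        seed = SequenceRecord(id="s", residues="GGGGGGGGGG")
        cand = SequenceRecord(id="p", residues="WWWWWWWWWW")
        assert fish_homologs([seed], [cand], min_bsr=0.1) == []

    def test_empty_seeds_error(self):
        with pytest.raises(ValueError, match="seed"):
            fish_homologs([], [], min_bsr=0.4)

    def test_panel_pool_recovered_exactly(self, panel, rng):
        """Same-species flagellins are fished; unrelated randoms are not."""
        flag = panel.truth[panel.truth.category == "flagellin"]
        focal = flag[flag.species == flag.species.iloc[0]].record_id
        members = [r for r in panel.proteins if r.id in set(focal)]
        seeds, pool_flag = members[: len(members) // 2], members[len(members) // 2:]
        pool_rand = [SequenceRecord(id=f"rand{i}",
                                    residues=random_protein(rng, 400))
                     for i in range(10)]
        fished = fish_homologs(seeds, pool_flag[:10] + pool_rand, min_bsr=0.4)
        assert [r.id for r in fished] == [r.id for r in pool_flag[:10]]


class TestCurate:
    def test_exclusion_list_overrides_acceptance(self, small_panel):
        flag_id = small_panel.truth[
            small_panel.truth.category == "flagellin"].record_id.iloc[0]
        report = curate(small_panel.proteins, small_panel.models,
                        exclusion_ids={flag_id})
        assert flag_id not in report.accepted
        assert (flag_id, "exclusion_list", "listed") in report.rejected

    def test_all_decoys_rejected(self, rng, n_model):
        decoys = [SequenceRecord(id=f"d{i}",
                                 residues=random_protein(rng, 200))
                  for i in range(10)]
        report = curate(decoys, [n_model])
        assert report.accepted == {}
        assert len(report.rejected) == 10
        assert {r[1] for r in report.rejected} <= {"domain_filter",
                                                   "flgl_filter"}

    def test_mixed_panel_matches_truth(self, panel):
        report = curate(panel.proteins, panel.models)
        truth = dict(zip(panel.truth.record_id, panel.truth.category))
        for rid, cat in report.accepted.items():
            assert truth[rid] == ("flagellin" if cat == BACTERIAL
                                  else "archaeal")
        for rid, stage, _ in report.rejected:
            assert truth[rid] in ("flgl_decoy", "random")
            assert stage == ("flgl_filter" if truth[rid] == "flgl_decoy"
                             else "domain_filter")

    def test_record_conservation(self, panel):
        report = curate(panel.proteins, panel.models)
        accounted = set(report.accepted) | {r[0] for r in report.rejected}
        assert accounted == {r.id for r in panel.proteins}
        assert len(report.accepted) + len(report.rejected) == \
            len(panel.proteins)

    def test_threshold_monotonicity(self, small_panel):
        """Raising every min_score never grows the accepted set."""
        import copy

        baseline = curate(small_panel.proteins, small_panel.models)
        prev = len(baseline.accepted)
        for factor in (1.3, 1.8, 2.5):
            models = copy.deepcopy(small_panel.models)
            for m in models:
                m.min_score *= factor
            cur = len(curate(small_panel.proteins, models).accepted)
            assert cur <= prev
            prev = cur


class TestPssmIO:
    def test_round_trip(self, tmp_path, n_model):
        path = tmp_path / "flag_n.tsv"
        write_pssm(n_model, path)
        back = read_pssm(path)
        assert back.domain_id == n_model.domain_id
        assert back.expected_terminus == n_model.expected_terminus
        assert back.min_score == pytest.approx(n_model.min_score)
        np.testing.assert_allclose(back.pssm, n_model.pssm, atol=1e-4)
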