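"""Distance-map pipeline: PDB parsing, alignment, filtering, correlation."""

import numpy as np
import pytest

from ppibench.distmap import (
    AlignScoring,
    CandidateEntry,
    ChainStructure,
    compare_maps,
    filter_candidates,
    local_align,
    map_comparison_pipeline,
    parse_structure,
    real_distance_map,
    extract_predicted_map,
)
from ppibench.estimators import MapCapabilityError, RandomForestPairClassifier
from ppibench.synthetic import NegatedMapMock, generate_complex


def chain(coords, seq=None, chain_id="A"):
    coords = np.asarray(coords, float)
    seq = seq or "A" * len(coords)
    return ChainStructure(chain_id, seq, coords, np.isfinite(coords).all(axis=1))


class TestParseStructure:
    def test_two_chain_file(self, small_dataset, small_config):
        recs = small_dataset[0]
        _, pdb_text = generate_complex((recs[0], recs[1]), small_config)
        chains = parse_structure(pdb_text)
        assert [c.chain_id for c in chains] == ["A", "B"]
        assert chains[0].resolved_mask.all()

    def test_hetatm_only_rejected(self):
        text = (
            "HETATM    1  O   HOH A   1      0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="ATOM"):
            parse_structure(text)

    def test_modified_residue_mapped_to_parent(self):
        text = (
            "ATOM      1  CA  MSE A   1      0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  XYZ A   2      3.800   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        (c,) = parse_structure(text)
        assert c.sequence == "MX"


class TestRealDistanceMap:
    def test_worked_example(self):
        c1 = chain([[0, 0, 0], [3, 4, 0]])
        c2 = chain([[0, 0, 5], [0, 0, 10]], chain_id="B")
        d = real_distance_map(c1, c2)
        np.testing.assert_allclose(
            d, [[5.0, 10.0], [7.0711, 11.1803]], atol=1e-4
        )

    def test_swap_transposes(self, rng):
        c1 = chain(rng.standard_normal((4, 3)))
        c2 = chain(rng.standard_normal((6, 3)), chain_id="B")
        np.testing.assert_allclose(
            real_distance_map(c1, c2), real_distance_map(c2, c1).T, atol=1e-12
        )

    def test_matches_double_loop_oracle(self, rng):
        a, b = rng.standard_normal((5, 3)), rng.standard_normal((7, 3))
        d = real_distance_map(chain(a), chain(b, chain_id="B"))
        for i in range(5):
            for j in range(7):
                assert abs(d[i, j] - np.linalg.norm(a[i] - b[j])) < 1e-12

    def test_unresolved_residue_yields_nan(self):
        coords = np.array([[0.0, 0, 0], [np.nan, np.nan, np.nan]])
        d = real_distance_map(chain(coords), chain([[1.0, 0, 0]], chain_id="B"))
        assert np.isfinite(d[0, 0]) and np.isnan(d[1, 0])

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            real_distance_map(
                ChainStructure("A", "", np.zeros((0, 3)), np.zeros(0, bool)),
                chain([[0.0, 0, 0]]),
            )


def sw_matrix_oracle(q, t, match=2.0, mismatch=-1.0, gap=-2.0):
    """Textbook Smith-Waterman DP with linear gaps; returns the max score."""
    H = np.zeros((len(q) + 1, len(t) + 1))
    for i in range(1, len(q) + 1):
        for j in range(1, len(t) + 1):
            sub = match if q[i - 1] == t[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, H[i - 1, j] + gap, H[i, j - 1] + gap)
    return H.max()


class TestLocalAlign:
    SIMPLE = AlignScoring(matrix=None, match=2.0, mismatch=-1.0,
                          gap_open=-2.0, gap_extend=-2.0)

    def test_identity_mapping_and_score(self):
        mapping, score = local_align("MKLVAQWERT", "MKLVAQWERT", self.SIMPLE)
        assert mapping == [(i, i) for i in range(10)]
        assert score == 20.0

    def test_offset_mapping_matches_dp_oracle(self):
        mapping, score = local_align("MKLVA", "XXMKIVAXX", self.SIMPLE)
        assert score == sw_matrix_oracle("MKLVA", "XXMKIVAXX")
        offsets = {t - q for q, t in mapping}
        assert offsets == {2}

    def test_random_scores_match_dp_oracle(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            q = "".join(rng.choice(aas, size=rng.integers(5, 15)))
            t = "".join(rng.choice(aas, size=rng.integers(5, 20)))
            _, score = local_align(q, t, self.SIMPLE)
            assert score == sw_matrix_oracle(q, t)

    def test_disjoint_alphabets_empty_mapping(self):
        mapping, score = local_align("MMMM", "KKKK", self.SIMPLE)
        assert mapping == [] and score == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MKL")

    def test_blosum62_default_runs(self):
        mapping, score = local_align("MKLVAQWERT", "MKLVAQWERT")
        assert len(mapping) == 10 and score > 0


class TestFilterCandidates:
    @staticmethod
    def entry(score=0.95, n_entities=2, extra=False, seqs=("MKLVAQWERT", "ACDEFGHIKL"),
              queries=None, pair=("P1", "P2")):
        return CandidateEntry(
            pair=pair,
            score=score,
            structure_id="1ABC",
            n_polymer_entities=n_entities,
            has_extra_entities=extra,
            chain_sequences=seqs,
            query_sequences=queries or seqs,
        )

    def test_confidence_threshold_strict(self):
        entries = [self.entry(score=s) for s in (0.95, 0.90, 0.85)]
        retained, excluded = filter_candidates(entries, confidence=0.9)
        assert [e.score for e in retained] == [0.95]
        assert [reason for _, reason in excluded] == ["low_confidence"] * 2

    def test_homomer_excluded(self):
        e = self.entry(seqs=("MKLVAQWERT", "MKLVAQWERT"))
        retained, excluded = filter_candidates([e])
        assert retained == [] and excluded[0][1] == "homomer"

    def test_extra_entities_excluded(self):
        for e in (self.entry(n_entities=3), self.entry(extra=True)):
            retained, excluded = filter_candidates([e])
            assert excluded[0][1] == "extra_entities"

    def test_low_coverage_excluded(self):
        e = self.entry(queries=("MKLVAQWERTMKLVAQWERTMKLVAQWERT", "ACDEFGHIKL"),
                       seqs=("MKLVAQWERT"[:4], "ACDEFGHIKL"))
        retained, excluded = filter_candidates([e], min_coverage=0.4)
        assert excluded[0][1] == "low_coverage"

    def test_cohort_matches_rule_by_rule_oracle(self, rng):
        """Synthetic cohort: the retained set equals an explicit rule oracle."""
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        entries = []
        for k in range(30):
            seq_a = "".join(rng.choice(aas, size=20))
            seq_b = "".join(rng.choice(aas, size=20))
            homomer = k % 7 == 0
            entries.append(self.entry(
                score=float(rng.uniform(0.8, 1.0)),
                n_entities=int(rng.choice([2, 2, 3])),
                extra=bool(rng.random() < 0.2),
                seqs=(seq_a, seq_a if homomer else seq_b),
                pair=(f"P{k}", f"Q{k}"),
            ))
        retained, excluded = filter_candidates(entries, confidence=0.9)
        expected = [
            e for e in entries
            if e.score > 0.9 and e.n_polymer_entities == 2
            and not e.has_extra_entities
            and e.chain_sequences[0] != e.chain_sequences[1]
        ]  # coverage is trivially full here (queries == chains)
        assert [e.pair for e in retained] == [e.pair for e in expected]
        assert len(retained) + len(excluded) == 30


class TestCompareMaps:
    def test_self_comparison_is_one(self, rng):
        m = rng.random((6, 5))
        idx1 = [(i, i) for i in range(6)]
        idx2 = [(j, j) for j in range(5)]
        comp = compare_maps(m, m, idx1, idx2)
        assert comp.pearson_r == pytest.approx(1.0)
        assert comp.n_overlap == 30

    def test_negated_comparison_is_minus_one(self, rng):
        m = rng.random((4, 4))
        idx = [(i, i) for i in range(4)]
        comp = compare_maps(m, 3.0 - m, idx, idx)
        assert comp.pearson_r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        pred, real = rng.random((5, 7)), rng.random((5, 7))
        idx1 = [(i, i) for i in range(5)]
        idx2 = [(j, j) for j in range(7)]
        comp = compare_maps(pred, real, idx1, idx2)
        x, y = pred.ravel(), real.ravel()
        xc, yc = x - x.mean(), y - y.mean()
        expect = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert abs(comp.pearson_r - expect) < 1e-12

    def test_constant_map_flagged_degenerate(self):
        idx = [(i, i) for i in range(3)]
        comp = compare_maps(np.ones((3, 3)), np.random.rand(3, 3), idx, idx)
        assert comp.degenerate and np.isnan(comp.pearson_r)

    def test_out_of_bounds_alignment_rejected(self, rng):
        m = rng.random((4, 4))
        with pytest.raises(IndexError):
            compare_maps(m, m, [(0, 0), (9, 1)], [(0, 0), (1, 1)])

    def test_fuzzed_alignments_never_index_outside(self, rng):
        for _ in range(100):
            p = rng.random((rng.integers(3, 10), rng.integers(3, 10)))
            r = rng.random((rng.integers(3, 10), rng.integers(3, 10)))
            n1 = rng.integers(2, min(p.shape[0], r.shape[0]) + 1)
            n2 = rng.integers(2, min(p.shape[1], r.shape[1]) + 1)
            idx1 = list(zip(
                rng.choice(p.shape[0], n1, replace=False),
                rng.choice(r.shape[0], n1, replace=False),
            ))
            idx2 = list(zip(
                rng.choice(p.shape[1], n2, replace=False),
                rng.choice(r.shape[1], n2, replace=False),
            ))
            comp = compare_maps(p, r, idx1, idx2)
            assert comp.n_overlap == n1 * n2


class TestEndToEnd:
    def test_negated_mock_correlation_monotone_in_noise(
        self, small_dataset, small_config
    ):
        recs = small_dataset[0]
        cplx, pdb_text = generate_complex((recs[0], recs[1]), small_config)
        correlations = []
        for sigma in (0.01, 1.0, 10.0):
            mock = NegatedMapMock(cplx.true_map, noise_sd=sigma, seed=1)
            comp = map_comparison_pipeline(
                mock, None, None,
                (recs[0].sequence, recs[1].sequence), pdb_text,
            )
            correlations.append(comp.pearson_r)
        assert correlations[0] < -0.99
        assert correlations[0] < correlations[1] < correlations[2]

    def test_chain_order_invariance_up_to_transposition(
        self, small_dataset, small_config
    ):
        recs = small_dataset[0]
        cplx, pdb_text = generate_complex((recs[0], recs[1]), small_config)
        chains = parse_structure(pdb_text)
        d12 = real_distance_map(chains[0], chains[1])
        d21 = real_distance_map(chains[1], chains[0])
        np.testing.assert_allclose(d12, d21.T, atol=1e-12)

    def test_map_capability_error_for_maples_families(self):
        with pytest.raises(MapCapabilityError):
            extract_predicted_map(RandomForestPairClassifier(), None, None)

    def test_dscript_map_extraction(self, rng):
        from ppibench.models import DScriptNet

        net = DScriptNet(16, d=8, h=4, seed=0)
        net.exposes_map = True
        a, b = rng.standard_normal((12, 16)), rng.standard_normal((14, 16))
        m1, s1 = extract_predicted_map(net, a, b)
        m2, s2 = extract_predicted_map(net, a, b)
        assert (m1 >= 0).all()
        assert m1.shape == (12 - 4, 14 - 4)  # two stride-1 valid convolutions
        np.testing.assert_array_equal(m1, m2)
        assert s1 == s2
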