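import numpy as np
import pandas as pd
import pytest

from aavep.descriptors import residue_vector
from aavep.domains import DomainPartition
from aavep.encoding import (
    DescriptorEncoder,
    FeatureMatrix,
    build_matrix,
    encode_domains,
    encode_full,
    pca_variance,
    standardize,
)
from aavep.variants import ProteinSequence, VariantRecord, apply_variant

RESIDUES = "ARNDCQEGHILKMFPSTWYV"


def random_sequence(rng, n):
    return ProteinSequence("s", "".join(rng.choice(list(RESIDUES), size=n)))


class TestEncodeFull:
    def test_homopolymer_equals_residue_vector(self, z3):
        vec = encode_full(ProteinSequence("s", "AAAA"), [z3])
        assert np.allclose(vec.values, residue_vector(z3, "A"))

    def test_two_residue_mean_matches_hand_average(self, z3):
        # mean of A (0.07,-1.73,0.09) and L (-4.19,-1.03,-0.98) from fixture
        vec = encode_full(ProteinSequence("s", "AL"), [z3])
        assert vec.values == pytest.approx([-2.06, -1.38, -0.445])

    def test_permutation_invariance(self, z3, rng):
        seq = random_sequence(rng, 30)
        perm = ProteinSequence("p", "".join(rng.permutation(list(seq.residues))))
        assert np.allclose(encode_full(seq, [z3]).values, encode_full(perm, [z3]).values)

    def test_full_registry_gives_75_named_features(self):
        vec = encode_full(ProteinSequence("s", "ACD"))
        assert len(vec) == 75 and vec.index.is_unique

    def test_unsupported_residue_names_position(self, z3):
        with pytest.raises(Exception, match="position 2"):
            encode_full(ProteinSequence("s", "AXA"), [z3])


class TestEncodeDomains:
    def test_single_domain_equals_full(self, z3, rng):
        seq = random_sequence(rng, 12)
        p = DomainPartition("s", (), 12)
        assert np.allclose(encode_domains(seq, p, z3).values, encode_full(seq, [z3]).values)

    def test_two_domain_toy(self, z3):
        seq = ProteinSequence("s", "AALL")
        vec = encode_domains(seq, DomainPartition("s", (3,), 4), z3)
        assert list(vec.index) == ["d1.z1", "d1.z2", "d1.z3", "d2.z1", "d2.z2", "d2.z3"]
        assert np.allclose(vec.values[:3], residue_vector(z3, "A"))
        assert np.allclose(vec.values[3:], residue_vector(z3, "L"))

    def test_mutation_locality_against_brute_force(self, z3, rng):
        """A point mutation moves exactly the containing domain's features,
        by (alt-wt)/domain_length; checked on 100 random sequences."""
        for _ in range(100):
            n = int(rng.integers(12, 60))
            seq = random_sequence(rng, n)
            cuts = np.sort(rng.choice(np.arange(2, n + 1), size=3, replace=False))
            p = DomainPartition("s", tuple(int(c) for c in cuts), n)
            pos = int(rng.integers(1, n + 1))
            wt = seq.residues[pos - 1]
            alt = rng.choice([r for r in RESIDUES if r != wt])
            mut = apply_variant(seq, VariantRecord("s", pos, wt, alt))
            before, after = encode_domains(seq, p, z3), encode_domains(mut, p, z3)
            diff = after.values - before.values
            k = p.domain_of(pos)
            start, end = p.ranges()[k - 1]
            length = end - start + 1
            expected = (residue_vector(z3, alt) - residue_vector(z3, wt)) / length
            for d in range(p.n_domains):
                block = diff[3 * d : 3 * d + 3]
                if d == k - 1:
                    assert np.allclose(block, expected, atol=1e-12)
                else:
                    assert np.allclose(block, 0.0)

    def test_full_is_length_weighted_mean_of_domains(self, z3, rng):
        seq = random_sequence(rng, 40)
        p = DomainPartition("s", (11, 25), 40)
        dom = encode_domains(seq, p, z3).values.reshape(3, 3)
        lengths = np.array([e - s + 1 for s, e in p.ranges()])
        weighted = (dom * lengths[:, None]).sum(axis=0) / lengths.sum()
        assert np.allclose(weighted, encode_full(seq, [z3]).values)


class TestBuildMatrix:
    @pytest.fixture
    def toy(self):
        wts = [ProteinSequence("w1", "ACDEFGHIKL"), ProteinSequence("w2", "MNPQRSTVWY")]
        variants = [
            VariantRecord("w1", 1, "A", "V", "pathogenic"),
            VariantRecord("w1", 5, "F", "L", "benign"),
            VariantRecord("w2", 2, "N", "K", "pathogenic"),
            VariantRecord("w2", 3, "A", "G", "benign"),  # wt mismatch: position 3 is P
        ]
        return wts, variants

    def test_row_count_and_drop_log(self, toy):
        wts, variants = toy
        m = build_matrix(wts, variants, mode="full")
        assert m.data.shape[0] == 5  # 2 wild types + 3 surviving mutants
        assert m.provenance["wt_mismatch"] == 1

    def test_wildtypes_labeled_benign(self, toy):
        wts, variants = toy
        m = build_matrix(wts, variants, mode="full")
        assert m.labels.loc["w1"] == 0 and m.labels.loc["w2"] == 0
        assert m.labels.loc["w1:A1V"] == 1

    def test_duplicates_deduplicated_with_log(self, toy):
        wts, variants = toy
        m = build_matrix(wts, variants + [variants[0]], mode="full")
        assert m.data.shape[0] == 5
        assert m.provenance["duplicate"] == 1

    def test_zero_variants_single_wildtype(self):
        m = build_matrix([ProteinSequence("w", "ACDEF")], [], mode="full")
        assert m.data.shape[0] == 1 and m.labels.iloc[0] == 0

    def test_domainwise_mode_feature_order(self, family, strong_matrix):
        names = strong_matrix.feature_names
        assert len(names) == 36
        expected = [f"d{k}.z{j}" for k in range(1, 13) for j in (1, 2, 3)]
        assert names == expected

    def test_csv_round_trip(self, toy, tmp_path):
        wts, variants = toy
        m = build_matrix(wts, variants, mode="full")
        m.to_csv(tmp_path / "m.tsv")
        back = FeatureMatrix.from_csv(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.data, m.data)
        assert np.array_equal(back.y, m.y)


class TestStandardize:
    def _matrix(self, values, names=None):
        df = pd.DataFrame(values, columns=names or [f"f{i}" for i in range(np.shape(values)[1])])
        return FeatureMatrix(df, pd.Series(np.zeros(len(df)), index=df.index))

    def test_population_scaling(self):
        m = self._matrix([[1.0], [3.0]])
        out, _ = standardize(m)
        assert np.allclose(out.X.ravel(), [-1.0, 1.0])

    def test_constant_column_warns_and_zeroes(self):
        m = self._matrix([[2.0, 1.0], [2.0, 3.0]])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out, _ = standardize(m)
        assert np.allclose(out.X[:, 0], 0.0)

    def test_fit_rows_have_zero_mean(self, strong_matrix):
        out, _ = standardize(strong_matrix)
        assert np.all(np.abs(out.X.mean(axis=0)) < 1e-12)

    def test_heldout_uses_training_parameters(self):
        train = self._matrix([[0.0], [2.0]])
        test = self._matrix([[4.0]])
        _, scaler = standardize(train)
        out, _ = standardize(test, scaler=scaler)
        assert np.allclose(out.X.ravel(), [3.0])  # (4-1)/1


class TestPCAVariance:
    def test_rank_one_matrix(self):
        base = np.outer(np.arange(1, 6, dtype=float), [1.0, 2.0, 3.0])
        m = FeatureMatrix(
            pd.DataFrame(base, columns=list("abc")),
            pd.Series(np.zeros(5)),
        )
        ratios = pca_variance(m)
        assert ratios[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one_and_decrease(self, strong_matrix):
        out, _ = standardize(strong_matrix)
        ratios = pca_variance(out)
        assert np.sum(ratios) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ratios) <= 1e-12)

    def test_isotropic_gaussian_near_equal_ratios(self, rng):
        X = rng.normal(size=(4000, 5))
        m = FeatureMatrix(pd.DataFrame(X, columns=list("abcde")), pd.Series(np.zeros(4000)))
        ratios = pca_variance(m)
        assert np.all(np.abs(ratios - 0.2) < 0.02)

    def test_single_row_rejected(self):
        m = FeatureMatrix(pd.DataFrame([[1.0]], columns=["a"]), pd.Series([0.0]))
        with pytest.raises(ValueError):
            pca_variance(m)


def test_encoder_is_sklearn_compatible(family):
    enc = DescriptorEncoder(mode="domainwise", partitions=family.partitions)
    params = enc.get_params()
    assert params["mode"] == "domainwise"
    enc.set_params(mode="full", partitions=None)
    out = enc.fit(family.wildtypes).transform(family.wildtypes)
    assert out.shape == (len(family.wildtypes), 75)
    assert list(enc.get_feature_names_out()) == list(out.columns)
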