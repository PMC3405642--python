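"""Encoding, train/validation split arithmetic, and the RBF network."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitomatch as mm
from mitomatch.errors import ValidationError
from mitomatch.rbf import (
    DECODING,
    ENCODING,
    RBFModel,
    decode_genotypes,
    fit_rbf,
    read_genotype_tsv,
    train_size,
    validation_accuracy,
    write_genotype_tsv,
)


def cloud_matrix(n_pos, n_neg, pos_vec, neg_vec, loci=None, seed=0):
    """Two point clouds of integer codes, jittered within the code alphabet."""
    rng = np.random.default_rng(seed)
    loci = loci or tuple(range(1, len(pos_vec) + 1))
    rows, labels = [], []
    for i in range(n_pos):
        rows.append(pos_vec)
        labels.append("pos")
    for i in range(n_neg):
        rows.append(neg_vec)
        labels.append("neg")
    codes = np.array(rows, dtype=np.int8)
    ids = tuple(f"s{i:03d}" for i in range(n_pos + n_neg))
    return mm.GenotypeMatrix(ids, loci, codes, tuple(labels))


class TestEncoding:
    def test_row_agct_maps_to_1234(self):
        raw = pd.DataFrame([["A", "G", "C", "T"]], index=["s"], columns=[1, 2, 3, 4])
        gm = mm.encode_genotypes(raw, ["c"])
        assert gm.codes.tolist() == [[1, 2, 3, 4]]

    def test_all_a_matrix(self):
        raw = pd.DataFrame([["A"] * 3] * 2, index=["a", "b"], columns=[1, 2, 3])
        gm = mm.encode_genotypes(raw, ["c", "c"])
        assert (gm.codes == 1).all()

    def test_unknown_letter_becomes_missing(self):
        raw = pd.DataFrame([["A", "N", "-"]], index=["s"], columns=[1, 2, 3])
        gm = mm.encode_genotypes(raw, ["c"])
        assert gm.codes.tolist() == [[1, 0, 0]]

    @given(
        st.lists(
            st.lists(st.sampled_from("ACGT"), min_size=4, max_size=4),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_decode_encode_round_trip(self, letters):
        raw = pd.DataFrame(
            letters,
            index=[f"s{i}" for i in range(len(letters))],
            columns=[10, 20, 30, 40],
        )
        gm = mm.encode_genotypes(raw, ["c"] * len(letters))
        assert decode_genotypes(gm).values.tolist() == letters

    def test_encoding_is_bijection(self):
        assert sorted(ENCODING.values()) == [1, 2, 3, 4]
        assert all(ENCODING[DECODING[v]] == v for v in DECODING)

    def test_genotype_tsv_round_trip(self, tmp_path):
        gm = cloud_matrix(3, 2, [1, 2, 3], [4, 4, 4])
        p = tmp_path / "g.tsv"
        write_genotype_tsv(gm, p, header_lines=["seed: 0"])
        back = read_genotype_tsv(p)
        assert back == gm


class TestSplit:
    @pytest.mark.parametrize("n,n_train", [(96, 64), (112, 75), (3, 2)])
    def test_split_sizes(self, n, n_train):
        labels = ["x"] * n
        train, val = mm.split_train_validation(labels, mm.TrainConfig(seed=5))
        assert len(train) == n_train and len(val) == n - n_train

    def test_partition(self):
        labels = ["a"] * 10 + ["b"] * 7
        train, val = mm.split_train_validation(labels, mm.TrainConfig(seed=1))
        assert sorted(train + val) == list(range(17))
        assert set(train).isdisjoint(val)

    def test_stratified_per_class(self):
        labels = ["a"] * 96 + ["b"] * 112
        train, val = mm.split_train_validation(labels, mm.TrainConfig(seed=2))
        a_train = sum(1 for i in train if labels[i] == "a")
        b_train = sum(1 for i in train if labels[i] == "b")
        assert (a_train, b_train) == (64, 75)

    def test_deterministic_given_seed(self):
        labels = ["a"] * 30 + ["b"] * 30
        c = mm.TrainConfig(seed=9)
        assert mm.split_train_validation(labels, c) == mm.split_train_validation(labels, c)

    def test_class_of_one_rejected(self):
        with pytest.raises(ValidationError):
            mm.split_train_validation(["a", "b", "b"], mm.TrainConfig())

    def test_eight_class_design_total_training_vectors(self):
        """Seven classes of 96 and one of 112 give 64*7 + 75 = 523 vectors."""
        sizes = [96] * 7 + [112]
        assert sum(train_size(n) for n in sizes) == 523


class TestPredict:
    def test_score_at_center_equals_weight(self):
        model = RBFModel(
            centers=np.array([[1.0, 2.0, 3.0]]),
            widths=np.array([1.0]),
            weights=np.array([0.7]),
            bias=0.0,
            loci=(1, 2, 3),
        )
        assert mm.predict(model, [1.0, 2.0, 3.0]) == pytest.approx(0.7)

    def test_zero_weights_zero_everywhere(self):
        model = RBFModel(
            centers=np.array([[0.0, 0.0]]),
            widths=np.array([2.0]),
            weights=np.array([0.0]),
            bias=0.0,
            loci=(1, 2),
        )
        assert mm.predict(model, [3.0, 4.0]) == 0.0

    def test_gaussian_formula_at_distance(self):
        # oracle: hand-computed exp(-d^2/2) for sigma=1, w=1
        model = RBFModel(
            centers=np.array([[0.0, 0.0]]),
            widths=np.array([1.0]),
            weights=np.array([1.0]),
            bias=0.0,
            loci=(1, 2),
        )
        d = 1.3
        raw = model.decision_function(np.array([[d, 0.0]]))[0]
        assert raw == pytest.approx(math.exp(-(d**2) / 2.0), rel=1e-12)

    def test_length_mismatch_rejected(self):
        model = RBFModel(
            centers=np.array([[0.0, 0.0]]),
            widths=np.array([1.0]),
            weights=np.array([1.0]),
            bias=0.0,
            loci=(1, 2),
        )
        with pytest.raises(ValidationError):
            mm.predict(model, [1.0])

    def test_probabilities_clipped_to_unit_interval(self):
        model = RBFModel(
            centers=np.array([[0.0]]),
            widths=np.array([1.0]),
            weights=np.array([5.0]),
            bias=-1.0,
            loci=(1,),
        )
        X = np.linspace(-3, 3, 25).reshape(-1, 1)
        p = model.predict_proba(X)
        assert (p >= 0).all() and (p <= 1).all()


class TestTrain:
    def test_separated_clouds_perfect_validation(self):
        # oracle: nearest-centroid classification separates the clouds
        gm = cloud_matrix(40, 40, [1, 1, 1, 1], [4, 4, 4, 4])
        cfg = mm.TrainConfig(m=2, seed=0)
        model, (train_idx, val_idx) = mm.train_rbf(gm, "pos", cfg)
        assert validation_accuracy(model, gm, val_idx) == 1.0

    def test_auto_grid_reaches_perfect_accuracy(self):
        gm = cloud_matrix(30, 30, [1, 2, 1, 2], [4, 3, 4, 3])
        model, (_, val_idx) = mm.train_rbf(gm, "pos", mm.TrainConfig(seed=3))
        assert validation_accuracy(model, gm, val_idx) == 1.0

    def test_constant_zero_targets_fit_near_zero(self):
        X = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 2.0], [4.0, 1.0]])
        model = fit_rbf(X, np.zeros(4), loci=(1, 2), m=2, seed=0)
        assert np.abs(model.decision_function(X)).max() < 1e-6

    def test_same_seed_bit_identical(self):
        gm = cloud_matrix(20, 20, [1, 2, 3, 4], [4, 3, 2, 1], seed=1)
        cfg = mm.TrainConfig(m=4, seed=11)
        m1, _ = mm.train_rbf(gm, "pos", cfg)
        m2, _ = mm.train_rbf(gm, "pos", cfg)
        assert (m1.weights == m2.weights).all() and m1.bias == m2.bias
        assert (m1.centers == m2.centers).all()

    def test_m_larger_than_training_set_rejected(self):
        gm = cloud_matrix(3, 3, [1, 1], [4, 4])
        with pytest.raises(ValidationError):
            mm.train_rbf(gm, "pos", mm.TrainConfig(m=50, seed=0))

    def test_no_positive_samples_rejected(self):
        gm = cloud_matrix(0, 6, [1, 1], [4, 4])
        with pytest.raises(ValidationError):
            mm.train_rbf(gm, "pos", mm.TrainConfig(m=2, seed=0))

    def test_degenerate_identical_rows_fall_back_to_single_center(self):
        X = np.ones((5, 3))
        model = fit_rbf(X, np.array([1.0, 1, 0, 0, 0]), loci=(1, 2, 3), m=3, seed=0)
        assert model.m == 1


class TestPersistence:
    def test_save_load_exact_round_trip(self, tmp_path):
        gm = cloud_matrix(20, 20, [1, 2, 3, 4], [4, 3, 2, 1])
        model, _ = mm.train_rbf(gm, "pos", mm.TrainConfig(m=4, seed=2))
        p = tmp_path / "model.json"
        model.save(p)
        back = RBFModel.load(p)
        assert (back.centers == model.centers).all()
        assert (back.widths == model.widths).all()
        assert (back.weights == model.weights).all()
        assert back.bias == model.bias and back.loci == model.loci
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        assert back.decision_function(x) == model.decision_function(x)
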