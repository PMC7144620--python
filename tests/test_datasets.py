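"""Decoy labeling protocol, similarity filtering and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocketrank.datasets import (
    ComplexInput,
    LabelingThresholds,
    PairVectorScaler,
    build_dataset,
    cosine_similarity,
    examples_to_arrays,
    label_decoys,
    normalize,
    select_negatives,
    similarity_filter,
    write_manifest,
)
from pocketrank.featurize import pocket_vector

from conftest import pocket_at


class TestCosineSimilarity:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_matches_manual_dot_norm(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.standard_normal(300), rng.standard_normal(300)
            manual = float(np.dot(a, b) / (np.sqrt(np.dot(a, a)) * np.sqrt(np.dot(b, b))))
            assert cosine_similarity(a, b) == pytest.approx(manual, abs=1e-12)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestLabelDecoys:
    @pytest.mark.parametrize(
        "distance,bucket",
        [(0.25, "positives"), (0.5, "excluded_band"), (1.2, "negative_candidates")],
    )
    def test_rule_forced_buckets(self, distance, bucket):
        known = pocket_at([0, 0, 0], pocket_id="known")
        decoy = pocket_at([distance, 0, 0], pocket_id="d")
        part = label_decoys(known, [decoy])
        assert [p.id for p, _ in getattr(part, bucket)] == ["d"]

    @given(st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=1, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_partition_is_exhaustive_and_disjoint(self, distances):
        known = pocket_at([0, 0, 0], pocket_id="known")
        decoys = [pocket_at([d, 0, 0], pocket_id=str(i)) for i, d in enumerate(distances)]
        part = label_decoys(known, decoys)
        ids = [p.id for p, _ in part.positives + part.negative_candidates + part.excluded_band]
        assert sorted(ids) == sorted(str(i) for i in range(len(distances)))
        assert len(part) == len(decoys)

    def test_thresholds_validation(self):
        with pytest.raises(ValueError):
            LabelingThresholds(near_native_max=1.5, negative_min=1.0)


class TestSelectNegatives:
    def test_fewer_than_k_keeps_all(self):
        assert select_negatives(["a", "b"], k=3, seed=0) == ["a", "b"]

    def test_exactly_k_distinct(self):
        chosen = select_negatives(list(range(10)), k=3, seed=1)
        assert len(chosen) == 3 and len(set(chosen)) == 3

    def test_seed_reproducibility(self):
        pool = list(range(50))
        assert select_negatives(pool, 3, seed=42) == select_negatives(pool, 3, seed=42)

    def test_empty_in_empty_out(self):
        assert select_negatives([], k=3, seed=0) == []


class TestSimilarityFilter:
    def test_identical_vector_removed(self, table16):
        p = pocket_at([2, 0, 0], resnames=("GLY", "ALA"))
        v = pocket_vector(p, table16)
        assert similarity_filter([(p, v)], v) == []

    def test_orthogonal_vector_retained(self):
        p = pocket_at([2, 0, 0])
        kept = similarity_filter([(p, np.array([1.0, 0.0]))], np.array([0.0, 1.0]))
        assert len(kept) == 1

    def test_boundary_removes_at_cutoff(self):
        p = pocket_at([2, 0, 0])
        v = np.array([1.0, 1.0])
        assert similarity_filter([(p, v)], v, cutoff=1.0) == []

    def test_zero_norm_retained_with_warning(self, caplog):
        p = pocket_at([2, 0, 0])
        kept = similarity_filter([(p, np.zeros(4))], np.ones(4))
        assert len(kept) == 1

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_raising_cutoff_never_loses_negatives(self, cutoff):
        rng = np.random.default_rng(7)
        known_vec = rng.standard_normal(20)
        entries = [
            (pocket_at([2, 0, 0], pocket_id=str(i)), rng.standard_normal(20))
            for i in range(15)
        ]
        low = similarity_filter(entries, known_vec, cutoff=cutoff)
        high = similarity_filter(entries, known_vec, cutoff=min(1.0, cutoff + 0.2))
        assert len(high) >= len(low)


class TestNormalization:
    def test_fixed_mode_published_constants(self):
        X = np.array([[-0.5696, 30.3048]])
        out = normalize(X, mode="fixed", mean=-0.5696, std=30.8744)
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_self_mode_global_moments(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-50, 50, size=(40, 600))
        out = normalize(X, mode="self")
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_zero_std_errors(self):
        with pytest.raises(ValueError):
            normalize(np.ones((3, 3)), mode="self")

    def test_fixed_requires_params(self):
        with pytest.raises(ValueError):
            normalize(np.ones((2, 2)), mode="fixed")

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 6)) * 30 - 0.5
        scaler = PairVectorScaler(mode="fixed", mean=-0.5696, std=30.8744).fit(X)
        assert np.allclose(scaler.inverse_transform(scaler.transform(X)), X, atol=1e-9)


class TestBuildDataset:
    def test_near_native_strategy_counts(self, table16, toy_complex_factory):
        cx = toy_complex_factory()
        examples = build_dataset(
            [ComplexInput("toy", cx.structure, cx.ligand, cx.decoys)], table16, seed=0
        )
        labels = [e.label for e in examples]
        assert labels.count(1) == 2 and labels.count(0) == 3

    def test_native_strategy_counts(self, table16, toy_complex_factory):
        cx = toy_complex_factory()
        examples = build_dataset(
            [ComplexInput("toy", cx.structure, cx.ligand, cx.decoys)],
            table16,
            strategy="native",
            seed=0,
        )
        labels = [e.label for e in examples]
        assert labels.count(1) == 1 and labels.count(0) == 3
        positive = next(e for e in examples if e.label == 1)
        assert positive.center_distance_nm == 0.0

    def test_duplicate_vector_decoy_filtered(self, table16, toy_complex_factory):
        cx = toy_complex_factory(
            decoy_distances_nm=[0.1, 0.2, 0.5, 1.5, 2.5],
            duplicate_decoy_distance_nm=2.0,
        )
        examples = build_dataset(
            [ComplexInput("toy", cx.structure, cx.ligand, cx.decoys)], table16, seed=0
        )
        negatives = [e for e in examples if e.label == 0]
        duplicate_id = cx.toy.manifest[-1]["pocket_id"]
        assert duplicate_id not in {e.pocket_id for e in negatives}
        assert len(negatives) == 2  # two genuine far decoys remain

    def test_reproducible_under_seed(self, table16, toy_complex_factory):
        cx = toy_complex_factory(decoy_distances_nm=[0.1, 1.1, 1.2, 1.3, 1.4, 1.5])
        runs = []
        for _ in range(2):
            ex = build_dataset(
                [ComplexInput("toy", cx.structure, cx.ligand, cx.decoys)], table16, seed=5
            )
            X, y = examples_to_arrays(ex)
            runs.append((X, y, [e.pocket_id for e in ex]))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])
        assert runs[0][2] == runs[1][2]

    def test_positive_replication(self, table16, toy_complex_factory):
        cx = toy_complex_factory()
        examples = build_dataset(
            [ComplexInput("toy", cx.structure, cx.ligand, cx.decoys)], table16, seed=0
        )
        X, y = examples_to_arrays(examples, replicate_positives=3)
        assert int(y.sum()) == 6 and len(y) == 9

    def test_manifest_written(self, table16, toy_complex_factory, tmp_path):
        cx = toy_complex_factory()
        examples = build_dataset(
            [ComplexInput("toy", cx.structure, cx.ligand, cx.decoys)], table16, seed=0
        )
        out = tmp_path / "manifest.tsv"
        write_manifest(examples, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t")[:3] == ["complex_id", "pocket_id", "label"]
        assert len(lines) == len(examples) + 1
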