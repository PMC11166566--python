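"""Training: loss formula, gradient steps, streaming contract, recovery."""

import resource

import numpy as np
import pytest

from atacspace import (
    CellEmbeddingModel,
    Dataset,
    FeatureSpec,
    TrainingConfig,
    margin_ranking_loss,
    reverse_complement,
    select_variable_events,
    simulate_dataset,
    SimConfig,
)
from atacspace._train import _apply_example


def _unit(v):
    return np.asarray(v, dtype=float) / np.linalg.norm(v)


class TestMarginRankingLoss:
    def test_inactive_hinge(self):
        # sim(pos)=1, sim(neg)=0 -> max(0, 0.05 - 1 + 0) = 0
        lhs = np.array([1.0, 0.0])
        loss, hinges = margin_ranking_loss(
            lhs, lhs * 3, np.array([[0.0, 1.0]]), margin=0.05
        )
        assert loss == 0.0

    def test_active_hinge_arithmetic(self):
        # sim(pos)=0, sim(neg)=0.5 -> 0.05 - 0 + 0.5 = 0.55
        lhs = np.array([1.0, 0.0])
        pos = np.array([0.0, 2.0])
        neg = np.array([0.5, np.sqrt(3) / 2])
        loss, _ = margin_ranking_loss(lhs, pos, neg[None], margin=0.05)
        assert loss == pytest.approx(0.55, abs=1e-12)

    def test_mean_over_k(self):
        # hinges {0, 0.3} -> loss 0.15
        lhs = np.array([1.0, 0.0])
        pos = np.array([0.0, 1.0])  # sim 0
        neg_zero = _unit([-0.05, np.sqrt(1 - 0.05**2)])  # sim -0.05 -> hinge 0
        neg_act = _unit([0.25, np.sqrt(1 - 0.25**2)])  # sim 0.25 -> 0.3
        loss, hinges = margin_ranking_loss(
            lhs, pos, np.stack([neg_zero, neg_act]), margin=0.05
        )
        assert loss == pytest.approx(0.15, abs=1e-12)
        assert hinges[0] == 0.0

    def test_zero_norm_cosine_is_zero(self):
        lhs = np.zeros(3)
        loss, _ = margin_ranking_loss(
            lhs, np.ones(3), np.ones((1, 3)), margin=0.05
        )
        assert loss == pytest.approx(0.05)

    def test_oracle_direct_transcription(self):
        """Loss matches the printed formula on many random instances."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            d, K = rng.integers(2, 8), rng.integers(1, 6)
            lhs = rng.normal(size=d)
            pos = rng.normal(size=d)
            negs = rng.normal(size=(K, d))

            def cos(a, b):
                return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

            margin = rng.uniform(0.01, 0.5)
            expected = np.mean(
                [
                    max(0.0, margin - cos(lhs, pos) + cos(lhs, n))
                    for n in negs
                ]
            )
            got, _ = margin_ranking_loss(lhs, pos, negs, margin)
            assert got == pytest.approx(expected, abs=1e-12)


class TestSgdStep:
    def _setup(self, seed=0, d=5, active=True):
        rng = np.random.default_rng(seed)
        cell = rng.normal(size=(4, d)).astype(np.float32)
        feat = rng.normal(size=(10, d)).astype(np.float32)
        rows = np.array([1, 3, 3, 7], dtype=np.int64)
        negs = np.array([2, 3], dtype=np.int32)
        return cell, feat, rows, negs

    def test_zero_loss_is_noop(self):
        d = 4
        feat = np.zeros((6, d), dtype=np.float32)
        feat[0] = [1, 0, 0, 0]
        cell = np.zeros((3, d), dtype=np.float32)
        cell[0] = [1, 0, 0, 0]  # pos aligned with lhs
        cell[1] = [-1, 0, 0, 0]  # neg opposed: hinge 0
        rows = np.array([0], dtype=np.int64)
        c0, f0 = cell.copy(), feat.copy()
        loss, _ = _apply_example(
            cell, feat, rows, 1, 0, np.array([1], dtype=np.int32), 1,
            0.05, 0.1, np.zeros(3), np.zeros(6), True,
        )
        assert loss == 0.0
        np.testing.assert_array_equal(cell, c0)
        np.testing.assert_array_equal(feat, f0)

    def test_gradient_support(self):
        """Only LHS feature rows, the positive and active negatives move."""
        cell, feat, rows, _ = self._setup()
        negs = np.array([2, 3], dtype=np.int32)
        c0, f0 = cell.copy(), feat.copy()
        loss, _ = _apply_example(
            cell, feat, rows, len(rows), 0, negs, 2,
            0.5, 1e-3, np.zeros(4), np.zeros(10), True,
        )
        assert loss > 0
        changed_cells = {
            i for i in range(4) if not np.array_equal(cell[i], c0[i])
        }
        changed_feats = {
            i for i in range(10) if not np.array_equal(feat[i], f0[i])
        }
        assert changed_cells <= {0, 2, 3}
        assert 0 in changed_cells
        assert changed_feats == {1, 3, 7}

    def test_one_step_decreases_loss(self):
        """Finite-check: a small step reduces the example's own loss."""
        for seed in range(5):
            cell, feat, rows, negs = self._setup(seed)
            margin = 0.8

            def current_loss(cell, feat):
                lhs = feat[rows].astype(float).sum(axis=0)
                return margin_ranking_loss(
                    lhs, cell[0].astype(float),
                    cell[negs].astype(float), margin,
                )[0]

            before = current_loss(cell, feat)
            assert before > 0
            _apply_example(
                cell, feat, rows, len(rows), 0, negs, 2,
                margin, 1e-4, np.zeros(4), np.zeros(10), False,
            )
            after = current_loss(cell, feat)
            assert after < before


def _mini_dataset(batch=None):
    import scipy.sparse as sp

    rng = np.random.default_rng(3)
    n_cells, n_events = 12, 8
    mat = (rng.random((n_cells, n_events)) < 0.4).astype(np.int8)
    mat[0, :] = 1  # keep every event non-degenerate
    mat[1, :] = 0
    seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(n_events)]
    return Dataset(
        matrix=sp.csr_matrix(mat),
        cell_ids=[f"c{i}" for i in range(n_cells)],
        event_names=[f"e{i}" for i in range(n_events)],
        sequences=seqs,
        batch=batch,
    )


SMALL_SPEC = FeatureSpec(k=6, N=3, bucket=2000)


class TestTrainContract:
    def test_epochs_zero_returns_initialized_model(self):
        ds = _mini_dataset()
        cfg = TrainingConfig(epochs=0, d=8, L=40, spec=SMALL_SPEC)
        r1 = CellEmbeddingModel(ds, cfg).fit(seed=9)
        r2 = CellEmbeddingModel(ds, cfg).fit(seed=9)
        np.testing.assert_array_equal(r1.cell_embeddings, r2.cell_embeddings)
        assert r1.loss_trace.size == 0

    def test_same_seed_bit_reproducible(self):
        ds = _mini_dataset()
        cfg = TrainingConfig(
            epochs=3, d=8, L=40, examples_per_event=4, spec=SMALL_SPEC
        )
        r1 = CellEmbeddingModel(ds, cfg).fit(seed=4)
        r2 = CellEmbeddingModel(ds, cfg).fit(seed=4)
        np.testing.assert_array_equal(r1.cell_embeddings, r2.cell_embeddings)
        np.testing.assert_array_equal(
            r1.feature_embeddings, r2.feature_embeddings
        )
        r3 = CellEmbeddingModel(ds, cfg).fit(seed=5)
        assert not np.array_equal(r1.cell_embeddings, r3.cell_embeddings)

    def test_training_strand_invariant(self):
        ds = _mini_dataset()
        rc = Dataset(
            matrix=ds.matrix,
            cell_ids=ds.cell_ids,
            event_names=ds.event_names,
            sequences=[reverse_complement(s) for s in ds.sequences],
        )
        cfg = TrainingConfig(
            epochs=3, d=8, L=40, examples_per_event=4, spec=SMALL_SPEC
        )
        r1 = CellEmbeddingModel(ds, cfg).fit(seed=4)
        r2 = CellEmbeddingModel(rc, cfg).fit(seed=4)
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)
        np.testing.assert_array_equal(r1.cell_embeddings, r2.cell_embeddings)

    def test_streaming_memory_constant(self):
        """Peak RSS does not grow with epochs x examples_per_event."""
        ds = _mini_dataset()

        def run(epochs, epe):
            cfg = TrainingConfig(
                epochs=epochs, d=8, L=40, examples_per_event=epe,
                spec=SMALL_SPEC,
            )
            CellEmbeddingModel(ds, cfg).fit(seed=1)

        run(2, 2)  # includes one-off JIT/compile allocations
        before = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
        run(20, 20)  # 100x the examples
        after = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
        assert (after - before) < 50_000  # KiB

    def test_batch_aware_skips_without_eligible_negatives(self):
        import scipy.sparse as sp

        rng = np.random.default_rng(0)
        # event open in all of batch b0; only closed cells are in b1
        mat = np.array([[1, 1], [1, 1], [0, 1], [0, 1]], dtype=np.int8)
        ds = Dataset(
            matrix=sp.csr_matrix(mat),
            cell_ids=["a", "b", "c", "d"],
            event_names=["e1", "e2"],
            sequences=[
                "".join(rng.choice(list("ACGT"), size=40)) for _ in range(2)
            ],
            batch=np.array(["b0", "b0", "b1", "b1"], dtype=object),
        )
        cfg = TrainingConfig(
            epochs=2, d=4, L=40, examples_per_event=5, K_neg=2,
            batch_aware=True, spec=SMALL_SPEC,
        )
        r = CellEmbeddingModel(ds, cfg).fit(seed=0)
        # event e1 has positives only in b0 and negatives only in b1:
        # every one of its examples must be skipped
        assert r.skipped_examples.sum() >= 2 * 5

    def test_no_usable_events_raises(self):
        import scipy.sparse as sp

        ds = Dataset(
            matrix=sp.csr_matrix(np.ones((3, 2), dtype=np.int8)),
            cell_ids=["a", "b", "c"],
            event_names=["e1", "e2"],
            sequences=["ACGTACGTAC", "ACGTACGTAC"],
        )
        with pytest.raises(ValueError, match="usable"):
            CellEmbeddingModel(ds, TrainingConfig(spec=SMALL_SPEC, L=10))

    def test_batch_aware_requires_batches(self):
        ds = _mini_dataset()
        with pytest.raises(ValueError, match="batch"):
            CellEmbeddingModel(
                ds, TrainingConfig(batch_aware=True, L=40, spec=SMALL_SPEC)
            )


class TestMultiDatasetCoEmbedding:
    def test_two_atlases_share_one_space(self):
        """Two datasets with different event sets co-embed; same planted
        types end up more similar across datasets than different types."""
        from atacspace import DatasetCollection, SimConfig, simulate_dataset

        base = dict(
            n_cells=60, n_types=2, n_events=120, event_len=200,
            genome_size=8000, n_batches=1,
        )
        # same motifs across datasets: same generator seed fixes them, and
        # we re-slice events by taking disjoint halves as the two "atlases"
        ds, truth = simulate_dataset(SimConfig(**base, seed=21))
        import scipy.sparse as sp

        half = ds.matrix.shape[1] // 2
        parts = []
        for j, sl in enumerate([slice(0, half), slice(half, None)]):
            parts.append(
                Dataset(
                    matrix=sp.csr_matrix(ds.matrix[:, sl]),
                    cell_ids=[f"d{j}_{c}" for c in ds.cell_ids],
                    event_names=ds.event_names[sl],
                    sequences=ds.sequences[sl],
                    dataset_id=f"atlas{j}",
                )
            )
        cfg = TrainingConfig(
            epochs=6, d=10, L=100, examples_per_event=5, spec=SMALL_SPEC
        )
        r = CellEmbeddingModel(DatasetCollection(parts), cfg).fit(seed=2)
        assert r.n_cells == 120
        assert r.dataset_ids == ["atlas0", "atlas1"]
        assert set(r.cell_dataset) == {0, 1}
        cu = r.cell_embeddings / np.linalg.norm(
            r.cell_embeddings, axis=1, keepdims=True
        )
        types = np.concatenate([truth.cell_types, truth.cell_types])
        d0 = np.arange(120) < 60
        same = cu[d0 & (types == "type0")] @ cu[~d0 & (types == "type0")].T
        diff = cu[d0 & (types == "type0")] @ cu[~d0 & (types == "type1")].T
        assert same.mean() > diff.mean()


class TestTrainingConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"d": 1},
            {"L": 4},
            {"K_neg": 0},
            {"margin": 0.0},
            {"examples_per_event": 0},
            {"epochs": -1},
            {"similarity": "dot"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)


class TestVariableEventSelection:
    def test_identity_and_warning(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((30, 10)) < 0.3).astype(np.int8)
        mat[0] = 1
        assert len(select_variable_events(mat, 10)) == 10
        with pytest.warns(UserWarning):
            got = select_variable_events(mat, 25)
        assert len(got) == 10

    def test_ubiquitous_events_ranked_last(self):
        rng = np.random.default_rng(1)
        n_cells = 60
        informative = np.zeros((n_cells, 4), dtype=np.int8)
        informative[: n_cells // 2, :2] = 1  # open in one half
        informative[n_cells // 2 :, 2:] = 1
        ubiquitous = np.ones((n_cells, 2), dtype=np.int8)
        noise = (rng.random((n_cells, 4)) < 0.5).astype(np.int8)
        mat = np.concatenate([informative, ubiquitous, noise], axis=1)
        order = select_variable_events(mat, mat.shape[1])
        # all-cells events (cols 4,5) rank behind the block-informative ones
        assert set(order[-2:]) == {4, 5}

    def test_planted_events_outrank_background(self, small_sim):
        ds, truth = small_sim
        order = select_variable_events(ds.matrix, ds.matrix.shape[1])
        ranks = {name: i for i, name in enumerate(order)}
        specific = [
            i for i, r in enumerate(truth.event_roles) if r.startswith("type")
        ]
        background = [
            i for i, r in enumerate(truth.event_roles) if r == "background"
        ]
        med_spec = np.median([ranks[i] for i in specific])
        med_bg = np.median([ranks[i] for i in background])
        assert med_spec < med_bg
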