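"""De novo motif discovery from the latent space."""

import itertools

import numpy as np
import pytest

from atacspace import FeatureSpec, TrainingConfig, n_canonical_kmers
from atacspace.denovo import (
    align_and_build_pwm,
    cluster_10mers,
    discover_motifs,
    embed_all_10mers,
    group_associated_10mers,
    kmer_dissimilarity_matrix,
)
from atacspace.features import kmer_bag, reverse_complement
from atacspace.model import CellEmbeddingResults


def _results_with(feats, cells, k=8, N=1, bucket=0, ids=None):
    spec = FeatureSpec(k=k, N=N, bucket=bucket)
    assert feats.shape[0] == spec.n_feature_rows
    return CellEmbeddingResults(
        cell_embeddings=cells,
        feature_embeddings=feats,
        cell_ids=ids or [f"c{i}" for i in range(len(cells))],
        spec=spec,
        config=TrainingConfig(spec=spec, d=feats.shape[1]),
    )


class TestTenmerTable:
    def test_row_count_matches_exhaustive_enumeration(self):
        """Small-alphabet analogue: model with k=2 covers all canonical 4-mers."""
        rng = np.random.default_rng(0)
        res = _results_with(
            rng.normal(size=(n_canonical_kmers(2), 6)),
            rng.normal(size=(5, 6)),
            k=2,
        )
        with pytest.warns(UserWarning):
            table = embed_all_10mers(res, strict=False)
        brute = {
            min(s, reverse_complement(s))
            for s in map("".join, itertools.product("ACGT", repeat=4))
        }
        assert len(table) == len(brute) == n_canonical_kmers(4)

    def test_strict_mode_requires_k8(self):
        rng = np.random.default_rng(0)
        res = _results_with(
            rng.normal(size=(n_canonical_kmers(2), 6)),
            rng.normal(size=(5, 6)),
            k=2,
        )
        with pytest.raises(ValueError, match="k=8"):
            embed_all_10mers(res, strict=True)

    def test_homopolymer_equals_single_row(self, tiny_results):
        from atacspace import canonical_kmer_index

        table = embed_all_10mers(tiny_results)
        i = np.searchsorted(table.codes, 0)  # AAAAAAAAAA has code 0
        assert table.string(i) == "AAAAAAAAAA"
        row = tiny_results.feature_embeddings[canonical_kmer_index("A" * 8)]
        np.testing.assert_allclose(table.embeddings[i], row, rtol=1e-6)

    def test_mean_of_constituents(self, tiny_results):
        from atacspace import canonical_kmer_index

        table = embed_all_10mers(tiny_results)
        s = "ACGTTACGTC"
        rows = [canonical_kmer_index(s[i : i + 8]) for i in range(3)]
        expected = tiny_results.feature_embeddings[rows].mean(axis=0)
        # locate the row for s (canonical)
        code = 0
        for b in s:
            code = code * 4 + "ACGT".index(b)
        rc_code = 0
        for b in reverse_complement(s):
            rc_code = rc_code * 4 + "ACGT".index(b)
        i = np.searchsorted(table.codes, min(code, rc_code))
        np.testing.assert_allclose(table.embeddings[i], expected, rtol=1e-6)


class TestGroupAssociation:
    def _toy(self):
        rng = np.random.default_rng(0)
        res = _results_with(
            rng.normal(size=(n_canonical_kmers(2), 8)).astype(np.float32),
            rng.normal(size=(6, 8)).astype(np.float32),
            k=2,
        )
        with pytest.warns(UserWarning):
            table = embed_all_10mers(res, strict=False)
        return res, table

    def test_single_cell_group_gets_exactly_k_neighbors(self):
        res, table = self._toy()
        groups = np.array(["a", "b", "b", "b", "b", "b"])
        sets = group_associated_10mers(
            table, res.cell_embeddings, groups, K=7, freq=0.2
        )
        assert len(sets["a"]) == 7

    def test_freq_one_is_intersection(self):
        res, table = self._toy()
        groups = np.array(["g"] * 6)
        sets = group_associated_10mers(
            table, res.cell_embeddings, groups, K=15, freq=1.0
        )
        # brute-force: intersection of all cells' top-15 neighbor sets
        C = res.cell_embeddings / np.linalg.norm(
            res.cell_embeddings, axis=1, keepdims=True
        )
        T = table.embeddings / np.linalg.norm(
            table.embeddings, axis=1, keepdims=True
        )
        sims = C @ T.T
        tops = [
            set(np.argsort(-sims[i])[:15]) for i in range(6)
        ]
        expected = set.intersection(*tops)
        assert set(sets["g"]) == expected

    def test_threshold_is_ceil_of_group_fraction(self):
        res, table = self._toy()
        groups = np.array(["g"] * 6)
        sets = group_associated_10mers(
            table, res.cell_embeddings, groups, K=10, freq=0.2
        )
        # threshold = ceil(0.2 * 6) = 2: brute-force recount
        C = res.cell_embeddings / np.linalg.norm(
            res.cell_embeddings, axis=1, keepdims=True
        )
        T = table.embeddings / np.linalg.norm(
            table.embeddings, axis=1, keepdims=True
        )
        sims = C @ T.T
        counts = np.zeros(len(table), dtype=int)
        for i in range(6):
            counts[np.argsort(-sims[i])[:10]] += 1
        assert set(sets["g"]) == set(np.flatnonzero(counts >= 2))


class TestKmerClustering:
    def test_identical_and_revcomp_distance_zero(self):
        D = kmer_dissimilarity_matrix(
            ["ACGTACGTAA", "ACGTACGTAA", reverse_complement("ACGTACGTAA")]
        )
        assert D.max() == 0.0
        labels = cluster_10mers(
            ["ACGTACGTAA", "ACGTACGTAA", reverse_complement("ACGTACGTAA")]
        )
        assert len(np.unique(labels)) == 1

    def test_disjoint_composition_separates(self):
        D = kmer_dissimilarity_matrix(["A" * 10, "C" * 10])
        assert D[0, 1] == 1.0
        labels = cluster_10mers(["A" * 10, "C" * 10], cut=0.5)
        assert len(np.unique(labels)) == 2

    def test_shifted_variant_close(self):
        # one-base shift of the same core: 9/10 matches -> dissim 0.1
        D = kmer_dissimilarity_matrix(["ACGTTGCAGT", "CGTTGCAGTA"])
        assert D[0, 1] == pytest.approx(0.1)

    def test_singleton_one_cluster(self):
        assert list(cluster_10mers(["ACGTACGTAA"])) == [0]


class TestPwmConstruction:
    def test_identical_members_near_one_columns(self):
        m = align_and_build_pwm(["ACGTTGCAGT"] * 4)
        assert m.width == 10
        assert m.consensus() == "ACGTTGCAGT"
        assert m.pwm.max(axis=0).min() > 0.95

    def test_revcomp_members_resolved(self):
        s = "ACGTTGCAGT"
        m1 = align_and_build_pwm([s, s, s, reverse_complement(s)])
        m2 = align_and_build_pwm([s] * 4)
        assert (
            np.allclose(m1.pwm, m2.pwm)
            or np.allclose(m1.pwm, m2.pwm[::-1, ::-1])
        )

    def test_small_cluster_discarded(self):
        with pytest.raises(ValueError, match="discarded"):
            align_and_build_pwm(["ACGTTGCAGT"] * 3)

    def test_column_stochastic(self):
        rng = np.random.default_rng(0)
        members = [
            "".join(rng.choice(list("ACGT"), size=10)) for _ in range(6)
        ]
        m = align_and_build_pwm(members)
        np.testing.assert_allclose(m.pwm.sum(axis=0), 1.0, atol=1e-9)


class TestEndToEndOnConstructedSpace:
    """Pipeline recovers a motif planted directly in an idealized latent space."""

    def _constructed(self, d=16, seed=0):
        rng = np.random.default_rng(seed)
        spec = FeatureSpec(k=8, N=1, bucket=0)
        feats = rng.normal(scale=0.05, size=(spec.n_kmer_rows, d)).astype(
            np.float32
        )
        direction = rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        consensus = "CGTCTTATCA"
        # plant: the motif's constituent 8-mers (all shift variants) point at
        # the group direction
        for shift in range(3):
            row = kmer_bag(consensus, spec)[shift]
            feats[row] = (direction + rng.normal(scale=0.02, size=d)).astype(
                np.float32
            )
        cells = (
            direction[None, :] * 1.0
            + rng.normal(scale=0.05, size=(20, d))
        ).astype(np.float32)
        other = rng.normal(scale=0.3, size=(20, d)).astype(np.float32)
        res = CellEmbeddingResults(
            cell_embeddings=np.vstack([cells, other]),
            feature_embeddings=feats,
            cell_ids=[f"c{i}" for i in range(40)],
            spec=spec,
            config=TrainingConfig(spec=spec, d=d),
        )
        groups = np.array(["planted"] * 20 + ["other"] * 20)
        return res, groups, consensus

    def test_recovers_planted_consensus(self):
        res, groups, consensus = self._constructed()
        found = discover_motifs(res, groups, K=50, freq=0.2)
        assert found["planted"], "no motif emitted for the planted group"
        best = max(
            found["planted"], key=lambda dn: len(dn.member_10mers)
        )
        # the emitted consensus contains the planted core (either strand)
        joined = best.motif.consensus()
        core = consensus[1:-1]
        assert (
            core in joined or reverse_complement(core) in joined
        )

    def test_deterministic(self):
        res, groups, _ = self._constructed()
        f1 = discover_motifs(res, groups)
        f2 = discover_motifs(res, groups)
        for g in f1:
            assert len(f1[g]) == len(f2[g])
            for a, b in zip(f1[g], f2[g]):
                np.testing.assert_array_equal(a.pwm, b.pwm)

    def test_every_emitted_motif_valid(self):
        res, groups, _ = self._constructed()
        for ms in discover_motifs(res, groups).values():
            for dn in ms:
                assert len(dn.member_10mers) > 3
                np.testing.assert_allclose(
                    dn.pwm.sum(axis=0), 1.0, atol=1e-9
                )
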