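"""Synthetic-corpus generator: determinism, structure, round trips."""

import numpy as np
import pytest

from proteus.io_tracks import load_corpus
from proteus.synthetic_fixtures import (
    GeneratorConfig,
    generate_corpus,
    generate_protein,
    generate_topography_corpus,
    shuffled_labels,
    write_corpus,
)


class TestDeterminism:
    def test_same_seed_identical_corpus(self):
        cfg = GeneratorConfig(n_proteins=8, seed=42)
        a, b = generate_corpus(cfg), generate_corpus(cfg)
        for pa, pb in zip(a.proteins, b.proteins):
            assert pa.sequence == pb.sequence
            np.testing.assert_array_equal(pa.pssm.scores, pb.pssm.scores)
            np.testing.assert_array_equal(pa.diso.scores, pb.diso.scores)
            assert pa.ss.calls == pb.ss.calls
            np.testing.assert_array_equal(pa.labels.labels, pb.labels.labels)

    def test_different_seeds_differ(self):
        a = generate_corpus(GeneratorConfig(n_proteins=3, seed=1))
        b = generate_corpus(GeneratorConfig(n_proteins=3, seed=2))
        assert any(pa.sequence != pb.sequence for pa, pb in zip(a.proteins, b.proteins))


class TestStructure:
    def test_noise_free_track_separates_regions_at_half(self):
        cfg = GeneratorConfig(
            n_proteins=1, disorder_noise=0.0, protean_protein_fraction=1.0,
            disordered_fraction=0.3, length_range=(120, 120), seed=3,
        )
        protein, regions = generate_protein(cfg, seed=3, protein_id="p")
        dis = regions.disordered_mask(len(protein))
        assert regions.protean  # a protean segment was placed
        assert np.all(protein.diso.scores[dis] >= 0.5)
        assert np.all(protein.diso.scores[~dis] < 0.5)

    def test_protean_segments_inside_disordered_regions(self, corpus200):
        for p in corpus200.proteins:
            rm = corpus200.region_maps[p.id]
            dis = rm.disordered_mask(len(p))
            assert np.all(dis[rm.protean_mask(len(p))])

    def test_labels_match_region_map(self, corpus200):
        for p in corpus200.proteins:
            rm = corpus200.region_maps[p.id]
            np.testing.assert_array_equal(
                p.labels.labels.astype(bool), rm.protean_mask(len(p))
            )

    def test_positive_fraction_near_two_percent(self, corpus200):
        pos = sum(int(p.labels.labels.sum()) for p in corpus200.proteins)
        tot = sum(len(p) for p in corpus200.proteins)
        assert 0.012 <= pos / tot <= 0.032

    def test_protean_segment_lengths_in_bounds(self, corpus200):
        lengths = [
            e - s + 1
            for p in corpus200.proteins
            for s, e in corpus200.region_maps[p.id].protean
        ]
        assert lengths and all(5 <= n <= 60 for n in lengths)
        assert 10 <= float(np.median(lengths)) <= 25  # mode near the window size

    def test_families_share_region_architecture(self, corpus_small):
        by_family: dict[int, list[str]] = {}
        for pid, fam in corpus_small.clusters.mapping.items():
            by_family.setdefault(fam, []).append(pid)
        multi = [pids for pids in by_family.values() if len(pids) > 1]
        assert multi  # duplicates exist at the default rate
        for pids in multi:
            maps = [corpus_small.region_maps[pid] for pid in pids]
            assert len({tuple(m.protean) for m in maps}) == 1


class TestRecovery:
    def test_propensity_recovers_configured_enrichment(self, corpus200):
        from collections import Counter

        from proteus.consensus_analysis import count_residues, propensity

        full, protean = Counter(), Counter()
        for p in corpus200.proteins:
            lab = p.labels.labels.astype(bool)
            full.update(count_residues(p.sequence))
            protean.update(count_residues(p.sequence, lab))
        table = propensity(protean, full, "protean")
        assert table["L"] > 1.0 and table["W"] > 1.0
        assert table["P"] < 1.0 and table["C"] < 1.0

    def test_shuffled_labels_preserve_counts(self, corpus_small):
        shuffled = shuffled_labels(corpus_small, seed=5)
        orig = np.concatenate([p.labels.labels for p in corpus_small.proteins])
        perm = np.concatenate([shuffled[p.id] for p in corpus_small.proteins])
        assert orig.sum() == perm.sum()
        assert not np.array_equal(orig, perm)


class TestTopographyCorpus:
    def test_track_never_drops_below_half(self):
        corpus = generate_topography_corpus(n_proteins=5, seed=1)
        for p in corpus.proteins:
            assert np.all(p.diso.scores >= 0.5)

    def test_protean_residues_sit_in_valleys(self):
        from proteus.disorder_features import topography_classes

        corpus = generate_topography_corpus(n_proteins=5, seed=1)
        for p in corpus.proteins:
            klass = topography_classes(p.diso.scores)
            assert np.all(klass[p.labels.labels.astype(bool)] == -1)


class TestRoundTrip:
    def test_disk_round_trip_is_exact(self, tmp_path):
        corpus = generate_corpus(GeneratorConfig(n_proteins=6, seed=17))
        write_corpus(corpus, tmp_path)
        loaded = load_corpus(tmp_path)
        assert [p.id for p in loaded] == [p.id for p in corpus.proteins]
        for orig, back in zip(corpus.proteins, loaded):
            assert back.sequence == orig.sequence
            np.testing.assert_array_equal(back.pssm.scores, orig.pssm.scores)
            np.testing.assert_array_equal(back.pssm.info, orig.pssm.info)
            np.testing.assert_array_equal(back.ss.probs, orig.ss.probs)
            assert back.ss.calls == orig.ss.calls
            np.testing.assert_array_equal(back.diso.scores, orig.diso.scores)
            np.testing.assert_array_equal(back.labels.labels, orig.labels.labels)

    def test_cluster_file_round_trip(self, tmp_path):
        from proteus.io_tracks import read_clusters

        corpus = generate_corpus(GeneratorConfig(n_proteins=10, seed=17))
        write_corpus(corpus, tmp_path)
        clusters = read_clusters(tmp_path / "clusters.txt")
        # cluster ids may be renumbered by line order; the partition must match
        def partition(c):
            groups = {}
            for pid, cid in c.mapping.items():
                groups.setdefault(cid, set()).add(pid)
            return {frozenset(g) for g in groups.values()}

        assert partition(clusters) == partition(corpus.clusters)
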