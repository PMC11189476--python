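"""Binding-event extraction and phi/single-linkage clustering vs oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from lipgate import binding_sites as bs
from lipgate.core import DistanceTable

from conftest import table_from_bool


# ------------------------------------------------------------------ oracles


def scan_runs_oracle(occupied, gap_tolerance):
    """Hand-written run scan with gap bridging; inclusive (start, end)."""
    runs = []
    cur_start = None
    gap = 0
    for f, on in enumerate(occupied):
        if on:
            if cur_start is None:
                cur_start = f
                cur_end = f
            else:
                cur_end = f
            gap = 0
        elif cur_start is not None:
            gap += 1
            if gap > gap_tolerance:
                runs.append((cur_start, cur_end))
                cur_start = None
                gap = 0
    if cur_start is not None:
        runs.append((cur_start, cur_end))
    return runs


def pearson_oracle(a, b):
    """Textbook Pearson correlation of two sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    denom = np.sqrt((am**2).sum() * (bm**2).sum())
    return 0.0 if denom == 0 else float((am * bm).sum() / denom)


def phi_oracle(a, b):
    """Phi from the 2x2 contingency table."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    tp = np.sum(a & b)
    tn = np.sum(~a & ~b)
    fp = np.sum(~a & b)
    fn = np.sum(a & ~b)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return 0.0 if denom == 0 else float((tp * tn - fp * fn) / np.sqrt(denom))


def single_linkage_oracle(dist):
    """Naive O(n^3) single-linkage agglomeration.

    Returns the list of merge heights and the final partition reachable
    below height 1 (positive-similarity components).
    """
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(dist[a, b] for a in clusters[i] for b in clusters[j])
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((d, frozenset(clusters[i]), frozenset(clusters[j])))
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return merges


def components_below(merges, n, level):
    parts = [{i} for i in range(n)]
    for d, a, b in merges:
        if d < level:
            ia = next(k for k, p in enumerate(parts) if a & p)
            ib = next(k for k, p in enumerate(parts) if b & p)
            if ia != ib:
                parts[ia] |= parts[ib]
                del parts[ib]
    return {frozenset(p) for p in parts}


def labels_to_partition(labels):
    return {
        frozenset(np.flatnonzero(labels == lab).tolist()) for lab in np.unique(labels)
    }


def make_event(fingerprint, lipid=0):
    fingerprint = np.asarray(fingerprint, dtype=bool)
    return bs.BindingEvent(
        lipid=lipid,
        species="PIP2",
        repeat=0,
        t_start=0.0,
        t_end=float(fingerprint.shape[1]),
        fingerprint=fingerprint,
        residue_ids=np.arange(fingerprint.shape[0]),
    )


# ------------------------------------------------------------------- tests


class TestEventExtraction:
    def test_paper_scale_persistence_filter(self):
        # 12 us below the cutoff passes a 10 us filter with duration 12 us
        n = 140
        occ = np.zeros((n, 1, 2), dtype=bool)
        occ[10:130, 0, 0] = True  # 120 frames x 100 ns = 12 us
        table = table_from_bool(occ, dt=100.0)
        events = bs.extract_binding_events(table, min_duration=10_000.0)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(12_000.0)

    def test_never_in_contact_gives_no_events(self):
        table = table_from_bool(np.zeros((30, 2, 3), dtype=bool))
        assert bs.extract_binding_events(table, min_duration=0.0) == []

    @pytest.mark.parametrize("gap_tolerance", [0, 2])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_run_scan_oracle(self, seed, gap_tolerance):
        rng = np.random.default_rng(300 + seed)
        occ = (rng.random((40, 1, 1)) < 0.45)
        table = table_from_bool(occ, dt=1.0)
        events = bs.extract_binding_events(
            table, min_duration=0.0, gap_tolerance=gap_tolerance
        )
        expected = scan_runs_oracle(occ[:, 0, 0], gap_tolerance)
        got = [(int(ev.t_start), int(ev.t_start + ev.duration) - 1) for ev in events]
        assert got == expected

    def test_fingerprint_spans_event_frames(self):
        occ = np.zeros((20, 1, 3), dtype=bool)
        occ[5:15, 0, 1] = True
        occ[7:9, 0, 2] = True
        table = table_from_bool(occ, dt=1.0)
        (ev,) = bs.extract_binding_events(table, min_duration=0.0)
        assert ev.fingerprint.shape == (3, 10)
        assert set(ev.contacted_residues.tolist()) == {1, 2}


class TestCooccurrence:
    def test_identical_rows_correlate_fully(self):
        fp = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]])
        adj = bs.residue_cooccurrence(make_event(fp))
        assert adj.values[0, 1] == pytest.approx(1.0)
        assert adj.values[0, 2] == pytest.approx(-1.0)

    def test_never_contacting_row_is_zero(self):
        fp = np.array([[1, 0, 1], [0, 0, 0]])
        adj = bs.residue_cooccurrence(make_event(fp))
        assert adj.values[1, 0] == 0.0
        assert adj.values[1, 1] == 0.0  # diagonal 0 for non-contacting
        assert adj.values[0, 0] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pearson_formula_and_pandas(self, seed):
        rng = np.random.default_rng(400 + seed)
        fp = rng.random((3, 8)) < 0.5
        adj = bs.residue_cooccurrence(make_event(fp))
        ref = pd.DataFrame(fp.T.astype(float)).corr().to_numpy()
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                const = fp[i].all() or not fp[i].any() or fp[j].all() or not fp[j].any()
                expected = 0.0 if const else pearson_oracle(fp[i], fp[j])
                assert adj.values[i, j] == pytest.approx(expected, abs=1e-12)
                if not const:
                    assert adj.values[i, j] == pytest.approx(ref[i, j], abs=1e-12)

    def test_single_frame_event_rejected(self):
        with pytest.raises(ValueError):
            bs.residue_cooccurrence(make_event(np.array([[1], [0]])))


class TestPhi:
    def test_identical_adjacencies_give_unit_phi(self):
        fp = np.array([[1, 0, 1, 1], [0, 1, 0, 0], [1, 1, 0, 1]])
        adj = bs.residue_cooccurrence(make_event(fp))
        phi, flagged = bs.event_similarity(adj, adj)
        assert phi == pytest.approx(1.0)
        assert not flagged

    def test_disjoint_vectors_give_minus_one(self):
        phi, flagged = bs.phi_coefficient([1, 1, 0, 0], [0, 0, 1, 1])
        assert phi == pytest.approx(-1.0)
        assert not flagged

    def test_constant_vector_flagged_zero(self):
        phi, flagged = bs.phi_coefficient([1, 1, 1], [1, 0, 1])
        assert phi == 0.0
        assert flagged

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_contingency_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(500 + seed)
        a = rng.random(15) < 0.5
        b = rng.random(15) < 0.5
        phi, flagged = bs.phi_coefficient(a, b)
        assert phi == pytest.approx(phi_oracle(a, b), abs=1e-12)
        if not flagged:
            assert phi == pytest.approx(
                matthews_corrcoef(a.astype(int), b.astype(int)), abs=1e-9
            )

    def test_dimension_mismatch_rejected(self):
        a = bs.residue_cooccurrence(make_event(np.eye(3, 4, dtype=bool)))
        b = bs.residue_cooccurrence(make_event(np.eye(4, 5, dtype=bool)))
        with pytest.raises(ValueError):
            bs.event_similarity(a, b)


class TestClustering:
    def test_two_perfect_pairs_give_two_pure_clusters(self):
        values = np.array(
            [
                [1.0, 1.0, -1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [-1.0, -1.0, 1.0, 1.0],
                [-1.0, -1.0, 1.0, 1.0],
            ]
        )
        sim = bs.EventSimilarityMatrix(values, np.zeros((4, 4), dtype=bool))
        res = bs.cluster_events(sim)
        assert labels_to_partition(res.labels) == {
            frozenset({0, 1}),
            frozenset({2, 3}),
        }

    def test_chaining_behaviour(self):
        # a-b 0.9, b-c 0.9, a-c -0.5: single linkage chains all three
        values = np.array([[1.0, 0.9, -0.5], [0.9, 1.0, 0.9], [-0.5, 0.9, 1.0]])
        sim = bs.EventSimilarityMatrix(values, np.zeros((3, 3), dtype=bool))
        res = bs.cluster_events(sim)
        assert len(np.unique(res.labels)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_linkage_oracle(self, seed):
        rng = np.random.default_rng(600 + seed)
        n = int(rng.integers(4, 13))
        raw = rng.uniform(-1, 1, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        sim = bs.EventSimilarityMatrix(values, np.zeros((n, n), dtype=bool))
        res = bs.cluster_events(sim)
        dist = 1.0 - values
        np.fill_diagonal(dist, 0.0)
        merges = single_linkage_oracle(dist)
        # merge heights agree merge-for-merge and are non-decreasing
        np.testing.assert_allclose(
            res.linkage[:, 2], [m[0] for m in merges], atol=1e-9
        )
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)
        # default cut equals components connected below d = 1
        assert labels_to_partition(res.labels) == components_below(merges, n, 1.0)

    def test_permutation_equivariance(self, rng):
        n = 8
        raw = rng.uniform(-1, 1, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        perm = rng.permutation(n)
        sim = bs.EventSimilarityMatrix(values, np.zeros((n, n), dtype=bool))
        simp = bs.EventSimilarityMatrix(
            values[np.ix_(perm, perm)], np.zeros((n, n), dtype=bool)
        )
        p1 = labels_to_partition(bs.cluster_events(sim).labels)
        p2 = labels_to_partition(bs.cluster_events(simp).labels)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        p2_mapped = {frozenset(int(perm[i]) for i in part) for part in p2}
        assert p1 == p2_mapped

    def test_too_few_events_rejected(self):
        sim = bs.EventSimilarityMatrix(np.eye(1), np.zeros((1, 1), dtype=bool))
        with pytest.raises(ValueError):
            bs.cluster_events(sim)


class TestSitePipeline:
    @staticmethod
    def _two_site_table(seed=0, n_frames=400, dt=100.0):
        """Alternating long visits of two lipids to disjoint footprints."""
        rng = np.random.default_rng(seed)
        n_res = 12
        occ = np.zeros((n_frames, 4, n_res), dtype=bool)
        site_a, site_b = [1, 2, 3], [7, 8, 9]
        for lip, site in [(0, site_a), (1, site_a), (2, site_b), (3, site_b)]:
            start = int(rng.integers(0, 50))
            length = int(rng.integers(150, 250))  # 15-25 us at dt = 100 ns
            occ[start : start + length, lip, site] = True
            # sprinkle per-frame dropouts on one footprint residue
            drop = rng.random(n_frames) < 0.2
            occ[drop, lip, site[0]] = False
        return table_from_bool(occ, dt=dt)

    def test_two_planted_footprints_recovered(self):
        table = self._two_site_table(seed=42)
        res = bs.site_pipeline(table, bs.SitePipelineConfig(min_duration=10_000.0))
        assert res.n_events == 4
        labels = res.clusters.labels
        assert len(np.unique(labels)) == 2
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        cons = res.clusters.consensus_residues
        sets = {frozenset(v.tolist()) for v in cons.values()}
        assert sets == {frozenset({1, 2, 3}), frozenset({7, 8, 9})}

    def test_overlong_filter_yields_empty_notice(self):
        table = self._two_site_table()
        res = bs.site_pipeline(
            table, bs.SitePipelineConfig(min_duration=1e9)
        )
        assert res.n_events == 0
        assert res.clusters is None
        assert "no binding event" in res.notice

    def test_frame_rate_doubling_invariance(self):
        table = self._two_site_table(seed=7)
        # double the frame rate: repeat each frame, halve dt
        dense = np.repeat(table.distances, 2, axis=0)
        table2 = DistanceTable(
            times=np.arange(dense.shape[0]) * (table.dt / 2),
            distances=dense,
            lipid_species=table.lipid_species,
            residue_ids=table.residue_ids,
        )
        cfg = bs.SitePipelineConfig(min_duration=10_000.0, gap_tolerance=0)
        cfg2 = bs.SitePipelineConfig(min_duration=10_000.0, gap_tolerance=1)
        res = bs.site_pipeline(table, cfg)
        res2 = bs.site_pipeline(table2, cfg2)
        assert res.n_events == res2.n_events
        assert labels_to_partition(res.clusters.labels) == labels_to_partition(
            res2.clusters.labels
        )


class TestSimilarityMatrixInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_unit_diagonal_bounded(self, seed):
        rng = np.random.default_rng(700 + seed)
        events = [make_event(rng.random((6, 10)) < 0.5) for _ in range(5)]
        adjs = [bs.residue_cooccurrence(ev) for ev in events]
        sim = bs.similarity_matrix(adjs)
        np.testing.assert_allclose(sim.values, sim.values.T)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        assert np.all(sim.values >= -1.0 - 1e-12)
        assert np.all(sim.values <= 1.0 + 1e-12)
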