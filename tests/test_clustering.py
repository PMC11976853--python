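"""Rarity model, pairwise distances, complete-linkage clustering."""

import numpy as np
import pytest

from psmtransfer import (
    Cluster,
    ClusterState,
    PSM,
    PSMTable,
    PeptideIdent,
    RarityModel,
    Spectrum,
    annotate_clusters,
    bin_peaks,
    build_rarity_model,
    cluster_distance_matrix,
    complete_linkage,
    oracle_predictor,
    pairwise_distance,
    simulate_dataset,
    stringency_threshold,
)
from psmtransfer.clustering import _bin_distance
from psmtransfer.simulate import SimConfig


def _spectrum(mz, intensity, sid="r.raw:1", prec=500.0, charge=2, scan=1):
    return Spectrum(spectrum_id=sid, raw_file="r.raw", batch_id="b", scan=scan,
                    precursor_mz=prec, precursor_charge=charge,
                    retention_time=10.0, mz=np.asarray(mz, float),
                    intensity=np.asarray(intensity, float))


def naive_complete_linkage(dm: np.ndarray, t: float) -> list[set[int]]:
    """Exhaustive agglomeration oracle: repeatedly merge the pair of
    clusters with the smallest complete-linkage (max pairwise) distance,
    while that distance is <= t."""
    clusters = [{i} for i in range(dm.shape[0])]
    while len(clusters) > 1:
        best, best_d = None, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dm[i, j] for i in clusters[a] for j in clusters[b])
                if best_d is None or d < best_d:
                    best, best_d = (a, b), d
        if best_d is None or best_d > t:
            break
        a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    return clusters


class TestBinPeaks:
    def test_floor_arithmetic_collapses(self):
        s = _spectrum([100.01, 100.015], [1.0, 2.0])
        assert bin_peaks(s, bin_width=0.02, top_k=10) == {5000}

    def test_top_k_most_intense(self):
        s = _spectrum([100.0, 200.0, 300.0], [1.0, 5.0, 2.0])
        assert bin_peaks(s, bin_width=0.02, top_k=1) == {int(200.0 / 0.02)}

    def test_empty_spectrum(self):
        s = _spectrum([], [])
        assert bin_peaks(s) == frozenset()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(5, 60))
            mz = np.sort(rng.uniform(100, 1500, k))
            inten = rng.uniform(0, 1, k)
            s = _spectrum(mz, inten)
            top_k = int(rng.integers(1, 50))
            # oracle: sort by intensity desc (m/z asc ties), take k, floor-divide
            order = sorted(range(k), key=lambda i: (-s.intensity[i], s.mz[i]))[:top_k]
            expected = {int(np.floor(s.mz[i] / 0.02)) for i in order}
            assert bin_peaks(s, 0.02, top_k) == expected


class TestRarityModel:
    def test_ubiquitous_bin_weight_zero(self):
        m = RarityModel(bin_width=0.02, document_frequency={5: 1000},
                        n_spectra=1000, top_k=40)
        assert m.weight(5) == 0.0

    def test_rare_bin_weight(self):
        m = RarityModel(bin_width=0.02, document_frequency={5: 1},
                        n_spectra=1000, top_k=40)
        assert m.weight(5) == pytest.approx(3.0)

    def test_frequencies_match_recount(self):
        rng = np.random.default_rng(1)
        spectra = []
        for i in range(20):
            k = int(rng.integers(3, 25))
            spectra.append(_spectrum(np.sort(rng.uniform(100, 800, k)),
                                     rng.uniform(0, 1, k), sid=f"r.raw:{i}", scan=i))
        model = build_rarity_model(spectra, 0.02, 40)
        recount = {}
        for s in spectra:
            for b in bin_peaks(s, 0.02, 40):
                recount[b] = recount.get(b, 0) + 1
        assert model.document_frequency == recount


class TestPairwiseDistance:
    def _model(self, spectra):
        return build_rarity_model(spectra, 0.02, 40)

    def test_self_distance_zero(self):
        s = _spectrum([100.0, 200.0, 300.0], [1.0, 1.0, 1.0])
        assert pairwise_distance(s, s, self._model([s])) == 0.0

    def test_disjoint_distance_one(self):
        a = _spectrum([100.0, 200.0], [1, 1], sid="a")
        b = _spectrum([400.0, 500.0], [1, 1], sid="b", scan=2)
        assert pairwise_distance(a, b, self._model([a, b])) == 1.0

    def test_incompatible_precursor_infinite(self):
        a = _spectrum([100.0], [1], prec=500.0)
        b = _spectrum([100.0], [1], prec=501.0, scan=2)
        c = _spectrum([100.0], [1], prec=500.0, charge=3, scan=3)
        m = self._model([a, b, c])
        assert pairwise_distance(a, b, m) == np.inf
        assert pairwise_distance(a, c, m) == np.inf

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(2)
        spectra = []
        for i in range(5):
            k = int(rng.integers(5, 20))
            spectra.append(_spectrum(np.sort(rng.uniform(100, 600, k)),
                                     rng.uniform(0, 1, k), sid=f"s{i}", scan=i))
        model = build_rarity_model(spectra, 0.02, 40)
        # independent oracle: recompute from bin sets and -log10 weights
        def w(bins):
            return sum(-np.log10(model.document_frequency[b] / 5) for b in bins)
        for a in spectra:
            for b in spectra:
                ba, bb = bin_peaks(a, 0.02, 40), bin_peaks(b, 0.02, 40)
                denom = min(w(ba), w(bb))
                sim = (w(ba & bb) / denom) if denom > 0 else (1.0 if ba == bb else 0.0)
                expected = min(max(1 - sim, 0.0), 1.0)
                got = pairwise_distance(a, b, model)
                assert got == pytest.approx(expected)
                assert got == pytest.approx(pairwise_distance(b, a, model))


class TestCompleteLinkage:
    def test_threshold_map(self):
        assert stringency_threshold(10) == pytest.approx(0.5)
        assert stringency_threshold(20) == 0.0
        with pytest.raises(ValueError):
            stringency_threshold(0)

    def test_all_far_apart_singletons(self):
        spectra = [_spectrum([100.0 + 10 * i], [1.0], sid=f"s{i}", scan=i,
                             prec=500.0) for i in range(6)]
        model = build_rarity_model(spectra)
        clusters = complete_linkage(spectra, model, stringency=10)
        assert all(len(c.members) == 1 for c in clusters)

    def test_replicate_blocks_recovered(self):
        spectra = []
        for g in range(3):
            mz = [100.0 + 50 * g, 200.0 + 50 * g, 300.0 + 50 * g]
            for r in range(4):
                spectra.append(_spectrum(mz, [1.0, 0.5, 0.2],
                                         sid=f"g{g}r{r}", scan=g * 4 + r,
                                         prec=400.0 + 10 * g))
        model = build_rarity_model(spectra)
        clusters = complete_linkage(spectra, model, stringency=10)
        groups = sorted(frozenset(c.members) for c in clusters)
        expected = sorted(frozenset(f"g{g}r{r}" for r in range(4)) for g in range(3))
        assert groups == expected

    def test_matrix_clustering_matches_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 13))
            dm = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            dm[iu] = rng.uniform(0, 1, iu[0].size)
            dm += dm.T
            labels = cluster_distance_matrix(dm, 0.5)
            got = sorted(sorted(np.where(labels == l)[0].tolist())
                         for l in set(labels))
            expected = sorted(sorted(c) for c in naive_complete_linkage(dm, 0.5))
            assert got == expected

    def test_partition_and_monotonicity(self, small_sim):
        spectra, _, _ = small_sim
        model = build_rarity_model(spectra)
        n_prev = 0
        for stringency in (5, 10, 15):
            clusters = complete_linkage(spectra, model, stringency)
            members = [m for c in clusters for m in c.members]
            assert len(members) == len(spectra)
            assert len(set(members)) == len(spectra)
            assert len(clusters) >= n_prev
            n_prev = len(clusters)

    def test_diameter_guarantee(self, small_sim):
        spectra, _, _ = small_sim
        model = build_rarity_model(spectra)
        t = stringency_threshold(10)
        lookup = {s.spectrum_id: s for s in spectra}
        for c in complete_linkage(spectra, model, 10):
            for i, a in enumerate(c.members):
                for b in c.members[i + 1:]:
                    assert pairwise_distance(lookup[a], lookup[b], model) <= t + 1e-12

    def test_cluster_purity_on_simulation(self):
        # multi-member clusters should nearly always hold one true peptide
        impure = multi = 0
        for seed in range(5):
            spectra, _, truth = simulate_dataset(
                SimConfig(seed=seed, n_proteins=10, peptides_per_protein=5,
                          spectra_per_peptide_per_batch=3.0))
            model = build_rarity_model(spectra)
            for c in complete_linkage(spectra, model, 10):
                if len(c.members) < 2:
                    continue
                entries = [truth.entries[m] for m in c.members]
                peps = {e.peptide.modified_sequence for e in entries
                        if e.peptide is not None}
                has_junk = any(e.peptide is None for e in entries)
                if not peps:  # all-junk cluster: no peptide claim to violate
                    continue
                multi += 1
                if len(peps) > 1 or has_junk:
                    impure += 1
        assert multi > 50
        assert impure / multi <= 0.05


class TestAnnotate:
    def _cluster(self, members):
        return Cluster(cluster_id=0, members=members)

    def _psm(self, sid, seq, charge=2):
        pep = PeptideIdent(sequence=seq, charge=charge, proteins=("P1",))
        raw, _, scan = sid.rpartition(":")
        return PSM(spectrum_ref=sid, raw_file=raw, scan=int(scan), peptide=pep,
                   search_score=1.0, posterior_error_prob=0.001, q_value=0.001)

    def test_states(self):
        clusters = [self._cluster(["r:1", "r:2", "r:3"]),
                    self._cluster(["r:4", "r:5"]),
                    self._cluster(["r:6"])]
        accepted = PSMTable([self._psm("r:1", "PEPTIDEK"),
                             self._psm("r:4", "PEPTIDEK"),
                             self._psm("r:5", "EDITPEPK")])
        annotate_clusters(clusters, accepted)
        assert clusters[0].state is ClusterState.UNIQUE
        assert clusters[1].state is ClusterState.AMBIGUOUS
        assert clusters[2].state is ClusterState.UNIDENTIFIED

    def test_same_sequence_different_charge_is_ambiguous(self):
        clusters = [self._cluster(["r:1", "r:2", "r:3"])]
        accepted = PSMTable([self._psm("r:1", "PEPTIDEK", 2),
                             self._psm("r:2", "PEPTIDEK", 3)])
        annotate_clusters(clusters, accepted)
        assert clusters[0].state is ClusterState.AMBIGUOUS
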