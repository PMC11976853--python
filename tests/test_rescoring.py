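"""Target-decoy q-values, fold assignment, semi-supervised training, PEP."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from psmtransfer import (
    FEATURE_NAMES,
    PSM,
    PSMTable,
    PeptideIdent,
    RescoreModel,
    apply_static,
    assign_folds,
    compute_qvalues,
    estimate_pep,
    merge_models,
    peptide_qvalues,
    train_rescorer,
)


def brute_force_qvalues(labels):
    """Independent oracle: direct enumeration of the
    (decoys+1)/max(targets,1) running-minimum formula, assuming PSMs are
    already given in descending-score order."""
    fdrs = []
    d = t = 0
    for is_decoy in labels:
        d += is_decoy
        t += not is_decoy
        fdrs.append((d + 1) / max(t, 1))
    qs = []
    running = float("inf")
    for f in reversed(fdrs):
        running = min(running, f)
        qs.append(min(running, 1.0))
    return qs[::-1]


class TestComputeQvalues:
    def test_frozen_example(self):
        # [T:10, T:9, D:8, T:7, D:6]; oracle gives [1/2, 1/2, 1, 2/3, 1]
        scores = [10, 9, 8, 7, 6]
        decoy = [False, False, True, False, True]
        q = compute_qvalues(scores, decoy)
        expected = brute_force_qvalues(decoy)
        assert q.tolist() == pytest.approx(expected)
        assert q[[0, 1, 3]].tolist() == pytest.approx([0.5, 0.5, 2 / 3])

    def test_no_decoys_all_one_over_n(self):
        q = compute_qvalues([5, 4, 3, 2], [False] * 4)
        assert q.tolist() == pytest.approx([0.25] * 4)

    def test_all_decoys_above_targets_clamped(self):
        q = compute_qvalues([10, 9, 2, 1], [True, True, False, False])
        assert all(qi == 1.0 for qi in q[2:])

    @given(st.lists(st.tuples(st.floats(-100, 100), st.booleans()),
                    min_size=1, max_size=60))
    def test_monotone_in_score(self, rows):
        scores = [r[0] for r in rows]
        decoy = [r[1] for r in rows]
        q = compute_qvalues(scores, decoy)
        order = np.argsort(-np.array(scores), kind="stable")
        assert all(q[order[i]] <= q[order[i + 1]] + 1e-12
                   for i in range(len(order) - 1))

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            decoy = rng.random(n) < 0.5
            scores = np.arange(n, 0, -1, dtype=float)  # strictly descending
            assert compute_qvalues(scores, decoy).tolist() == pytest.approx(
                brute_force_qvalues(decoy.tolist()))


def _psm(sid, seq, decoy=False, charge=2, feats=None, score=None):
    pep = PeptideIdent(sequence=seq, charge=charge,
                       proteins=(("REV__P1",) if decoy else ("P1",)),
                       is_decoy=decoy)
    raw, _, scan = sid.rpartition(":")
    p = PSM(spectrum_ref=sid, raw_file=raw, scan=int(scan), peptide=pep,
            search_score=score, features=feats, rescore=score)
    return p


def _random_feature_table(rng, n_targets, n_decoys, separation=0.0, noise=1.0):
    """Synthetic feature table; ``separation`` shifts target spectral angles
    (0 = exchangeable null), ``noise`` scales the uninformative features."""
    rows = []
    for i in range(n_targets + n_decoys):
        decoy = i >= n_targets
        feats = {name: float(rng.normal(0.0, noise)) for name in FEATURE_NAMES}
        feats["spectral_angle"] = float(
            np.clip(rng.normal(0.5 + (0 if decoy else separation), 0.1), 0, 1))
        feats["has_search_score"] = 1.0
        feats["is_transfer"] = 0.0
        seq = "".join(rng.choice(list("ACDEFGHILMNPQSTVWY"), 9)) + "K"
        rows.append(_psm(f"r.raw:{i+1}", seq, decoy=decoy, feats=feats,
                         score=feats["spectral_angle"]))
    return PSMTable(rows)


class TestAssignFolds:
    def test_spectrum_and_peptide_cohesion(self):
        rows = [
            _psm("r:1", "AAAAAAAK"), _psm("r:1", "CCCCCCCK"),  # same spectrum
            _psm("r:2", "CCCCCCCK"),  # shares peptide with r:1's 2nd candidate
            _psm("r:3", "DDDDDDDK"),
        ]
        folds = assign_folds(PSMTable(rows), 3)
        assert folds[0] == folds[1] == folds[2]

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        table = _random_feature_table(rng, 30, 30)
        f1 = assign_folds(table, 3)
        f2 = assign_folds(table, 3)
        assert np.array_equal(f1, f2)


class TestTrainRescorer:
    def test_training_does_no_harm_under_perfect_separation(self):
        # spectral angle alone separates targets from decoys completely:
        # the trained model must accept at least the SA-accepted set
        rng = np.random.default_rng(1)
        table = _random_feature_table(rng, 600, 600, separation=0.0, noise=0.2)
        for p in table:
            lo, hi = (0.0, 0.35) if p.is_decoy else (0.65, 1.0)
            p.features["spectral_angle"] = float(rng.uniform(lo, hi))
        sa = [p.features["spectral_angle"] for p in table]
        decoy = [p.is_decoy for p in table]
        q_sa = compute_qvalues(sa, decoy)
        sa_set = {p.spectrum_ref for p, q in zip(table, q_sa)
                  if not p.is_decoy and q <= 0.01}
        _, scored = train_rescorer(table, seed=1)
        trained_set = {p.spectrum_ref for p in scored
                       if not p.is_decoy and p.q_value <= 0.01}
        assert sa_set and sa_set <= trained_set

    def test_null_calibration(self):
        # label-scrambled decoys: acceptance at 1% stays near-nominal
        accepted = decoys = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            table = _random_feature_table(rng, 300, 300, separation=0.0)
            _, scored = train_rescorer(table, seed=seed)
            accepted += sum(1 for p in scored if not p.is_decoy and p.q_value <= 0.01)
            decoys += sum(1 for p in scored if p.is_decoy)
        assert accepted <= 3 * 0.01 * decoys

    def test_determinism(self):
        rng = np.random.default_rng(2)
        table = _random_feature_table(rng, 100, 100, separation=0.3)
        m1, s1 = train_rescorer(table, seed=7)
        m2, s2 = train_rescorer(table, seed=7)
        for a, b in zip(m1, m2):
            assert a.weights == b.weights and a.intercept == b.intercept
        assert [p.q_value for p in s1] == [p.q_value for p in s2]
        assert [p.rescore for p in s1] == [p.rescore for p in s2]


class TestApplyStatic:
    def test_zero_weights_degenerate(self):
        rng = np.random.default_rng(3)
        table = _random_feature_table(rng, 20, 20)
        model = RescoreModel(weights={n: 0.0 for n in FEATURE_NAMES}, intercept=1.5)
        scored = apply_static(model, table)
        assert all(p.rescore == 1.5 for p in scored)
        target_qs = {p.q_value for p in scored if not p.is_decoy}
        assert len(target_qs) == 1

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(3)
        table = _random_feature_table(rng, 5, 5)
        model = RescoreModel(weights={"nope": 1.0}, intercept=0.0)
        with pytest.raises(ValueError):
            apply_static(model, table)

    def test_normalization_scale_invariant_ranking(self):
        rng = np.random.default_rng(5)
        table = _random_feature_table(rng, 50, 50, separation=0.2)
        w = {n: float(rng.normal()) for n in FEATURE_NAMES}
        m1 = RescoreModel(weights=w, intercept=0.0)
        m2 = RescoreModel(weights=w, intercept=0.0,
                          center={n: 1.0 for n in FEATURE_NAMES},
                          scale={n: 2.0 for n in FEATURE_NAMES})
        r1 = [p.rescore for p in apply_static(m1, table)]
        r2 = [p.rescore for p in apply_static(m2, table)]
        assert np.array_equal(np.argsort(r1), np.argsort(r2))

    def test_static_equals_merged_training_weights(self):
        rng = np.random.default_rng(6)
        table = _random_feature_table(rng, 100, 100, separation=0.3)
        models, scored = train_rescorer(table, seed=0)
        static = merge_models(models)
        # re-applying the merged static model reproduces a deterministic scoring
        s1 = apply_static(static, table)
        s2 = apply_static(static, table)
        assert [p.rescore for p in s1] == [p.rescore for p in s2]


class TestEstimatePEP:
    def test_separated_distributions(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(10, 0.5, 400), rng.normal(0, 0.5, 400)])
        decoy = np.concatenate([np.zeros(400, bool), np.ones(400, bool)])
        pep = estimate_pep(scores, decoy)
        assert np.all(pep[:400] < 0.1)
        assert np.all(pep[400:] > 0.9)

    def test_null_distributions_near_one(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 1000)
        decoy = rng.random(1000) < 0.5
        pep = estimate_pep(scores, decoy)
        assert np.median(pep) > 0.7

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 2, 800)
        decoy = rng.random(800) < (1 / (1 + np.exp(scores)))
        pep = estimate_pep(scores, decoy)
        order = np.argsort(scores)
        assert np.all(np.diff(pep[order]) <= 1e-12)

    def test_small_sample_falls_back_to_q(self):
        with pytest.warns(UserWarning, match="fallback"):
            pep = estimate_pep([3.0, 2.0, 1.0], [False, False, True])
        assert pep.tolist() == pytest.approx(
            compute_qvalues([3.0, 2.0, 1.0], [False, False, True]).tolist())


class TestPeptideQvalues:
    def test_best_psm_per_peptide(self):
        rows = [_psm("r:1", "AAAAAAAK", score=5.0), _psm("r:2", "AAAAAAAK", score=7.0),
                _psm("r:3", "CCCCCCCK", score=6.0, decoy=False)]
        out = peptide_qvalues(PSMTable(rows))
        assert len(out) == 2
        by_seq = {p.peptide.sequence: p for p in out}
        assert by_seq["AAAAAAAK"].rescore == 7.0
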