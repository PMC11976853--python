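"""Semi-supervised linear target-decoy rescoring and FDR machinery.

The learner follows the Percolator recipe: starting from the spectral
angle as the initial score direction, each iteration labels as positives
the target PSMs passing the training FDR under the current score, takes
all decoys as negatives, and refits a linear large-margin classifier
(L2-regularized squared hinge, C = 1, solved in the primal for
determinism). Cross-validation folds are assigned by a stable hash so
that all candidate PSMs of one spectrum — and all PSMs of one peptide —
share a fold; each fold is scored by the averaged weights of the models
trained on the *other* folds, which keeps every score out-of-sample.

q-values come from target-decoy competition with the conservative +1
pseudocount: sort descending by score, running FDR at rank i is
(decoys(i) + 1) / max(targets(i), 1), and the q-value is the running
minimum from the bottom up, clipped to 1. Posterior error probabilities
(local FDR) are estimated by isotonic regression of the binned
decoy/target ratio, non-increasing in score.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.svm import LinearSVC

from .features import FEATURE_NAMES, features_matrix
from .spectra import PSM, PSMTable

DEFAULT_TRAIN_FDR = 0.01
DEFAULT_N_ITERATIONS = 10
DEFAULT_N_FOLDS = 3
_MIN_PSMS_FOR_PEP = 500

_SA_INDEX = FEATURE_NAMES.index("spectral_angle")


def stable_hash(text: str) -> int:
    """Process-independent integer hash (md5-based)."""
    return int.from_bytes(hashlib.md5(text.encode()).digest()[:8], "big")


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def compute_qvalues(scores, is_decoy) -> np.ndarray:
    """Target-decoy q-values for every PSM (targets and decoys alike).

    FDR at rank i (descending score) = (decoys(i) + 1) / max(targets(i), 1);
    the q-value is the bottom-up running minimum, clipped to 1. Ties are
    broken by input order (callers pre-sort canonically for determinism).
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    if scores.size == 0:
        return np.zeros(0)
    order = np.argsort(-scores, kind="stable")
    d = np.cumsum(decoy[order])
    t = np.cumsum(~decoy[order])
    fdr = (d + 1) / np.maximum(t, 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# fold assignment (leakage guard)
# ---------------------------------------------------------------------------

def assign_folds(psms: PSMTable, n_folds: int) -> np.ndarray:
    """Fold per PSM such that all candidates of one spectrum and all PSMs
    of one peptide land in the same fold.

    Spectrum/peptide co-membership chains (keep_all candidates link one
    spectrum to several peptides), so folds are assigned to connected
    components of the spectrum-peptide graph, hashed by the component's
    lexicographically smallest peptide sequence.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for p in psms:
        union("s:" + p.spectrum_ref, "p:" + p.peptide.modified_sequence)
    comp_key: dict[str, str] = {}
    for p in psms:
        root = find("s:" + p.spectrum_ref)
        key = comp_key.get(root)
        seq = p.peptide.modified_sequence
        if key is None or seq < key:
            comp_key[root] = seq
    folds = np.empty(len(psms), dtype=int)
    for i, p in enumerate(psms):
        folds[i] = stable_hash(comp_key[find("s:" + p.spectrum_ref)]) % n_folds
    return folds


# ---------------------------------------------------------------------------
# the linear model
# ---------------------------------------------------------------------------

@dataclass
class RescoreModel:
    """Linear weights over FEATURE_NAMES with a per-feature normalization."""

    weights: dict[str, float]
    intercept: float
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    n_iterations: int = DEFAULT_N_ITERATIONS
    train_fdr: float = DEFAULT_TRAIN_FDR

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = np.array([self.weights[n] for n in FEATURE_NAMES])
        c = np.array([self.center.get(n, 0.0) for n in FEATURE_NAMES])
        s = np.array([self.scale.get(n, 1.0) for n in FEATURE_NAMES])
        return w, c, s

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        w, c, s = self._arrays()
        return ((X - c) / s) @ w + self.intercept

    def raw_space(self) -> "RescoreModel":
        """Equivalent model with identity normalization."""
        w, c, s = self._arrays()
        w_raw = w / s
        b_raw = self.intercept - float(np.dot(w_raw, c))
        return RescoreModel(
            weights=dict(zip(FEATURE_NAMES, w_raw.tolist())),
            intercept=b_raw,
            n_iterations=self.n_iterations,
            train_fdr=self.train_fdr,
        )


def merge_models(models: list[RescoreModel]) -> RescoreModel:
    """Average models in raw feature space (identity normalization)."""
    raws = [m.raw_space() for m in models]
    weights = {
        n: float(np.mean([m.weights[n] for m in raws])) for n in FEATURE_NAMES
    }
    intercept = float(np.mean([m.intercept for m in raws]))
    return RescoreModel(weights=weights, intercept=intercept,
                        n_iterations=raws[0].n_iterations, train_fdr=raws[0].train_fdr)


def _sa_direction() -> RescoreModel:
    weights = {n: 0.0 for n in FEATURE_NAMES}
    weights["spectral_angle"] = 1.0
    return RescoreModel(weights=weights, intercept=0.0)


def _train_one_fold(X: np.ndarray, decoy: np.ndarray, train_fdr: float,
                    n_iterations: int) -> RescoreModel:
    targets = ~decoy
    if not targets.any() or not decoy.any():
        warnings.warn("fold lacks targets or decoys; using spectral-angle direction")
        return _sa_direction()
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xn = (X - center) / scale
    score = X[:, _SA_INDEX]
    clf = None
    for _ in range(n_iterations):
        q = compute_qvalues(score, decoy)
        pos = targets & (q <= train_fdr)
        if not pos.any():
            warnings.warn("no positives at training FDR; falling back to top targets")
            t_idx = np.where(targets)[0]
            top = t_idx[np.argsort(-score[t_idx], kind="stable")[:100]]
            pos = np.zeros_like(targets)
            pos[top] = True
        idx = pos | decoy
        y = np.where(pos[idx], 1, 0)
        clf = LinearSVC(C=1.0, dual=False, tol=1e-6, max_iter=20000)
        clf.fit(Xn[idx], y)
        score = clf.decision_function(Xn)
    return RescoreModel(
        weights=dict(zip(FEATURE_NAMES, clf.coef_[0].tolist())),
        intercept=float(clf.intercept_[0]),
        center=dict(zip(FEATURE_NAMES, center.tolist())),
        scale=dict(zip(FEATURE_NAMES, scale.tolist())),
        n_iterations=n_iterations,
        train_fdr=train_fdr,
    )


def train_rescorer(features: PSMTable, train_fdr: float = DEFAULT_TRAIN_FDR,
                   n_iterations: int = DEFAULT_N_ITERATIONS,
                   n_folds: int = DEFAULT_N_FOLDS,
                   seed: int = 0) -> tuple[list[RescoreModel], PSMTable]:
    """Cross-validated semi-supervised rescoring.

    Returns one model per fold and the scored table: every PSM gains a
    ``rescore`` (out-of-sample: averaged weights of the other folds) and a
    global ``q_value`` over the merged held-out scores. Deterministic for
    a fixed input and seed (the seed only seeds the classifier, which is
    itself deterministic; it is accepted for interface stability).
    """
    table = features.sorted()
    X = features_matrix(table)
    decoy = np.array([p.is_decoy for p in table])
    folds = assign_folds(table, n_folds)
    models: list[RescoreModel] = []
    for f in range(n_folds):
        mask = folds == f
        if not mask.any():
            models.append(_sa_direction())
            continue
        models.append(_train_one_fold(X[mask], decoy[mask], train_fdr, n_iterations))
    scores = np.empty(len(table.rows))
    for f in range(n_folds):
        mask = folds == f
        if not mask.any():
            continue
        others = [m for g, m in enumerate(models) if g != f] or models
        scores[mask] = merge_models(others).score_matrix(X[mask])
    q = compute_qvalues(scores, decoy)
    rows = []
    for i, p in enumerate(table.rows):
        rows.append(p.copy(rescore=float(scores[i]), q_value=float(q[i]), fold=int(folds[i])))
    prov = dict(table.provenance)
    prov["rescoring"] = {"n_folds": n_folds, "n_iterations": n_iterations,
                         "train_fdr": train_fdr, "seed": seed}
    return models, PSMTable(rows, prov)


def apply_static(model: RescoreModel, features: PSMTable) -> PSMTable:
    """Score a feature table with fixed weights (no retraining) and
    recompute q-values on the new population."""
    for name in FEATURE_NAMES:
        if name not in model.weights:
            raise ValueError(f"model lacks weight for feature {name!r}")
    unknown = set(model.weights) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"model has unknown feature names: {sorted(unknown)}")
    table = features.sorted()
    X = features_matrix(table)
    scores = model.score_matrix(X)
    decoy = np.array([p.is_decoy for p in table])
    q = compute_qvalues(scores, decoy)
    rows = [p.copy(rescore=float(scores[i]), q_value=float(q[i]))
            for i, p in enumerate(table.rows)]
    return PSMTable(rows, dict(table.provenance))


# ---------------------------------------------------------------------------
# posterior error probability
# ---------------------------------------------------------------------------

def estimate_pep(scores, is_decoy, n_bins: int = 50) -> np.ndarray:
    """Per-PSM posterior error probability: isotonic (non-increasing in
    score) estimate of the local decoy/target ratio, clipped to [0, 1].

    Falls back to q-values with a warning below 500 PSMs.
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    n = scores.size
    if n < _MIN_PSMS_FOR_PEP:
        warnings.warn(f"only {n} PSMs; using q-values as PEP fallback")
        return compute_qvalues(scores, decoy)
    order = np.argsort(-scores, kind="stable")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    centers, ratios, weights = [], [], []
    for k in range(n_bins):
        sl = order[edges[k]:edges[k + 1]]
        if sl.size == 0:
            continue
        nd = int(decoy[sl].sum())
        nt = sl.size - nd
        centers.append(float(scores[sl].mean()))
        ratios.append(min(nd / max(nt, 1), 1.0) if nt else 1.0)
        weights.append(sl.size)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    iso.fit(centers, ratios, sample_weight=weights)
    return np.clip(iso.predict(scores), 0.0, 1.0)


def attach_pep(scored: PSMTable, n_bins: int = 50) -> PSMTable:
    """Recompute PEPs from rescores and attach them to each PSM."""
    scores = np.array([p.rescore for p in scored])
    decoy = np.array([p.is_decoy for p in scored])
    pep = estimate_pep(scores, decoy, n_bins)
    rows = [p.copy(posterior_error_prob=float(pep[i])) for i, p in enumerate(scored)]
    return PSMTable(rows, dict(scored.provenance))


def peptide_qvalues(scored: PSMTable) -> PSMTable:
    """Peptide-level q-values: keep each peptide's best PSM, recompute q."""
    best: dict[tuple[str, int], PSM] = {}
    for p in scored:
        key = p.peptide.ident_key
        cur = best.get(key)
        if cur is None or p.rescore > cur.rescore or \
                (p.rescore == cur.rescore and p.spectrum_ref < cur.spectrum_ref):
            best[key] = p
    rows = [best[k] for k in sorted(best)]
    scores = np.array([p.rescore for p in rows])
    decoy = np.array([p.is_decoy for p in rows])
    q = compute_qvalues(scores, decoy)
    rows = [p.copy(q_value=float(q[i])) for i, p in enumerate(rows)]
    return PSMTable(rows, {"level": "peptide"})
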