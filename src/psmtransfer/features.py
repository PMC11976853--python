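"""Similarity features between observed spectra and predicted peptide properties.

The central feature is the normalized spectral contrast angle between the
observed fragment intensities and a predicted fragment pattern:

    SA = 1 - 2 * arccos(x_obs . x_pred) / pi

where both vectors are square-root transformed and L2-normalized over the
union of predicted ions. SA is 1 when the two patterns are identical and 0
when no observed peak falls within the matching tolerance of any predicted
ion. Retention-time deviation is computed after a per-run monotone
piecewise-linear calibration fitted on confident anchor PSMs.

Chimeric (co-isolated) spectra need no special handling: each candidate is
scored independently against the same observed spectrum, so two conflicting
identifications of one spectrum can both reach a high spectral angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from pyteomics import mass as _mass
from sklearn.isotonic import IsotonicRegression

from .spectra import PSM, PSMTable, PeptideIdent, Spectrum, peptide_is_predictable

DEFAULT_FRAGMENT_TOL = 0.02  # Da
MIN_RT_ANCHORS = 10
MAX_RT_ANCHORS = 200

#: monoisotopic mass shifts of the modification names the package knows
MOD_MASSES = {"ox": 15.994915, "ac": 42.010565, "ph": 79.966331, "cm": 57.021464}

#: clamp for the precursor mass error feature, ppm
_PPM_CLAMP = 50.0

FEATURE_NAMES = (
    "spectral_angle",
    "pearson_corr",
    "matched_ion_fraction",
    "abs_rt_delta",
    "has_search_score",
    "search_score",
    "precursor_mass_error_ppm",
    "peptide_length",
    "charge_1",
    "charge_2",
    "charge_3",
    "charge_4",
    "charge_5",
    "charge_6",
    "is_transfer",
)


@dataclass(frozen=True)
class FragmentPrediction:
    """Annotated theoretical ion list with relative intensities in [0, 1]."""

    labels: tuple[str, ...]
    mz: np.ndarray
    intensity: np.ndarray  # normalized to max 1


class PropertyProvider(Protocol):
    def predict_fragments(self, peptide: PeptideIdent) -> FragmentPrediction: ...

    def predict_rt(self, peptide: PeptideIdent) -> float: ...


class TableProvider:
    """Property provider backed by a predictions table (TSV).

    Columns: ``modified_sequence``, ``predicted_rt``, and semicolon-joined
    ``ion_labels``, ``ion_mz``, ``ion_intensity``. Intensities are
    renormalized to max 1 on load.
    """

    def __init__(self, predictions: dict[str, tuple["FragmentPrediction", float]]):
        self._predictions = predictions

    @classmethod
    def from_tsv(cls, path) -> "TableProvider":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        preds = {}
        for rec in df.itertuples(index=False):
            inten = np.array([float(x) for x in rec.ion_intensity.split(";")])
            if inten.max() > 0:
                inten = inten / inten.max()
            preds[rec.modified_sequence] = (
                FragmentPrediction(
                    labels=tuple(rec.ion_labels.split(";")),
                    mz=np.array([float(x) for x in rec.ion_mz.split(";")]),
                    intensity=inten,
                ),
                float(rec.predicted_rt),
            )
        return cls(preds)

    @staticmethod
    def write_tsv(provider: "PropertyProvider", peptides, path) -> None:
        """Dump another provider's predictions for a peptide list."""
        import pandas as pd

        recs = []
        seen = set()
        for pep in peptides:
            key = pep.modified_sequence
            if key in seen:
                continue
            seen.add(key)
            pred = provider.predict_fragments(pep)
            recs.append({
                "modified_sequence": key,
                "predicted_rt": provider.predict_rt(pep),
                "ion_labels": ";".join(pred.labels),
                "ion_mz": ";".join(f"{x:.6f}" for x in pred.mz),
                "ion_intensity": ";".join(f"{x:.8f}" for x in pred.intensity),
            })
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)

    def predict_fragments(self, peptide: PeptideIdent) -> "FragmentPrediction":
        return self._predictions[peptide.modified_sequence][0]

    def predict_rt(self, peptide: PeptideIdent) -> float:
        return self._predictions[peptide.modified_sequence][1]


def fragment_ions(peptide: PeptideIdent) -> tuple[tuple[str, ...], np.ndarray]:
    """Singly-charged b/y ion labels and m/z values for a peptide
    (b2..b[n-1], y1..y[n-1]); modification masses are added to the
    covering fragments."""
    seq = peptide.sequence
    n = len(seq)
    mods = dict(peptide.modifications)
    labels: list[str] = []
    mzs: list[float] = []
    for i in range(2, n):  # b2 .. b(n-1)
        m = _mass.fast_mass(seq[:i], ion_type="b", charge=1)
        m += sum(MOD_MASSES.get(name, 0.0) for pos, name in mods.items() if 0 <= pos <= i)
        labels.append(f"b{i}")
        mzs.append(m)
    for i in range(1, n):  # y1 .. y(n-1)
        m = _mass.fast_mass(seq[n - i:], ion_type="y", charge=1)
        m += sum(MOD_MASSES.get(name, 0.0) for pos, name in mods.items() if pos > n - i)
        labels.append(f"y{i}")
        mzs.append(m)
    return tuple(labels), np.array(mzs)


def precursor_mz(peptide: PeptideIdent) -> float:
    """Theoretical precursor m/z including known modification masses."""
    m = _mass.fast_mass(peptide.sequence, charge=0)
    m += sum(MOD_MASSES.get(name, 0.0) for _, name in peptide.modifications)
    z = max(peptide.charge, 1)
    return (m + z * 1.00727646688) / z  # proton mass


def match_peaks(observed: Spectrum, predicted_mz: np.ndarray,
                fragment_tol: float = DEFAULT_FRAGMENT_TOL) -> np.ndarray:
    """One-to-one nearest matching of observed peaks to predicted ions.

    Returns, per predicted ion, the matched observed intensity (0 if no
    observed peak lies within ``fragment_tol``). Candidate pairs are
    assigned greedily by ascending |Δm/z| so the nearest pairing wins and
    each observed peak is used at most once.
    """
    out = np.zeros(predicted_mz.size)
    if observed.n_peaks == 0 or predicted_mz.size == 0:
        return out
    obs_mz = observed.mz
    cand: list[tuple[float, int, int]] = []
    for i, pm in enumerate(predicted_mz):
        lo = np.searchsorted(obs_mz, pm - fragment_tol, side="left")
        hi = np.searchsorted(obs_mz, pm + fragment_tol, side="right")
        for j in range(lo, hi):
            cand.append((abs(obs_mz[j] - pm), i, j))
    cand.sort()
    used_pred: set[int] = set()
    used_obs: set[int] = set()
    for _, i, j in cand:
        if i in used_pred or j in used_obs:
            continue
        out[i] = observed.intensity[j]
        used_pred.add(i)
        used_obs.add(j)
    return out


def spectral_angle(observed: Spectrum, predicted: FragmentPrediction,
                   fragment_tol: float = DEFAULT_FRAGMENT_TOL) -> float:
    """Normalized spectral contrast angle in [0, 1] (1 identical, 0 no overlap)."""
    if predicted.mz.size == 0:
        raise ValueError("predicted ion list is empty")
    obs = match_peaks(observed, predicted.mz, fragment_tol)
    if not np.any(obs > 0):
        return 0.0
    a = np.sqrt(obs)
    b = np.sqrt(np.clip(predicted.intensity, 0.0, None))
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    dot = float(np.clip(np.dot(a / na, b / nb), 0.0, 1.0))
    return float(1.0 - 2.0 * np.arccos(dot) / np.pi)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def align_rt(psms: PSMTable, spectra: list[Spectrum], provider: PropertyProvider,
             min_anchors: int = MIN_RT_ANCHORS,
             max_anchors: int = MAX_RT_ANCHORS) -> dict[str, Callable[[float], float]]:
    """Per-run monotone piecewise-linear map from predicted to observed RT.

    Anchors are the best-scoring target PSMs of each run; runs with fewer
    than ``min_anchors`` anchors fall back to the identity map with a
    warning. The returned callables clip outside the anchor range.
    """
    rt_by_spectrum = {s.spectrum_id: s.retention_time for s in spectra}
    anchors: dict[str, list[tuple[float, float, float]]] = {}
    for p in psms:
        if p.is_decoy or p.search_score is None or p.spectrum_ref not in rt_by_spectrum:
            continue
        anchors.setdefault(p.raw_file, []).append(
            (p.search_score, provider.predict_rt(p.peptide), rt_by_spectrum[p.spectrum_ref])
        )
    out: dict[str, Callable[[float], float]] = {}
    for raw_file, rows in anchors.items():
        rows.sort(key=lambda r: -r[0])
        rows = rows[:max_anchors]
        if len(rows) < min_anchors:
            warnings.warn(f"run {raw_file}: only {len(rows)} RT anchors, using identity map")
            out[raw_file] = lambda x: x
            continue
        pred = np.array([r[1] for r in rows])
        obs = np.array([r[2] for r in rows])
        iso = IsotonicRegression(out_of_bounds="clip").fit(pred, obs)
        out[raw_file] = lambda x, _iso=iso: float(_iso.predict([x])[0])
    return out


def compute_features(psm: PSM, spectrum: Spectrum, provider: PropertyProvider,
                     rt_map: Callable[[float], float] | None = None,
                     fragment_tol: float = DEFAULT_FRAGMENT_TOL) -> dict[str, float]:
    """The full feature vector for one candidate PSM (no missing values)."""
    pred = provider.predict_fragments(psm.peptide)
    obs = match_peaks(spectrum, pred.mz, fragment_tol)
    sa = spectral_angle(spectrum, pred, fragment_tol)
    matched = obs > 0
    pred_rt = provider.predict_rt(psm.peptide)
    calibrated = rt_map(pred_rt) if rt_map is not None else pred_rt
    theo_mz = precursor_mz(psm.peptide)
    ppm = (spectrum.precursor_mz - theo_mz) / theo_mz * 1e6
    is_transfer = 1.0 if psm.origin == "transfer" else 0.0
    has_score = 1.0 if psm.search_score is not None else 0.0
    feats = {
        "spectral_angle": sa,
        "pearson_corr": _pearson(obs, pred.intensity),
        "matched_ion_fraction": float(np.count_nonzero(matched)) / pred.mz.size,
        "abs_rt_delta": abs(spectrum.retention_time - calibrated),
        "has_search_score": has_score,
        "search_score": float(psm.search_score) if psm.search_score is not None else 0.0,
        "precursor_mass_error_ppm": float(np.clip(ppm, -_PPM_CLAMP, _PPM_CLAMP)),
        "peptide_length": float(len(psm.peptide.sequence)),
        "is_transfer": is_transfer,
    }
    for z in range(1, 7):
        feats[f"charge_{z}"] = 1.0 if psm.peptide.charge == z else 0.0
    return feats


def featurize(psms: PSMTable, spectra: list[Spectrum], provider: PropertyProvider,
              fragment_tol: float = DEFAULT_FRAGMENT_TOL,
              rt_maps: dict[str, Callable[[float], float]] | None = None) -> PSMTable:
    """Attach a complete FeatureVector to every PSM.

    PSMs whose peptide the provider does not cover (unpredictable) are
    dropped; the count is recorded in provenance. ``rt_maps`` defaults to
    a calibration fitted on this table's own search PSMs.
    """
    lookup = {s.spectrum_id: s for s in spectra}
    if rt_maps is None:
        rt_maps = align_rt(psms, spectra, provider)
    rows: list[PSM] = []
    n_dropped = 0
    for p in psms:
        spec = lookup.get(p.spectrum_ref)
        if spec is None or not peptide_is_predictable(p.peptide):
            n_dropped += 1
            continue
        rt_map = rt_maps.get(p.raw_file)
        try:
            feats = compute_features(p, spec, provider, rt_map, fragment_tol)
        except KeyError:  # peptide outside the provider's domain
            n_dropped += 1
            continue
        q = p.copy()
        q.features = feats
        rows.append(q)
    prov = dict(psms.provenance)
    prov["n_dropped_featurize"] = n_dropped
    return PSMTable(rows, prov)


def features_matrix(psms: PSMTable) -> np.ndarray:
    """PSM features as an (n, len(FEATURE_NAMES)) array in canonical order."""
    X = np.zeros((len(psms), len(FEATURE_NAMES)))
    for i, p in enumerate(psms):
        if p.features is None:
            raise ValueError(f"PSM {p.spectrum_ref} has no features")
        for j, name in enumerate(FEATURE_NAMES):
            X[i, j] = p.features[name]
    return X
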