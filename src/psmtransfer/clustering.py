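"""Cross-batch MS2 spectrum clustering.

Spectra are discretized into m/z bins; bins shared by few spectra carry
more evidence than ubiquitous ones, so each bin b is weighted
``w(b) = -log10(df(b) / n_spectra)`` (an IDF weight over the spectrum
corpus). The pairwise distance between two precursor-compatible spectra is
``1 - S`` where S is the rarity-weighted overlap of their bin sets
normalized by the lighter of the two spectra. Complete-linkage hierarchical
clustering then cuts the dendrogram at ``t = 1 - stringency/20``, so the
stringency-10 default corresponds to a diameter bound of 0.5 and higher
stringencies demand greater similarity.

Precursor compatibility (same known charge, precursor m/z within
``precursor_tol`` Da) gates every comparison; incompatible pairs are at
infinite distance, and clustering runs independently within each
connected precursor stratum so the full O(n^2) matrix is never formed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .spectra import PSMTable, Spectrum

DEFAULT_BIN_WIDTH = 0.02  # Da
DEFAULT_TOP_K = 40
DEFAULT_PRECURSOR_TOL = 0.01  # Da, ~10 ppm at m/z 1000
DEFAULT_STRINGENCY = 10

#: placeholder for "incompatible" inside a stratum (> any cut threshold)
_INF_DISTANCE = 2.0


class ClusterState(str, Enum):
    UNIDENTIFIED = "unidentified"
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"


@dataclass
class Cluster:
    cluster_id: int
    members: list[str]  # spectrum_ids
    identifications: set[tuple[str, int]] = field(default_factory=set)

    @property
    def state(self) -> ClusterState:
        if not self.identifications:
            return ClusterState.UNIDENTIFIED
        if len(self.identifications) == 1:
            return ClusterState.UNIQUE
        return ClusterState.AMBIGUOUS


@dataclass
class RarityModel:
    """Document frequencies of m/z bins over a spectrum corpus."""

    bin_width: float
    document_frequency: dict[int, int]
    n_spectra: int
    top_k: int

    def weight(self, bin_index: int) -> float:
        df = self.document_frequency.get(bin_index, 1)
        return float(-np.log10(df / self.n_spectra))


def bin_peaks(spectrum: Spectrum, bin_width: float = DEFAULT_BIN_WIDTH,
              top_k: int = DEFAULT_TOP_K) -> frozenset[int]:
    """Bin indices of the top_k most intense peaks: floor(mz / bin_width)."""
    if spectrum.n_peaks == 0:
        return frozenset()
    if spectrum.n_peaks > top_k:
        # stable tie-break: lower m/z wins among equal intensities
        order = np.lexsort((spectrum.mz, -spectrum.intensity))[:top_k]
        mz = spectrum.mz[order]
    else:
        mz = spectrum.mz
    return frozenset(np.floor(mz / bin_width).astype(np.int64).tolist())


def build_rarity_model(spectra: list[Spectrum], bin_width: float = DEFAULT_BIN_WIDTH,
                       top_k: int = DEFAULT_TOP_K) -> RarityModel:
    if not spectra:
        raise ValueError("rarity model needs at least one spectrum")
    df: Counter[int] = Counter()
    for s in spectra:
        df.update(bin_peaks(s, bin_width, top_k))
    return RarityModel(bin_width=bin_width, document_frequency=dict(df),
                       n_spectra=len(spectra), top_k=top_k)


def _binned_weight(bins: frozenset[int], model: RarityModel) -> float:
    return sum(model.weight(b) for b in bins)


def pairwise_distance(a: Spectrum, b: Spectrum, model: RarityModel,
                      precursor_tol: float = DEFAULT_PRECURSOR_TOL) -> float:
    """Rarity-weighted distance in [0, 1], or +inf if precursor-incompatible."""
    if not _precursor_compatible(a, b, precursor_tol):
        return float("inf")
    bins_a = bin_peaks(a, model.bin_width, model.top_k)
    bins_b = bin_peaks(b, model.bin_width, model.top_k)
    return _bin_distance(bins_a, bins_b, model)


def _precursor_compatible(a: Spectrum, b: Spectrum, precursor_tol: float) -> bool:
    if a.precursor_charge and b.precursor_charge and a.precursor_charge != b.precursor_charge:
        return False
    return abs(a.precursor_mz - b.precursor_mz) <= precursor_tol


def _bin_distance(bins_a: frozenset[int], bins_b: frozenset[int], model: RarityModel) -> float:
    wa = _binned_weight(bins_a, model)
    wb = _binned_weight(bins_b, model)
    denom = min(wa, wb)
    if denom <= 0.0:
        # all bins ubiquitous: no rarity evidence either way
        sim = 1.0 if bins_a == bins_b and bins_a else 0.0
    else:
        sim = _binned_weight(bins_a & bins_b, model) / denom
    return float(min(max(1.0 - sim, 0.0), 1.0))


def stringency_threshold(stringency: int) -> float:
    """Dendrogram cut distance for a stringency level: t = 1 - stringency/20."""
    if stringency < 1:
        raise ValueError("stringency must be >= 1")
    return max(1.0 - stringency / 20.0, 0.0)


def cluster_distance_matrix(dm: np.ndarray, t: float) -> np.ndarray:
    """Complete-linkage labels for a square distance matrix cut at ``t``.

    The workhorse behind :func:`complete_linkage`; exposed so the
    agglomeration can be checked against exhaustive oracles.
    """
    Z = linkage(squareform(dm, checks=False), method="complete")
    return fcluster(Z, t=t, criterion="distance")


def _strata(spectra: list[Spectrum], precursor_tol: float) -> list[list[int]]:
    """Indices grouped by charge, then chained by precursor m/z proximity."""
    by_charge: dict[int, list[int]] = {}
    for i, s in enumerate(spectra):
        by_charge.setdefault(s.precursor_charge, []).append(i)
    strata: list[list[int]] = []
    for charge in sorted(by_charge):
        idx = sorted(by_charge[charge], key=lambda i: (spectra[i].precursor_mz, i))
        current = [idx[0]]
        for i in idx[1:]:
            if spectra[i].precursor_mz - spectra[current[-1]].precursor_mz <= precursor_tol:
                current.append(i)
            else:
                strata.append(current)
                current = [i]
        strata.append(current)
    return strata


def complete_linkage(spectra: list[Spectrum], model: RarityModel,
                     stringency: int = DEFAULT_STRINGENCY,
                     precursor_tol: float = DEFAULT_PRECURSOR_TOL) -> list[Cluster]:
    """Agglomerative complete-linkage clustering cut at the stringency threshold.

    Every emitted cluster satisfies the complete-linkage diameter bound
    (max intra-cluster distance <= threshold). Deterministic given input
    order; cluster_ids are assigned in order of each cluster's first
    member in the input.
    """
    t = stringency_threshold(stringency)
    assignment: dict[int, int] = {}
    next_label = 0
    for stratum in _strata(spectra, precursor_tol):
        if len(stratum) == 1:
            assignment[stratum[0]] = next_label
            next_label += 1
            continue
        bins = [bin_peaks(spectra[i], model.bin_width, model.top_k) for i in stratum]
        n = len(stratum)
        dm = np.zeros((n, n))
        for i in range(n):
            si = spectra[stratum[i]]
            for j in range(i + 1, n):
                sj = spectra[stratum[j]]
                if _precursor_compatible(si, sj, precursor_tol):
                    d = _bin_distance(bins[i], bins[j], model)
                else:
                    d = _INF_DISTANCE
                dm[i, j] = dm[j, i] = d
        labels = cluster_distance_matrix(dm, t)
        local: dict[int, int] = {}
        for i, lab in enumerate(labels):
            if lab not in local:
                local[lab] = next_label
                next_label += 1
            assignment[stratum[i]] = local[lab]
    # renumber in order of first appearance over the input spectrum order
    remap: dict[int, int] = {}
    clusters: dict[int, Cluster] = {}
    for i, s in enumerate(spectra):
        lab = assignment[i]
        if lab not in remap:
            cid = len(remap)
            remap[lab] = cid
            clusters[cid] = Cluster(cluster_id=cid, members=[])
        clusters[remap[lab]].members.append(s.spectrum_id)
    return [clusters[c] for c in sorted(clusters)]


def annotate_clusters(clusters: list[Cluster], accepted_psms: PSMTable) -> list[Cluster]:
    """Attach distinct (modified sequence, charge) identifications per cluster.

    ``accepted_psms`` must already be filtered to the input FDR.
    """
    by_spectrum: dict[str, set[tuple[str, int]]] = {}
    for p in accepted_psms:
        by_spectrum.setdefault(p.spectrum_ref, set()).add(p.peptide.ident_key)
    for c in clusters:
        idents: set[tuple[str, int]] = set()
        for sid in c.members:
            idents |= by_spectrum.get(sid, set())
        c.identifications = idents
    return clusters


def write_clusters(clusters: list[Cluster], spectra: list[Spectrum], path) -> None:
    """Tab-delimited cluster assignment: cluster_id, spectrum_id, raw_file, scan, state."""
    lookup = {s.spectrum_id: s for s in spectra}
    recs = []
    for c in clusters:
        for sid in c.members:
            s = lookup[sid]
            recs.append((c.cluster_id, sid, s.raw_file, s.scan, c.state.value))
    pd.DataFrame(recs, columns=["cluster_id", "spectrum_id", "raw_file", "scan", "state"]).to_csv(
        path, sep="\t", index=False
    )
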