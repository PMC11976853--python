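"""Synthetic multi-batch isobaric-labeling datasets with known ground truth.

The generator emulates the statistical structure a transfer-and-rescore
pipeline assumes, without raw files or neural-network predictors:

* a small proteome digested into tryptic-like peptides, each with a latent
  reference retention time and a latent singly-charged b/y fragment
  pattern (intensities Dirichlet-distributed over the ions);
* several batches (one run each) in which every peptide is fragmented a
  Poisson number of times, with multiplicative log-normal intensity noise,
  uniform noise peaks and a per-run retention-time shift;
* chimeric spectra that superimpose a second, co-isolated peptide at a
  random mixing ratio in [0.3, 0.7];
* a search-engine stand-in that scores candidates by a noisy matched-peak
  cosine (plus Gumbel noise) and reports, per spectrum, the true peptide,
  the best decoy (full reversal, C-terminal residue fixed), and — when it
  outscores the true peptide — the best wrong candidate drawn from the
  target-plus-entrapment database;
* per-spectrum identification dropout that withholds PSMs (never spectra),
  producing the cross-batch missing values the pipeline exists to repair;
* junk spectra — noise-only scans with no true peptide, as real runs
  contain in quantity — whose best (necessarily wrong or decoy) search
  hit populates the low-score tail; these sustain the decoy population
  that target-decoy FDR estimation downstream depends on;
* entrapment peptides built by within-peptide shuffling (C-terminal
  residue preserved), present in the search database but never in any
  spectrum, with the database ratio r recorded for entrapment-FDR bounds.

All randomness flows from ``SimConfig.seed`` through one generator, so a
given config reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FragmentPrediction, fragment_ions, precursor_mz
from .rescoring import estimate_pep, stable_hash
from .spectra import (
    DECOY_PREFIX,
    ENTRAPMENT_PREFIX,
    PSM,
    PSMTable,
    PeptideIdent,
    Spectrum,
    spectrum_key,
)

_AA = np.array(list("ACDEFGHILMNPQSTVWY"))  # no K/R internally, no U/O
_SCORE_SCALE = 10.0
_GUMBEL_SCALE = 2.0
_NOISE_PEAK_MEAN = 8
_PRECURSOR_PPM_SD = 2.0
_RT_JITTER_SD = 0.2  # minutes, within-run


class ConfigError(ValueError):
    """The simulation configuration is internally impossible."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a three-batch experiment of ~3000 spectra over 200
    peptides with 30% per-batch identification dropout.
    """

    n_proteins: int = 40
    peptides_per_protein: int = 5
    n_batches: int = 3
    spectra_per_peptide_per_batch: float = 4.0  # Poisson mean
    junk_spectra_fraction: float = 0.25  # noise-only scans, of all spectra
    dropout_rate: float = 0.3
    chimera_rate: float = 0.05
    fragment_noise_sd: float = 0.2
    prediction_noise_sd: float = 0.05
    rt_run_shift_sd: float = 2.0  # minutes
    entrapment_fraction: float = 0.0
    n_wrong_candidates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "chimera_rate", "entrapment_fraction",
                     "junk_spectra_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.entrapment_fraction >= 1.0:
            raise ConfigError("entrapment_fraction must be < 1 (targets required)")
        if self.junk_spectra_fraction >= 1.0:
            raise ConfigError("junk_spectra_fraction must be < 1")
        for name in ("n_proteins", "peptides_per_protein", "n_batches"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if min(self.fragment_noise_sd, self.prediction_noise_sd,
               self.rt_run_shift_sd, self.spectra_per_peptide_per_batch) < 0:
            raise ConfigError("noise levels and rates must be >= 0")


@dataclass(frozen=True)
class LatentPeptide:
    """A database peptide with its latent (noise-free) properties."""

    peptide: PeptideIdent
    ref_rt: float  # minutes
    ion_labels: tuple[str, ...]
    ion_mz: np.ndarray
    ion_intensity: np.ndarray  # normalized to max 1


@dataclass(frozen=True)
class TruthEntry:
    peptide: PeptideIdent | None  # None for junk (noise-only) spectra
    co_peptide: PeptideIdent | None
    reported: bool

    @property
    def is_junk(self) -> bool:
        return self.peptide is None


@dataclass
class SimTruth:
    """Ground truth per synthetic spectrum plus the latent database."""

    entries: dict[str, TruthEntry]
    latents: dict[str, LatentPeptide]  # modified_sequence -> latent
    entrapment_ratio: float  # r: entrapment / original database size
    config: SimConfig

    def is_correct(self, spectrum_id: str, peptide: PeptideIdent) -> bool:
        """True if the peptide is the spectrum's true or co-isolated peptide."""
        e = self.entries.get(spectrum_id)
        if e is None or e.peptide is None:
            return False
        if peptide.modified_sequence == e.peptide.modified_sequence:
            return True
        return (e.co_peptide is not None
                and peptide.modified_sequence == e.co_peptide.modified_sequence)


def decoy_peptide(peptide: PeptideIdent) -> PeptideIdent:
    """Full sequence reversal with the C-terminal residue fixed."""
    seq = peptide.sequence[:-1][::-1] + peptide.sequence[-1]
    return replace(
        peptide,
        sequence=seq,
        proteins=tuple(DECOY_PREFIX + a for a in peptide.proteins),
        is_decoy=True,
        is_entrapment=False,
    )


def _shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    body = list(seq[:-1])
    rng.shuffle(body)
    return "".join(body) + seq[-1]


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 21))
    body = rng.choice(_AA, size=length - 1)
    cterm = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + cterm


def _make_latent(peptide: PeptideIdent, rng: np.random.Generator) -> LatentPeptide:
    labels, mz = fragment_ions(peptide)
    inten = rng.dirichlet(np.full(len(labels), 0.5))
    inten = inten / inten.max()
    return LatentPeptide(
        peptide=peptide,
        ref_rt=float(rng.uniform(10.0, 100.0)),
        ion_labels=labels,
        ion_mz=mz,
        ion_intensity=inten,
    )


def _build_database(config: SimConfig, rng: np.random.Generator
                    ) -> tuple[list[LatentPeptide], list[LatentPeptide], float]:
    """Target and entrapment latent peptides, plus the database ratio r."""
    seen: set[str] = set()
    targets: list[LatentPeptide] = []
    for ip in range(config.n_proteins):
        acc = f"P{ip + 1:04d}"
        for _ in range(config.peptides_per_protein):
            seq = _random_peptide(rng)
            while seq in seen:
                seq = _random_peptide(rng)
            seen.add(seq)
            charge = 2 if rng.random() < 0.7 else 3
            pep = PeptideIdent(sequence=seq, charge=charge, proteins=(acc,))
            targets.append(_make_latent(pep, rng))
    f = config.entrapment_fraction
    n_entrap = int(round(f / (1.0 - f) * len(targets))) if f > 0 else 0
    entrapment: list[LatentPeptide] = []
    for k in range(n_entrap):
        src = targets[k % len(targets)]
        seq = _shuffle_sequence(src.peptide.sequence, rng)
        tries = 0
        while seq in seen and tries < 50:
            seq = _shuffle_sequence(src.peptide.sequence, rng)
            tries += 1
        if seq in seen:
            continue
        seen.add(seq)
        acc = f"{ENTRAPMENT_PREFIX}E{k + 1:04d}"
        pep = PeptideIdent(sequence=seq, charge=src.peptide.charge,
                           proteins=(acc,), is_entrapment=True)
        entrapment.append(_make_latent(pep, rng))
    r = len(entrapment) / len(targets) if targets else 0.0
    return targets, entrapment, r


def _cosine_score(spectrum: Spectrum, ion_mz: np.ndarray, ion_intensity: np.ndarray,
                  tol: float = 0.02) -> float:
    """Matched-peak cosine between a spectrum and a theoretical pattern
    (the search engine stand-in's raw similarity, distinct from the
    spectral contrast angle used downstream)."""
    obs = np.zeros(ion_mz.size)
    mz = spectrum.mz
    for i, pm in enumerate(ion_mz):
        lo = np.searchsorted(mz, pm - tol, side="left")
        hi = np.searchsorted(mz, pm + tol, side="right")
        if hi > lo:
            j = lo + int(np.argmin(np.abs(mz[lo:hi] - pm)))
            obs[i] = spectrum.intensity[j]
    na = np.linalg.norm(obs)
    nb = np.linalg.norm(ion_intensity)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(obs / na, ion_intensity / nb))


def _realize_spectrum(lat: LatentPeptide, co: LatentPeptide | None, mix: float,
                      raw_file: str, batch_id: str, scan: int, run_shift: float,
                      config: SimConfig, rng: np.random.Generator) -> Spectrum:
    mz = lat.ion_mz
    inten = lat.ion_intensity * (mix if co is not None else 1.0)
    if co is not None:
        mz = np.concatenate([mz, co.ion_mz])
        inten = np.concatenate([inten, co.ion_intensity * (1.0 - mix)])
    if config.fragment_noise_sd > 0:
        inten = inten * np.exp(rng.normal(0.0, config.fragment_noise_sd, inten.size))
    n_noise = int(rng.poisson(_NOISE_PEAK_MEAN))
    if n_noise:
        lo, hi = 100.0, float(mz.max()) + 50.0
        mz = np.concatenate([mz, rng.uniform(lo, hi, n_noise)])
        inten = np.concatenate([inten, rng.uniform(0.0, 0.1, n_noise)])
    prec = precursor_mz(lat.peptide)
    prec = prec * (1.0 + rng.normal(0.0, _PRECURSOR_PPM_SD) * 1e-6)
    rt = lat.ref_rt + run_shift + rng.normal(0.0, _RT_JITTER_SD)
    return Spectrum(
        spectrum_id=spectrum_key(raw_file, scan),
        raw_file=raw_file,
        batch_id=batch_id,
        scan=scan,
        precursor_mz=prec,
        precursor_charge=lat.peptide.charge,
        retention_time=max(rt, 0.0),
        mz=mz,
        intensity=inten,
    )


def simulate_dataset(config: SimConfig) -> tuple[list[Spectrum], PSMTable, SimTruth]:
    """Generate spectra, a 100%-FDR search-style PSM table, and ground truth."""
    rng = np.random.default_rng(config.seed)
    targets, entrapment, r = _build_database(config, rng)
    if not targets:
        raise ConfigError("configuration produces no target peptides")
    database = targets + entrapment  # wrong candidates drawn from here
    decoys = [replace(_make_latent(decoy_peptide(lat.peptide), rng),
                      ref_rt=lat.ref_rt + float(rng.normal(0.0, 10.0)))
              for lat in database]
    latents = {lat.peptide.modified_sequence: lat for lat in database + decoys}

    spectra: list[Spectrum] = []
    entries: dict[str, TruthEntry] = {}
    spectrum_latent: list[tuple[Spectrum, LatentPeptide, LatentPeptide | None]] = []
    scan = 0
    for b in range(config.n_batches):
        raw_file = f"batch{b + 1:02d}_01.raw"
        batch_id = f"batch{b + 1:02d}"
        run_shift = float(rng.normal(0.0, config.rt_run_shift_sd))
        for lat in targets:
            n_spec = int(rng.poisson(config.spectra_per_peptide_per_batch))
            for _ in range(n_spec):
                scan += 1
                co = None
                mix = 1.0
                if len(targets) > 1 and rng.random() < config.chimera_rate:
                    j = int(rng.integers(0, len(targets)))
                    if targets[j] is not lat:
                        co = targets[j]
                        mix = float(rng.uniform(0.3, 0.7))
                s = _realize_spectrum(lat, co, mix, raw_file, batch_id, scan,
                                      run_shift, config, rng)
                spectra.append(s)
                reported = bool(rng.random() >= config.dropout_rate)
                entries[s.spectrum_id] = TruthEntry(
                    peptide=lat.peptide,
                    co_peptide=co.peptide if co is not None else None,
                    reported=reported,
                )
                spectrum_latent.append((s, lat, co))

    # junk scans: noise-only spectra with no true peptide; the search
    # still reports its best (wrong or decoy) candidate for each
    f_junk = config.junk_spectra_fraction
    n_junk = int(round(f_junk / (1.0 - f_junk) * len(spectra))) if f_junk > 0 else 0
    junk_spectra: list[Spectrum] = []
    for j in range(n_junk):
        b = j % config.n_batches
        raw_file = f"batch{b + 1:02d}_01.raw"
        scan += 1
        n_peaks = int(rng.integers(20, 60))
        mz = np.sort(rng.uniform(150.0, 1400.0, n_peaks))
        inten = rng.uniform(0.0, 1.0, n_peaks)
        s = Spectrum(
            spectrum_id=spectrum_key(raw_file, scan), raw_file=raw_file,
            batch_id=f"batch{b + 1:02d}", scan=scan,
            precursor_mz=float(rng.uniform(350.0, 950.0)),
            precursor_charge=2 if rng.random() < 0.7 else 3,
            retention_time=float(rng.uniform(5.0, 105.0)),
            mz=mz, intensity=inten)
        spectra.append(s)
        junk_spectra.append(s)
        entries[s.spectrum_id] = TruthEntry(peptide=None, co_peptide=None,
                                            reported=True)

    rows: list[PSM] = []
    for s, lat, co in spectrum_latent:
        if not entries[s.spectrum_id].reported:
            continue
        # the search reports the better-scoring of the peptides genuinely
        # present; for chimeric spectra the co-isolated peptide can win
        best_true, true_score = lat, (
            _SCORE_SCALE * _cosine_score(s, lat.ion_mz, lat.ion_intensity)
            + float(rng.gumbel(0.0, _GUMBEL_SCALE)))
        if co is not None:
            co_score = (_SCORE_SCALE * _cosine_score(s, co.ion_mz, co.ion_intensity)
                        + float(rng.gumbel(0.0, _GUMBEL_SCALE)))
            if co_score > true_score:
                best_true, true_score = co, co_score
        rows.append(PSM(
            spectrum_ref=s.spectrum_id, raw_file=s.raw_file, scan=s.scan,
            peptide=best_true.peptide, search_score=true_score,
        ))
        # best wrong candidate from the target+entrapment database
        best_wrong, best_wrong_score = None, -np.inf
        for _ in range(config.n_wrong_candidates):
            cand = database[int(rng.integers(0, len(database)))]
            if cand.peptide.modified_sequence == lat.peptide.modified_sequence or (
                    co is not None
                    and cand.peptide.modified_sequence == co.peptide.modified_sequence):
                continue
            sc = (_SCORE_SCALE * _cosine_score(s, cand.ion_mz, cand.ion_intensity)
                  + float(rng.gumbel(0.0, _GUMBEL_SCALE)))
            if sc > best_wrong_score:
                best_wrong, best_wrong_score = cand, sc
        if best_wrong is not None and best_wrong_score > true_score:
            rows.append(PSM(
                spectrum_ref=s.spectrum_id, raw_file=s.raw_file, scan=s.scan,
                peptide=best_wrong.peptide, search_score=best_wrong_score,
            ))
        # best decoy; like a search engine's scan-level competition, it is
        # reported only when it outscores the true peptide
        best_decoy, best_decoy_score = None, -np.inf
        for _ in range(config.n_wrong_candidates):
            cand = decoys[int(rng.integers(0, len(decoys)))]
            sc = (_SCORE_SCALE * _cosine_score(s, cand.ion_mz, cand.ion_intensity)
                  + float(rng.gumbel(0.0, _GUMBEL_SCALE)))
            if sc > best_decoy_score:
                best_decoy, best_decoy_score = cand, sc
        if best_decoy is not None and best_decoy_score > true_score:
            rows.append(PSM(
                spectrum_ref=s.spectrum_id, raw_file=s.raw_file, scan=s.scan,
                peptide=best_decoy.peptide, search_score=best_decoy_score,
            ))

    for s in junk_spectra:
        best, best_score = None, -np.inf
        for pool in (database, decoys):
            for _ in range(config.n_wrong_candidates):
                cand = pool[int(rng.integers(0, len(pool)))]
                sc = (_SCORE_SCALE * _cosine_score(s, cand.ion_mz, cand.ion_intensity)
                      + float(rng.gumbel(0.0, _GUMBEL_SCALE)))
                if sc > best_score:
                    best, best_score = cand, sc
        if best is not None:
            rows.append(PSM(
                spectrum_ref=s.spectrum_id, raw_file=s.raw_file, scan=s.scan,
                peptide=best.peptide, search_score=best_score,
            ))

    table = PSMTable(rows, {
        "generator": "simulate_dataset",
        "seed": config.seed,
        "n_spectra": len(spectra),
        "entrapment_ratio": r,
    }).sorted()
    if len(table):
        pep = estimate_pep([p.search_score for p in table],
                           [p.is_decoy for p in table])
        for i, p in enumerate(table.rows):
            p.posterior_error_prob = float(pep[i])
    truth = SimTruth(entries=entries, latents=latents, entrapment_ratio=r,
                     config=config)
    return spectra, table, truth


# ---------------------------------------------------------------------------
# oracle property provider
# ---------------------------------------------------------------------------

class OraclePredictor:
    """Deterministic stand-in for a learned property predictor.

    For database peptides the prediction is the latent pattern plus
    Gaussian noise; for any other peptide (e.g. a decoy) a latent pattern
    is derived reproducibly from the sequence itself, so wrong candidates
    are predicted from their *own* pattern and score poorly against other
    peptides' spectra. Predictions are cached: querying the same peptide
    twice returns the identical object.
    """

    def __init__(self, truth: SimTruth, prediction_noise_sd: float | None = None):
        self._latents = truth.latents
        self._noise_sd = (truth.config.prediction_noise_sd
                          if prediction_noise_sd is None else prediction_noise_sd)
        self._seed = truth.config.seed
        self._cache: dict[str, tuple[FragmentPrediction, float]] = {}

    def _get(self, peptide: PeptideIdent) -> tuple[FragmentPrediction, float]:
        key = peptide.modified_sequence
        if key in self._cache:
            return self._cache[key]
        lat = self._latents.get(key)
        if lat is None:
            rng = np.random.default_rng((stable_hash("latent:" + key) ^ self._seed)
                                        % 2**31)
            labels, mz = fragment_ions(peptide)
            inten = rng.dirichlet(np.full(len(labels), 0.5))
            inten = inten / inten.max()
            lat = LatentPeptide(peptide=peptide, ref_rt=float(rng.uniform(10, 100)),
                                ion_labels=labels, ion_mz=mz, ion_intensity=inten)
        rng = np.random.default_rng((stable_hash("noise:" + key) ^ self._seed) % 2**31)
        inten = lat.ion_intensity
        rt = lat.ref_rt
        if self._noise_sd > 0:
            inten = np.clip(inten + rng.normal(0.0, self._noise_sd, inten.size), 0.0, None)
            if inten.max() > 0:
                inten = inten / inten.max()
            rt = rt + float(rng.normal(0.0, self._noise_sd * 10.0))
        pred = FragmentPrediction(labels=lat.ion_labels, mz=lat.ion_mz,
                                  intensity=inten)
        self._cache[key] = (pred, rt)
        return self._cache[key]

    def predict_fragments(self, peptide: PeptideIdent) -> FragmentPrediction:
        return self._get(peptide)[0]

    def predict_rt(self, peptide: PeptideIdent) -> float:
        return self._get(peptide)[1]


def oracle_predictor(truth: SimTruth,
                     prediction_noise_sd: float | None = None) -> OraclePredictor:
    """Property provider backed by the simulation's latent peptides."""
    return OraclePredictor(truth, prediction_noise_sd)


def write_truth(truth: SimTruth, path) -> None:
    """Sidecar TSV mapping spectrum_id to its true (and co-isolated) peptide."""
    recs = []
    for sid in sorted(truth.entries):
        e = truth.entries[sid]
        recs.append((
            sid,
            e.peptide.modified_sequence if e.peptide else "",
            e.peptide.charge if e.peptide else 0,
            e.co_peptide.modified_sequence if e.co_peptide else "",
            int(e.reported),
        ))
    pd.DataFrame(recs, columns=["spectrum_id", "true_peptide", "charge",
                                "co_peptide", "reported"]).to_csv(
        path, sep="\t", index=False)
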