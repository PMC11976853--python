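# Methods

`psmtransfer` implements a desk-scale transfer-and-rescore pipeline for
multi-batch isobaric-labeling (TMT-style) proteomics: spectrum clustering
across batches, transfer of confident peptide identifications to
unidentified cluster members, data-driven rescoring of native and
transferred peptide-spectrum matches (PSMs) against predicted peptide
properties, and false discovery rate (FDR) control at the PSM, peptide and
protein-group level. This note records the model, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where the design was open.

## Spectrum clustering

Each MS2 spectrum is reduced to the m/z bins (width 0.02 Da, the typical
high-resolution fragment tolerance at mid-m/z) of its `top_k = 40` most
intense peaks. A bin shared by few spectra carries more evidence of
identity than a ubiquitous one, so bin *b* receives an IDF-style weight

    w(b) = -log10(df(b) / n_spectra),

where `df` is the number of spectra containing the bin. The similarity of
two precursor-compatible spectra is the summed weight of their shared bins
normalized by the lighter spectrum's total weight; distance is one minus
that, clamped to [0, 1]. Precursor compatibility requires equal known
charge and precursor m/z within `precursor_tol` (default 0.01 Da, about
10 ppm at m/z 1000); incompatible pairs are infinitely distant, and
clustering runs independently inside each connected precursor stratum so
the full pairwise matrix is never materialized.

Agglomerative complete-linkage clustering cuts the dendrogram at

    t(stringency) = 1 - stringency / 20,

so the recommended stringency 10 bounds every cluster's diameter at 0.5
and larger stringencies demand tighter similarity. Complete linkage is
what makes the diameter bound a guarantee rather than a tendency. The
normalization of the similarity and the stringency-to-threshold map are
this package's own definitions; they are interface-compatible with the
stringency scale used by the SIMSI/MaRaCluster family of tools but do not
reproduce MaRaCluster's Bayesian p-value machinery.

## Identification transfer

Clusters are annotated with the distinct (modified sequence, charge)
identifications among members that passed the input FDR (default 1%).
Transfer sources are additionally capped at a posterior error probability
(PEP) of `maximum_pep_percent` (default 5%). Every member without an
accepted identification receives the cluster's identification(s) as
`origin=transfer` PSMs. Ambiguous clusters (two or more conflicting
identifications) are governed by `ambiguity_decision`:

* `skip` — transfer nothing (the conservative historical behavior);
* `keep_all` (pipeline default) — give each unidentified member one
  candidate per conflicting identification, the analogue of a search
  engine's "second peptide" option; the final best-PSM step resolves the
  competition.

Ambiguity is judged on the cluster's accepted identification state, not on
the PEP-filtered source list: a cluster with a confident and a barely
accepted conflicting identification is still ambiguous. Transferred PSMs
carry no search score (the search engine never saw them); a
`has_search_score` indicator lets the rescorer degrade gracefully. Their
PEP is the best source PEP, kept as metadata only, since it describes the
source spectrum rather than the acceptor. Decoy identifications transfer
under exactly the same rules — transferred decoys are part of the null
model the downstream FDR estimate relies on.

## Property features and the spectral contrast angle

A property provider supplies, per peptide, an annotated theoretical
fragment-ion list with relative intensities and a reference retention
time. The central similarity feature is the normalized spectral contrast
angle between observed and predicted fragment intensities: observed peaks
are matched one-to-one to predicted ions within 0.02 Da (nearest wins),
aligned over the union of predicted ions, square-root transformed,
L2-normalized, and

    SA = 1 - 2 * arccos(x_obs . x_pred) / pi .

SA is 1 for identical patterns and 0 when no observed peak matches any
predicted ion. Chimeric (co-isolated) spectra need no special treatment:
each candidate is scored independently against the same spectrum, so both
of two genuinely present peptides can reach a high angle.

Retention-time deviation is measured after a per-run monotone calibration:
isotonic regression of observed on predicted retention time over each
run's best-scoring target PSMs (up to 200 anchors; runs with fewer than 10
anchors fall back to the identity map with a warning), with linear
interpolation between anchor points. The remaining features are the
Pearson correlation of matched intensities, the matched-ion fraction, the
search score with its presence indicator, the precursor mass error in ppm
(clamped to ±50 ppm so a single feature cannot dominate unboundedly),
peptide length, a charge one-hot (1–6), and the transfer indicator.
Feature vectors are complete by construction; missing quantities use a
documented zero sentinel plus indicator.

Peptides outside the property predictor's domain are excluded throughout:
length 7–30, charge at most 6, no selenocysteine or pyrrolysine, no
N-terminal protein acetylation.

## Rescoring and FDR estimation

The rescorer follows the Percolator recipe. PSMs are split into three
cross-validation folds by a stable (md5) hash such that all candidates of
a spectrum and all PSMs of a peptide share a fold — the two constraints
chain through keep_all candidates, so folds are assigned to connected
components of the spectrum-peptide graph. This prevents the same peptide
from appearing in both training and test data, a known leakage route that
understates the FDR.

Within a fold, the initial score direction is the spectral angle; each of
10 iterations labels as positives the target PSMs with q ≤ 1% under the
current score, takes all decoys as negatives, and refits a linear
large-margin classifier (L2-regularized squared hinge, C = 1, solved in
the primal so the fit is deterministic; the C-grid search of the original
Percolator is omitted for determinism and speed). Each fold is then scored
with the average raw-space weight vector of the models trained on the
*other* folds, keeping every reported score out-of-sample. The averaged
weights over all folds form the static model that the pipeline's second
pass re-applies without retraining.

q-values come from target-decoy competition with the conservative +1
pseudocount: sorting by score, the running FDR at rank *i* is
`(decoys(i) + 1) / max(targets(i), 1)` and the q-value is the bottom-up
running minimum, clipped to 1. PEPs (local FDR) are estimated by isotonic
regression, non-increasing in score, of the decoy/target ratio over 50
equal-count score bins; below 500 PSMs the q-value is used as a fallback
with a warning. Peptide-level q-values keep each peptide's best PSM and
recompute q-values — the standard best-PSM aggregation.

## Candidate merging and protein inference

After transfer, the first-round and transferred candidates are merged per
spectrum: a spectrum whose best first-round PSM passed the first-pass 1%
FDR keeps that PSM and drops its transfers; otherwise the transferred
candidates replace the failed first-round *target* PSM. Replacement is
deliberately confined to the target stream: a replaced spectrum's
first-round decoy rows ride along beside the transferred candidates.
Without this, transfers would thin the decoy population and the final
target-decoy competition would become anti-conservative — junk transfers
would face no null to compete against.

The merged table is rescored with the frozen static weights (the
second pass never retrains; the checkpointed weight files of both stages
are byte-identical), the best-scoring PSM per spectrum is retained (ties
broken by lexicographically smallest modified sequence), and q-values are
recomputed on the reduced set.

Protein inference groups proteins with identical peptide sets, scores each
group by its best peptide rescore, and applies the picked protein-group
strategy: every target protein competes only against its own mirrored
decoy (`REV__` accession); the lower scorer of each pair is removed before
protein-level q-values are computed. This halves the decoy count in
expectation under the null and avoids the decoy inflation of naive protein
FDR. Peptides shared between groups count for all of them (no razor
assignment). The three output levels (PSM, peptide, protein group) are
reported independently; protein-level rejection does not feed back into
the PSM list.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes
while staying self-contained (no raw files, no neural networks):

* a proteome of `n_proteins × peptides_per_protein` tryptic-like peptides
  (length 7–20, C-terminal K/R), each with a latent reference retention
  time and a latent singly-charged b/y fragment pattern drawn from a
  Dirichlet distribution — enough fragmentation chemistry to exercise the
  spectral angle and clustering, without isotope envelopes, multiply
  charged fragments, neutral losses or reporter ions;
* `n_batches` batches (one run each, default 3) in which every peptide is
  fragmented Poisson(`spectra_per_peptide_per_batch`, default 4) times,
  with multiplicative log-normal intensity noise
  (`fragment_noise_sd` = 0.2), Poisson(8) uniform noise peaks, ~2 ppm
  precursor error, a per-run retention-time shift
  (`rt_run_shift_sd` = 2 min) and 0.2 min within-run jitter;
* chimeric spectra (`chimera_rate`, default 5%) superimposing a second
  peptide at a mixing ratio uniform in [0.3, 0.7]; the search stand-in
  reports the better-scoring of the two genuinely present peptides, so
  conflicting-but-correct identifications arise naturally, as they do when
  two tools each identify one co-isolated peptide;
* junk scans (`junk_spectra_fraction`, default 25% of spectra; real runs
  contain more) with no true peptide, whose best hit is necessarily a
  wrong or decoy candidate — these sustain the decoy population that
  PSM-level FDR estimation needs all the way to the final output;
* a search-engine stand-in scoring candidates by a matched-peak cosine
  scaled by 10 plus Gumbel(0, 2) noise, reporting per spectrum the true
  peptide plus — only when they outscore it, mirroring a search engine's
  per-scan argmax — the best of 3 wrong candidates (drawn uniformly from
  the target-plus-entrapment database) and the best of 3 decoys (full
  sequence reversal, C-terminal residue fixed);
* per-spectrum identification dropout (default 30%) that withholds PSMs
  but never deletes spectra — the missing values the transfer step exists
  to repair;
* optional entrapment peptides built by within-peptide shuffling
  (C-terminal residue preserved), present in the search database but never
  in any spectrum, with the database ratio r recorded for the entrapment
  bounds below.

All randomness flows from a single seeded generator; a fixed configuration
reproduces byte-identical output. The oracle property provider returns
each database peptide's latent pattern plus Gaussian noise
(`prediction_noise_sd`, default 0.05) and derives reproducible latents for
out-of-database peptides (decoys) from a per-peptide hash, so wrong
candidates are predicted from their own pattern and score poorly against
other peptides' spectra. Predictions are cached and deterministic.

What passing on this generator does and does not show: the simulation has
clean isotopic peaks, complete fragment coverage, and a property oracle
whose errors are unbiased Gaussian noise, so score separation is better
than in real data; absolute identification rates here say nothing about
real gain percentages. What the tests do establish is structural: FDR
calibration (empirical false discovery proportion near the nominal 1%,
bracketed by entrapment bounds), that transfer strictly adds identified
spectra under batch dropout, that ambiguity policies have the stated
set-relationships, and that the whole pipeline is bit-reproducible.

## Entrapment FDR bounds

With N accepted target-side PSMs of which E are entrapment hits and r the
entrapment-to-original database size ratio,

    lower = E / N,      upper = E * (1 + 1/r) / N,

so `lower = upper * r/(r+1)` identically. The lower bound counts only
provable false positives; the upper bound extrapolates equally many false
hits into the original target space per unit of database. Validation
brackets the simulation's true false discovery proportion between the two
bounds with a binomial 95% margin derived from the standard error of E at
the given N. Default evaluation uses an entrapment fraction of 0.5
(r = 1); r is always an explicit parameter.

## Numerical and degenerate-input choices

* Spectral angle of an all-zero matched intensity vector is 0; the dot
  product is clipped to [0, 1] before `arccos`. Exactly identical
  patterns evaluate to 1 up to ~1e-8 (arccos amplifies last-bit rounding).
* Rarity distance when both spectra carry zero total bin weight: 0 for
  identical bin sets, 1 otherwise.
* Peak lists are sorted ascending on construction; exact duplicate m/z
  values are summed.
* Ties: equal (raw file, scan) PSMs order by modified sequence; equal
  rescores in best-PSM selection pick the lexicographically smallest
  modified sequence; fold hashes and cluster ids are input-order
  deterministic.
* `fcluster` distance criterion on a complete-linkage tree realizes the
  diameter bound; within-stratum incompatible pairs use a sentinel
  distance of 2 (> any threshold).
* Charge 0 means unknown and exempts a spectrum only from the
  charge-equality gate, not from clustering.

## Known limitations

* The clustering metric is a deliberately simple rarity-weighted overlap;
  it does not reproduce MaRaCluster's p-value distances, and its absolute
  stringency scale is calibrated only by the diameter bound.
* Quantification is out of scope end to end: no reporter-ion extraction,
  no protein intensity roll-up, no MS1 features.
* The PEP estimator is a binned isotonic local-FDR estimate; with few
  PSMs it degrades to q-values, which are tail- rather than local-based.
* Protein-level FDR assumes mirrored decoy accessions (`REV__`); unpaired
  decoys compete alone.
* The generator's search stand-in emits at most one wrong-candidate row
  per spectrum and scores candidates against noiseless theoretical
  patterns; real search-engine score distributions are heavier-tailed.
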