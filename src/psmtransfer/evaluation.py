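"""Validation harness: entrapment FDR bounds, run comparisons, score diagnostics.

Entrapment FDR brackets the true error rate of an accepted PSM set using
database sequences known to be absent from the sample. With N accepted
target-side PSMs (original targets + entrapment) of which E are
entrapment, and r the entrapment-to-original database size ratio:

    lower = E / N                 (only provable false positives)
    upper = E * (1 + 1/r) / N     (extrapolating equally many false
                                   original-target hits per database size)

so lower = upper * r / (r + 1) identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import PSMTable

DEFAULT_Q_THRESHOLD = 0.01
_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass(frozen=True)
class EntrapmentResult:
    threshold_q: float
    n_accepted: int
    n_entrapment_accepted: int
    r: float
    efdr_lower: float
    efdr_upper: float


def entrapment_fdr(accepted: PSMTable, r: float,
                   threshold_q: float = DEFAULT_Q_THRESHOLD) -> EntrapmentResult:
    """Entrapment FDR bounds over the accepted target-side PSMs.

    ``accepted`` should already be the q <= threshold acceptance set;
    decoys are ignored. N = 0 yields both bounds 0 by convention.
    """
    if r <= 0:
        raise ValueError("entrapment ratio r must be > 0")
    targets = [p for p in accepted if not p.is_decoy]
    n = len(targets)
    e = sum(1 for p in targets if p.is_entrapment)
    if n == 0:
        import warnings

        warnings.warn("no accepted target PSMs; entrapment bounds set to 0")
        lower = upper = 0.0
    else:
        lower = e / n
        upper = min(e * (1.0 + 1.0 / r) / n, 1.0)
        lower = min(lower, upper)
    return EntrapmentResult(
        threshold_q=threshold_q, n_accepted=n, n_entrapment_accepted=e,
        r=r, efdr_lower=lower, efdr_upper=upper,
    )


@dataclass
class GainLoss:
    baseline_ids: set[str]
    variant_ids: set[str]
    gained: set[str] = field(default_factory=set)
    lost: set[str] = field(default_factory=set)
    n_agree: int = 0
    n_disagree: int = 0

    @property
    def agreement(self) -> float:
        both = self.n_agree + self.n_disagree
        return self.n_agree / both if both else 1.0


def _accepted_idents(table: PSMTable, q_threshold: float) -> dict[str, set[tuple[str, int]]]:
    out: dict[str, set[tuple[str, int]]] = {}
    for p in table:
        if p.is_decoy or p.q_value is None or p.q_value > q_threshold:
            continue
        out.setdefault(p.spectrum_ref, set()).add(p.peptide.ident_key)
    return out


def compare_runs(baseline: PSMTable, variant: PSMTable,
                 q_threshold: float = DEFAULT_Q_THRESHOLD) -> GainLoss:
    """Spectra identified at q <= threshold by each run, their set algebra,
    and identification agreement over the intersection."""
    all_base = {p.spectrum_ref for p in baseline}
    all_var = {p.spectrum_ref for p in variant}
    if all_base and all_var and not (all_base & all_var):
        raise ValueError("disjoint spectrum namespaces; inputs likely mismatched")
    base = _accepted_idents(baseline, q_threshold)
    var = _accepted_idents(variant, q_threshold)
    gl = GainLoss(baseline_ids=set(base), variant_ids=set(var))
    gl.gained = gl.variant_ids - gl.baseline_ids
    gl.lost = gl.baseline_ids - gl.variant_ids
    for sid in gl.baseline_ids & gl.variant_ids:
        if base[sid] & var[sid]:
            gl.n_agree += 1
        else:
            gl.n_disagree += 1
    return gl


def score_shift_report(native: PSMTable, transferred: PSMTable) -> pd.DataFrame:
    """Score-distribution diagnostics for native vs transferred PSMs.

    One row per (population, label) with quantiles, the
    Hodges-Lehmann-style median shift versus the native population of the
    same label, and the rank-sum test p-value. Report only — no decision
    is taken here.
    """
    if not len(native) or not len(transferred):
        raise ValueError("both tables must be non-empty")

    def _scores(table: PSMTable, decoy: bool) -> np.ndarray:
        return np.array([p.rescore for p in table
                         if p.is_decoy == decoy and p.rescore is not None])

    rows = []
    for label, decoy in (("target", False), ("decoy", True)):
        ref = _scores(native, decoy)
        for pop, table in (("native", native), ("transfer", transferred)):
            s = _scores(table, decoy)
            if s.size == 0:
                continue
            rec = {"population": pop, "label": label, "n": s.size}
            for q in _QUANTILES:
                rec[f"q{int(q * 100):02d}"] = float(np.quantile(s, q))
            if pop == "native" or ref.size == 0:
                rec["median_shift"] = 0.0
                rec["ranksum_p"] = 1.0
            else:
                rec["median_shift"] = float(np.median(s) - np.median(ref))
                rec["ranksum_p"] = float(
                    stats.mannwhitneyu(s, ref, alternative="two-sided").pvalue
                )
            rows.append(rec)
    return pd.DataFrame(rows)
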