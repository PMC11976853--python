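"""Shared fixtures: small synthetic datasets and cached pipeline runs.

The calibration/entrapment fixtures run the full pipeline over several
seeds once per session; several tests read different statistics off the
same runs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psmtransfer import (
    PipelineConfig,
    PSMTable,
    entrapment_fdr,
    oracle_predictor,
    run_pipeline,
    simulate_dataset,
)
from psmtransfer.simulate import SimConfig

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

CALIBRATION_SEEDS = list(range(1, 11))
Q = 0.01


def _accepted_targets(psm_level: PSMTable, q: float = Q):
    return [p for p in psm_level if not p.is_decoy
            and p.q_value is not None and p.q_value <= q]


def _fdp(accepted, truth) -> float:
    if not accepted:
        return 0.0
    wrong = sum(1 for p in accepted if not truth.is_correct(p.spectrum_ref, p.peptide))
    return wrong / len(accepted)


@pytest.fixture(scope="session")
def small_sim():
    """A fast ~450-spectrum dataset for unit-level checks."""
    config = SimConfig(seed=42, n_proteins=10, peptides_per_protein=5,
                       spectra_per_peptide_per_batch=3.0)
    spectra, psms, truth = simulate_dataset(config)
    return spectra, psms, truth


@pytest.fixture(scope="session")
def calibration_runs():
    """Default-condition pipeline + rescoring-only ablation over 10 seeds."""
    out = []
    for seed in CALIBRATION_SEEDS:
        spectra, psms, truth = simulate_dataset(SimConfig(seed=seed))
        provider = oracle_predictor(truth)
        full = run_pipeline(spectra, psms, provider, PipelineConfig(seed=seed))
        ablation = run_pipeline(
            spectra, psms, provider,
            replace(PipelineConfig(seed=seed), transfer_enabled=False),
        )
        acc_full = _accepted_targets(full.psm_level)
        acc_abl = _accepted_targets(ablation.psm_level)
        out.append({
            "seed": seed,
            "fdp_full": _fdp(acc_full, truth),
            "fdp_ablation": _fdp(acc_abl, truth),
            "true_spectra_full": len({p.spectrum_ref for p in acc_full
                                      if truth.is_correct(p.spectrum_ref, p.peptide)}),
            "true_spectra_ablation": len({p.spectrum_ref for p in acc_abl
                                          if truth.is_correct(p.spectrum_ref, p.peptide)}),
        })
    return out


@pytest.fixture(scope="session")
def entrapment_runs():
    """Pipeline runs with a same-size entrapment database (r = 1), 10 seeds."""
    out = []
    for seed in CALIBRATION_SEEDS:
        config = SimConfig(seed=seed, entrapment_fraction=0.5)
        spectra, psms, truth = simulate_dataset(config)
        provider = oracle_predictor(truth)
        res = run_pipeline(spectra, psms, provider, PipelineConfig(seed=seed))
        accepted = _accepted_targets(res.psm_level)
        er = entrapment_fdr(PSMTable(accepted), truth.entrapment_ratio, Q)
        p_hat = er.efdr_lower
        eps = 1.96 * np.sqrt(max(p_hat * (1 - p_hat), 0.0) / max(er.n_accepted, 1))
        out.append({
            "seed": seed,
            "fdp": _fdp(accepted, truth),
            "result": er,
            "eps": float(eps),
        })
    return out
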