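"""Candidate merging, best-PSM selection and picked protein-group FDR.

Merging implements the pipeline's replacement rule: a spectrum keeps its
first-round (search) PSM if that PSM passed the first-pass FDR; otherwise
any transferred candidates replace it. After the final rescoring pass the
best-scoring candidate per spectrum is retained (ties broken by
lexicographically smallest modified sequence) and q-values are recomputed
on the reduced set.

Protein inference groups proteins with identical peptide sets, scores each
group by its best peptide rescore, and runs the "picked" target-decoy
competition: each target protein competes only against its own mirrored
decoy (``REV__`` accession), the lower scorer of the pair is eliminated
before q-value estimation, which halves the decoy count in expectation
under the null and removes the decoy-inflation bias of naive protein FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rescoring import compute_qvalues
from .spectra import DECOY_PREFIX, PSM, PSMTable

DEFAULT_FDR_THRESHOLD = 0.01


def merge_candidates(first_round: PSMTable, transferred: PSMTable,
                     fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> PSMTable:
    """Combine search and transferred candidates per spectrum.

    A spectrum whose best first-round PSM has q <= threshold keeps only
    that best first-round PSM; otherwise its transferred candidates (if
    any) replace the failed first-round target PSM. Spectra present in
    only one table pass through.

    Replacement acts on the *target* stream: a failed spectrum's
    first-round decoy rows ride along beside its transferred candidates,
    so the decoy population — the null model the final target-decoy
    competition estimates its FDR from — is never thinned by transfers.
    """
    first_by_spec: dict[str, list[PSM]] = {}
    for p in first_round:
        first_by_spec.setdefault(p.spectrum_ref, []).append(p)
    best_first: dict[str, PSM] = {}
    for sid, cands in first_by_spec.items():
        best = cands[0]
        for p in cands[1:]:
            if (p.rescore or 0.0) > (best.rescore or 0.0) or \
                    ((p.rescore or 0.0) == (best.rescore or 0.0)
                     and p.peptide.modified_sequence < best.peptide.modified_sequence):
                best = p
        best_first[sid] = best
    by_spec_transfer: dict[str, list[PSM]] = {}
    for p in transferred:
        if p.origin != "transfer":
            raise ValueError("transferred table contains non-transfer PSMs")
        by_spec_transfer.setdefault(p.spectrum_ref, []).append(p)
    rows: list[PSM] = []
    n_replaced = 0
    for sid, p in best_first.items():
        if p.q_value is not None and p.q_value <= fdr_threshold:
            rows.append(p)
        elif sid in by_spec_transfer:
            rows.extend(by_spec_transfer[sid])
            rows.extend(c for c in first_by_spec[sid] if c.is_decoy)
            n_replaced += 1
        else:
            rows.append(p)
    for sid, cands in by_spec_transfer.items():
        if sid not in best_first:
            rows.extend(cands)
    prov = {"n_spectra_replaced_by_transfer": n_replaced,
            "fdr_threshold": fdr_threshold}
    return PSMTable(rows, prov).sorted()


def best_psm_per_spectrum(scored: PSMTable) -> PSMTable:
    """Exactly one PSM per spectrum: highest rescore, ties by smallest
    modified sequence; q-values recomputed on the reduced set."""
    best: dict[str, PSM] = {}
    for p in scored:
        cur = best.get(p.spectrum_ref)
        if cur is None or p.rescore > cur.rescore or \
                (p.rescore == cur.rescore
                 and p.peptide.modified_sequence < cur.peptide.modified_sequence):
            best[p.spectrum_ref] = p
    rows = [best[k] for k in sorted(best)]
    q = compute_qvalues([p.rescore for p in rows], [p.is_decoy for p in rows])
    rows = [p.copy(q_value=float(q[i])) for i, p in enumerate(rows)]
    return PSMTable(rows, dict(scored.provenance)).sorted()


@dataclass
class ProteinGroup:
    group_id: int
    member_accessions: tuple[str, ...]
    peptides: frozenset[str] = field(default_factory=frozenset)
    best_score: float = float("-inf")
    is_decoy_group: bool = False
    q_value: float | None = None


def _mirror_key(accessions: tuple[str, ...]) -> tuple[str, ...]:
    """Accessions with the decoy prefix stripped — pairs mirrored groups."""
    return tuple(sorted(a[len(DECOY_PREFIX):] if a.startswith(DECOY_PREFIX) else a
                        for a in accessions))


def picked_protein_fdr(psms: PSMTable,
                       fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> list[ProteinGroup]:
    """Protein grouping and picked target-decoy protein-group FDR.

    ``psms`` should be the PSMs accepted at the PSM-level FDR. Proteins
    with identical peptide sets form one group; the group score is the
    best peptide rescore; each target group competes against its mirrored
    decoy group (higher scorer survives); q-values are computed over the
    survivors. Unpaired decoys compete alone.
    """
    pep_by_protein: dict[str, set[str]] = {}
    score_by_peptide: dict[str, float] = {}
    for p in psms:
        seq = p.peptide.modified_sequence
        score_by_peptide[seq] = max(score_by_peptide.get(seq, float("-inf")),
                                    p.rescore if p.rescore is not None else float("-inf"))
        for acc in p.peptide.proteins:
            pep_by_protein.setdefault(acc, set()).add(seq)
    # group proteins sharing an identical peptide set
    by_pepset: dict[tuple[bool, frozenset[str]], list[str]] = {}
    for acc, peps in pep_by_protein.items():
        is_decoy = acc.startswith(DECOY_PREFIX)
        by_pepset.setdefault((is_decoy, frozenset(peps)), []).append(acc)
    groups: list[ProteinGroup] = []
    for (is_decoy, pepset), accs in sorted(
            by_pepset.items(), key=lambda kv: tuple(sorted(kv[1]))):
        best = max(score_by_peptide[s] for s in pepset)
        groups.append(ProteinGroup(
            group_id=len(groups),
            member_accessions=tuple(sorted(accs)),
            peptides=pepset,
            best_score=best,
            is_decoy_group=is_decoy,
        ))
    # picked competition between mirrored target/decoy groups
    by_mirror: dict[tuple[str, ...], list[ProteinGroup]] = {}
    for g in groups:
        by_mirror.setdefault(_mirror_key(g.member_accessions), []).append(g)
    survivors: list[ProteinGroup] = []
    for key in sorted(by_mirror):
        pair = by_mirror[key]
        targets = [g for g in pair if not g.is_decoy_group]
        decoys = [g for g in pair if g.is_decoy_group]
        if targets and decoys:
            bt = max(targets, key=lambda g: g.best_score)
            bd = max(decoys, key=lambda g: g.best_score)
            survivors.append(bt if bt.best_score >= bd.best_score else bd)
        else:
            survivors.extend(pair)
    survivors.sort(key=lambda g: (-g.best_score, g.member_accessions))
    q = compute_qvalues([g.best_score for g in survivors],
                        [g.is_decoy_group for g in survivors])
    for i, g in enumerate(survivors):
        g.q_value = float(q[i])
    return survivors
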