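"""Identification transfer within spectrum clusters.

Spectra that cluster with confidently identified, highly similar spectra
inherit those identifications. Transfers are seeded only by cluster-member
PSMs that passed the input FDR filter and whose posterior error
probability is below a ceiling (default 5%). Clusters with conflicting
identifications are handled by one of two policies: ``skip`` (transfer
nothing) or ``keep_all`` (assign every conflicting candidate to each
unidentified member, the analogue of a search engine's "second peptide"
option). Decoy-identified sources transfer by exactly the same rules,
which downstream target-decoy FDR estimation relies on.

Transferred PSMs carry no search score (the search engine never scored
them); their posterior error probability is the best source PEP of that
peptide, recorded as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import Cluster, ClusterState
from .spectra import PSM, PSMTable


@dataclass(frozen=True)
class TransferConfig:
    maximum_pep_percent: float = 5.0
    ambiguity_decision: str = "keep_all"  # "skip" | "keep_all"
    input_fdr: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.maximum_pep_percent <= 100:
            raise ValueError("maximum_pep_percent must be in (0, 100]")
        if not 0 < self.input_fdr < 1:
            raise ValueError("input_fdr must be in (0, 1)")
        if self.ambiguity_decision not in ("skip", "keep_all"):
            raise ValueError("ambiguity_decision must be 'skip' or 'keep_all'")


def select_transfer_sources(cluster: Cluster, accepted_psms: PSMTable,
                            config: TransferConfig) -> list[PSM]:
    """Member PSMs eligible to seed transfers: accepted at the input FDR
    and with PEP <= maximum_pep_percent / 100."""
    members = set(cluster.members)
    ceiling = config.maximum_pep_percent / 100.0
    out = []
    for p in accepted_psms:
        if p.spectrum_ref in members and p.posterior_error_prob is not None \
                and p.posterior_error_prob <= ceiling:
            out.append(p)
    return out


def transfer_cluster(cluster: Cluster, sources: list[PSM], config: TransferConfig,
                     accepted_members: set[str] | None = None) -> list[PSM]:
    """Emit transfer PSMs for each member spectrum without an accepted PSM.

    ``accepted_members`` are spectra with any accepted input PSM (even one
    over the PEP ceiling); they never receive transfers. Defaults to the
    source spectra.
    """
    if not sources:
        return []
    # best (lowest-PEP) source PSM per distinct identification
    best_by_ident: dict[tuple[str, int], PSM] = {}
    for s in sources:
        key = s.peptide.ident_key
        cur = best_by_ident.get(key)
        if cur is None or s.posterior_error_prob < cur.posterior_error_prob:
            best_by_ident[key] = s
    # ambiguity is a property of the cluster's identification state (all
    # accepted identifications), not of the PEP-filtered transfer sources
    n_idents = len(cluster.identifications) if cluster.identifications \
        else len(best_by_ident)
    if n_idents >= 2 and config.ambiguity_decision == "skip":
        return []
    identified = accepted_members if accepted_members is not None \
        else {s.spectrum_ref for s in sources}
    out: list[PSM] = []
    for sid in cluster.members:
        if sid in identified:
            continue
        raw_file, _, scan = sid.rpartition(":")
        for key in sorted(best_by_ident):
            src = best_by_ident[key]
            out.append(
                PSM(
                    spectrum_ref=sid,
                    raw_file=raw_file,
                    scan=int(scan) if scan.isdigit() else 0,
                    peptide=src.peptide,
                    search_score=None,
                    posterior_error_prob=src.posterior_error_prob,
                    origin="transfer",
                )
            )
    return out


def run_transfer(clusters: list[Cluster], accepted_psms: PSMTable,
                 config: TransferConfig) -> PSMTable:
    """Transfer identifications over all clusters; output holds only
    origin=transfer PSMs. Provenance records cluster-state counts."""
    counts = {s.value: 0 for s in ClusterState}
    accepted_spectra = {p.spectrum_ref for p in accepted_psms}
    rows: list[PSM] = []
    for cluster in clusters:
        counts[cluster.state.value] += 1
        sources = select_transfer_sources(cluster, accepted_psms, config)
        members_accepted = accepted_spectra & set(cluster.members)
        rows.extend(transfer_cluster(cluster, sources, config, members_accepted))
    prov = {
        "n_clusters": len(clusters),
        "cluster_states": counts,
        "n_transferred": len(rows),
        "ambiguity_decision": config.ambiguity_decision,
        "maximum_pep_percent": config.maximum_pep_percent,
    }
    return PSMTable(rows, prov).sorted()
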