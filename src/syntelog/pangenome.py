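"""Pangenome hub assignment and hub-mediated ortholog candidates.

A gene is assigned to the pangenome hub whose member genes collect the
highest total BIT score over all per-accession hit tables.  Running the
same assignment for the reference proteome links query and reference genes
through shared hub ids; reference genes sharing the query's hub are its
pangenome co-orthologs.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

from .model import HitRecord, HubAssignment, HubMembership, PangenomeCall

logger = logging.getLogger(__name__)


def hub_scores(
    hits_per_accession: Mapping[str, Iterable[HitRecord]],
    membership: HubMembership,
) -> dict[str, dict[str, float]]:
    """Per-gene totals of BIT score by hub, summed over all accessions.

    Subjects missing from the membership map are excluded from every total;
    their count is logged as a warning.
    """
    scores: dict[str, dict[str, float]] = {}
    uncovered = 0
    for accession in sorted(hits_per_accession):
        for h in hits_per_accession[accession]:
            hub = membership.hub_of(h.subject_id)
            if hub is None:
                uncovered += 1
                continue
            per_hub = scores.setdefault(h.query_id, {})
            per_hub[hub] = per_hub.get(hub, 0.0) + h.bitscore
    if uncovered:
        logger.warning(
            "%d hits to subjects absent from hub membership were ignored",
            uncovered,
        )
    return scores


def assign_hub(gene_id: str, scores: Mapping[str, float]) -> HubAssignment | None:
    """Winning hub by total BIT score; ties go to the smallest hub id.
    Returns ``None`` for a gene with no scored hubs."""
    if not scores:
        return None
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    hub, total = ranked[0]
    runner_up, runner_total = (ranked[1] if len(ranked) > 1 else (None, 0.0))
    return HubAssignment(gene_id, hub, total, runner_up, runner_total)


def assign_hubs(
    scores: Mapping[str, Mapping[str, float]]
) -> dict[str, HubAssignment]:
    out = {}
    for gene in sorted(scores):
        ha = assign_hub(gene, scores[gene])
        if ha is not None:
            out[gene] = ha
    return out


def pangenome_orthologs(
    query_hubs: Mapping[str, HubAssignment],
    reference_hubs: Mapping[str, HubAssignment],
    direct_fwd_hits: Iterable[HitRecord],
) -> dict[str, PangenomeCall]:
    """Reference genes sharing each query gene's hub.

    The full co-ortholog list is retained; a single representative — the
    co-ortholog with the highest direct forward bitscore to the query,
    falling back to the smallest gene id when no direct hit exists — is
    distilled for conflict resolution.
    """
    hub_members: dict[str, list[str]] = {}
    for ref, ha in reference_hubs.items():
        hub_members.setdefault(ha.hub_id, []).append(ref)
    for members in hub_members.values():
        members.sort()

    direct: dict[tuple[str, str], float] = {
        (h.query_id, h.subject_id): h.bitscore for h in direct_fwd_hits
    }

    calls: dict[str, PangenomeCall] = {}
    for query in sorted(query_hubs):
        members = hub_members.get(query_hubs[query].hub_id, [])
        if not members:
            calls[query] = PangenomeCall(query, None, ())
            continue
        scored = [m for m in members if (query, m) in direct]
        if scored:
            rep = min(scored, key=lambda m: (-direct[(query, m)], m))
        else:
            rep = members[0]
        calls[query] = PangenomeCall(query, rep, tuple(members))
    return calls
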