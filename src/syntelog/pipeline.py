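"""End-to-end driver chaining the four assignment stages."""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .besthit import bbh_partner_map, best_hit_per_query, bidirectional_best_hits
from .model import (
    BlockMap,
    ConsensusResult,
    DecayParams,
    GeneOrder,
    HitRecord,
    HubMembership,
    OrthologCall,
    PangenomeCall,
    SyntenyCall,
)
from .pangenome import assign_hubs, hub_scores, pangenome_orthologs
from .resolve import resolve_all
from .synteny import consensus_blocks, initial_assignment, synteny_correct

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    calls: list[OrthologCall]
    consensus: dict[str, ConsensusResult]
    synteny_calls: dict[str, SyntenyCall]
    pangenome_calls: dict[str, PangenomeCall]
    bbh_partners: dict[str, str]
    initial_blocks: dict[str, str] = field(default_factory=dict)
    tallies: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    fwd_hits: Iterable[HitRecord],
    rev_hits: Iterable[HitRecord],
    order: GeneOrder,
    block_map: BlockMap,
    membership: HubMembership,
    query_accession_hits: Mapping[str, Iterable[HitRecord]],
    reference_accession_hits: Mapping[str, Iterable[HitRecord]],
    decay_params: DecayParams | None = None,
) -> PipelineResult:
    """Best hits -> synteny correction -> pangenome hubs -> resolution.

    Every gene in the query gene order receives exactly one final
    :class:`OrthologCall` (possibly with no reference).  Per-stage tallies
    are logged and returned for auditing.
    """
    fwd_hits = list(fwd_hits)

    best = best_hit_per_query(fwd_hits)
    initials = initial_assignment(best, block_map)
    consensus = consensus_blocks(order, initials, decay_params)
    synteny_calls = synteny_correct(initials, consensus, fwd_hits, block_map)

    q_hubs = assign_hubs(hub_scores(query_accession_hits, membership))
    r_hubs = assign_hubs(hub_scores(reference_accession_hits, membership))
    pangenome_calls = pangenome_orthologs(q_hubs, r_hubs, fwd_hits)

    bbh = bidirectional_best_hits(fwd_hits, rev_hits)
    partners = bbh_partner_map(bbh)

    calls = resolve_all(
        order.gene_ids(), synteny_calls, pangenome_calls, partners, block_map
    )

    flag_counts = Counter(c.flag for c in synteny_calls.values())
    tallies = {
        "queries": len(order),
        "best_hits": len(best),
        "syntenic": flag_counts.get("syntenic", 0),
        "non_syntenic": flag_counts.get("non_syntenic", 0),
        "unblocked": flag_counts.get("unblocked", 0),
        "corrected": sum(c.corrected for c in synteny_calls.values()),
        "pangenome_called": sum(
            1 for c in pangenome_calls.values() if c.representative is not None
        ),
        "bbh_pairs": len(bbh),
    }
    tallies.update(
        {f"resolved_{m}": n for m, n in Counter(c.method for c in calls).items()}
    )
    for key, value in tallies.items():
        logger.info("%s: %d", key, value)

    return PipelineResult(
        calls=calls,
        consensus=consensus,
        synteny_calls=synteny_calls,
        pangenome_calls=pangenome_calls,
        bbh_partners=partners,
        initial_blocks={ia.query_id: ia.block for ia in initials},
        tallies=tallies,
    )
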