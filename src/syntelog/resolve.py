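"""Conflict resolution between synteny and pangenome ortholog calls.

The decision tree, applied per query gene:

1. both methods report the same reference gene  -> keep it      (``agree``)
2. exactly one method reports an ortholog       -> keep it      (``synteny_only`` / ``pangenome_only``)
3. they disagree and exactly one candidate is syntenic (its block equals
   the consensus block)                          -> keep the syntenic one
                                                                (``syntenic_override``)
4. any other conflict — both candidates syntenic, neither syntenic, or no
   consensus block available — falls back to the query's bidirectional
   best hit, if one exists                       (``bbh_fallback``)
5. otherwise no call is made                     (``none``)

A gene for which neither method reports an ortholog has no conflict to
resolve and yields ``none`` even when a BBH partner exists.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

from .model import (
    BlockMap,
    OrthologCall,
    PangenomeCall,
    SyntenyCall,
)


def _syntenic_flag(
    reference_id: str | None, consensus: str | None, block_map: BlockMap
) -> str:
    if reference_id is None or consensus is None:
        return "unblocked"
    if block_map.lookup(reference_id) == consensus:
        return "syntenic"
    return "non_syntenic"


def resolve_one(
    query_id: str,
    synteny_call: SyntenyCall | None,
    pangenome_call: PangenomeCall | None,
    bbh_partner: str | None,
    block_map: BlockMap,
) -> OrthologCall:
    """Resolve one query gene through the decision tree."""
    s = synteny_call.reference_id if synteny_call is not None else None
    p = pangenome_call.representative if pangenome_call is not None else None
    consensus = synteny_call.consensus if synteny_call is not None else None

    def syntenic(gene: str) -> bool:
        return consensus is not None and block_map.lookup(gene) == consensus

    if s is not None and p is not None:
        if s == p:
            final, method = s, "agree"
        else:
            s_syn, p_syn = syntenic(s), syntenic(p)
            if s_syn != p_syn:
                final, method = (s, "syntenic_override") if s_syn else (
                    p,
                    "syntenic_override",
                )
            elif bbh_partner is not None:
                final, method = bbh_partner, "bbh_fallback"
            else:
                final, method = None, "none"
    elif s is not None:
        final, method = s, "synteny_only"
    elif p is not None:
        final, method = p, "pangenome_only"
    else:
        final, method = None, "none"

    return OrthologCall(
        query_id=query_id,
        reference_id=final,
        method=method,
        syntenic_flag=_syntenic_flag(final, consensus, block_map),
        consensus_block=consensus,
        synteny_candidate=s,
        pangenome_candidate=p,
        bbh_candidate=bbh_partner,
    )


def resolve_all(
    query_ids: Iterable[str],
    synteny_calls: Mapping[str, SyntenyCall],
    pangenome_calls: Mapping[str, PangenomeCall],
    bbh_partners: Mapping[str, str],
    block_map: BlockMap,
) -> list[OrthologCall]:
    """Resolve every listed query gene; queries are emitted in sorted order."""
    return [
        resolve_one(
            q,
            synteny_calls.get(q),
            pangenome_calls.get(q),
            bbh_partners.get(q),
            block_map,
        )
        for q in sorted(set(query_ids))
    ]
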