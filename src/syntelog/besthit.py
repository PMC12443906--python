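"""Best-hit and bidirectional-best-hit (BBH) extraction.

Ties on bitscore are broken by the lexicographically smallest partner id,
identically in both search directions, so the BBH set is symmetric under
swapping the two directions.
"""

from __future__ import annotations

from collections.abc import Iterable

from .model import HitRecord


def best_hit_per_query(hits: Iterable[HitRecord]) -> dict[str, tuple[str, float]]:
    """Highest-bitscore partner for each query gene.

    Input must already be HSP-collapsed (one row per gene pair).  A gene
    with no hits is simply absent from the result.
    """
    best: dict[str, tuple[str, float]] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.bitscore > cur[1]
            or (h.bitscore == cur[1] and h.subject_id < cur[0])
        ):
            best[h.query_id] = (h.subject_id, h.bitscore)
    return best


def bidirectional_best_hits(
    fwd: Iterable[HitRecord], rev: Iterable[HitRecord]
) -> set[tuple[str, str]]:
    """Mutual-best (query, reference) pairs.

    (q, r) is reported iff r is q's best forward hit and q is r's best
    reverse hit.  Non-syntenic pairs are reported too; syntenic filtering
    belongs to conflict resolution.
    """
    fbest = best_hit_per_query(fwd)
    rbest = best_hit_per_query(rev)
    return {
        (q, r)
        for q, (r, _) in fbest.items()
        if rbest.get(r, ("",))[0] == q
    }


def bbh_partner_map(bbh: set[tuple[str, str]]) -> dict[str, str]:
    """Query -> BBH reference partner (each query has at most one)."""
    return {q: r for q, r in bbh}
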