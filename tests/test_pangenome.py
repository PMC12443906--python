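import itertools
import random

import pytest

from conftest import hits
from syntelog import (
    HitRecord,
    HubMembership,
    assign_hub,
    assign_hubs,
    hub_scores,
    pangenome_orthologs,
)

MEMBER = HubMembership({"a1": "H1", "a2": "H1", "a3": "H2"})


def test_hub_scores_sum_over_members_and_accessions():
    tables = {
        "accA": hits(("q", "a1", 200.0), ("q", "a3", 300.0)),
        "accB": hits(("q", "a2", 150.0)),
    }
    assert hub_scores(tables, MEMBER) == {"q": {"H1": 350.0, "H2": 300.0}}


def test_uncovered_subjects_are_excluded(caplog):
    tables = {"accA": hits(("q", "a1", 200.0), ("q", "mystery", 900.0))}
    with caplog.at_level("WARNING"):
        scores = hub_scores(tables, MEMBER)
    assert scores == {"q": {"H1": 200.0}}
    assert "1 hits" in caplog.text


def test_no_hits_gives_empty_scores():
    assert hub_scores({}, MEMBER) == {}


def test_assign_hub_argmax_tie_and_runner_up():
    ha = assign_hub("q", {"H1": 350.0, "H2": 300.0})
    assert (ha.hub_id, ha.total) == ("H1", 350.0)
    assert (ha.runner_up_id, ha.runner_up_total) == ("H2", 300.0)
    assert assign_hub("q", {"H2": 300.0, "H1": 300.0}).hub_id == "H1"
    assert assign_hub("q", {}) is None


def test_hub_totals_permutation_invariant_over_accessions():
    tables = {
        "a": hits(("q", "a1", 10.0)),
        "b": hits(("q", "a2", 20.0), ("q", "a3", 5.0)),
        "c": hits(("q", "a1", 7.0)),
    }
    base = hub_scores(tables, MEMBER)
    for perm in itertools.permutations(tables):
        assert hub_scores({k: tables[k] for k in perm}, MEMBER) == base


def test_representative_prefers_highest_direct_hit():
    q_hubs = assign_hubs({"q": {"H1": 100.0}})
    r_hubs = assign_hubs(
        {"r1": {"H1": 50.0}, "r2": {"H1": 60.0}, "r3": {"H2": 70.0}}
    )
    direct = hits(("q", "r2", 180.0), ("q", "r1", 90.0))
    calls = pangenome_orthologs(q_hubs, r_hubs, direct)
    assert calls["q"].representative == "r2"
    assert calls["q"].co_orthologs == ("r1", "r2")


def test_representative_falls_back_to_lexicographic_without_direct_hits():
    q_hubs = assign_hubs({"q": {"H1": 100.0}})
    r_hubs = assign_hubs({"r2": {"H1": 1.0}, "r1": {"H1": 1.0}})
    calls = pangenome_orthologs(q_hubs, r_hubs, [])
    assert calls["q"].representative == "r1"


def test_query_hub_without_reference_members_gives_empty_call():
    q_hubs = assign_hubs({"q": {"H9": 100.0}})
    r_hubs = assign_hubs({"r1": {"H1": 50.0}})
    calls = pangenome_orthologs(q_hubs, r_hubs, [])
    assert calls["q"].representative is None
    assert calls["q"].co_orthologs == ()


def brute_force_hub_scores(tables, membership):
    out = {}
    for acc in tables:
        for h in tables[acc]:
            hub = membership.hub_of(h.subject_id)
            if hub is None:
                continue
            out.setdefault(h.query_id, {}).setdefault(hub, 0.0)
            out[h.query_id][hub] += h.bitscore
    return out


def test_matches_brute_force_on_random_instances():
    rng = random.Random(5)
    genes = [f"m{i}" for i in range(20)]
    membership = HubMembership({g: f"H{rng.randint(0, 4)}" for g in genes[:15]})
    for _ in range(20):
        tables = {
            f"acc{a}": [
                HitRecord(f"q{rng.randint(0, 5)}", rng.choice(genes),
                          float(rng.randint(1, 100)))
                for _ in range(rng.randint(0, 30))
            ]
            for a in range(3)
        }
        # collapse duplicates per accession as the reader would
        collapsed = {}
        for acc, rows in tables.items():
            best = {}
            for h in rows:
                k = (h.query_id, h.subject_id)
                if k not in best or h.bitscore > best[k].bitscore:
                    best[k] = h
            collapsed[acc] = list(best.values())
        got = hub_scores(collapsed, membership)
        expected = brute_force_hub_scores(collapsed, membership)
        for q in set(got) | set(expected):
            for hub in set(got.get(q, {})) | set(expected.get(q, {})):
                assert got[q][hub] == pytest.approx(expected[q][hub])


def test_representative_shares_hub_with_all_co_orthologs(small_trap_dataset):
    ds = small_trap_dataset
    q_hubs = assign_hubs(
        hub_scores(ds.query_accession_hits, ds.genomes.membership)
    )
    r_hubs = assign_hubs(
        hub_scores(ds.reference_accession_hits, ds.genomes.membership)
    )
    calls = pangenome_orthologs(q_hubs, r_hubs, ds.fwd_hits)
    for call in calls.values():
        if call.representative is None:
            continue
        assert call.representative in call.co_orthologs
        hubs = {r_hubs[m].hub_id for m in call.co_orthologs}
        assert hubs == {q_hubs[call.query_id].hub_id}
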