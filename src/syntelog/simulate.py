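"""Seeded simulator with planted ground truth, plus recovery metrics.

The simulator emulates the pipeline's four inputs for an
allopolyploid-versus-diploid comparison: a reference genome partitioned
into synteny blocks, a query genome carrying ``subgenome_copies``
block-contiguous copies of every reference gene (homoeologs map to one
reference gene), a pangenome of accession copies clustered into one hub
per reference gene family, and bidirectional plus per-accession hit
tables.  No sequences are simulated — BIT scores are drawn directly from
truncated-at-zero normal distributions, since only score order matters to
the algorithm.

*Trap* genes are the planted failure mode of plain best-hit assignment:
their top forward hit is forced to be a cross-block paralog, while the
true ortholog — which lies in the gene's chromosome-context block —
remains second best.  Synteny correction should recover them.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    BlockMap,
    GeneOrder,
    HitRecord,
    HubMembership,
    Locus,
    OrthologCall,
)

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: gene spacing (bp) used when laying out simulated chromosomes
_GENE_SPACING = 1000
_GENE_LENGTH = 600


def _block_label(i: int) -> str:
    if i < len(_LETTERS):
        return _LETTERS[i]
    return f"{_LETTERS[i % len(_LETTERS)]}{i // len(_LETTERS) + 1}"


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated instance.

    Defaults describe a 20-block x 50-gene reference genome duplicated
    into two subgenomes (2000 query genes) compared against 8 pangenome
    accessions.  Score distributions (means/sds in BIT score units) only
    need to define an order: true orthologs score highest, cross-block
    paralogs lower, background noise lowest.
    """

    seed: int
    n_blocks: int = 20
    genes_per_block: int = 50
    subgenome_copies: int = 2
    p_trap: float = 0.1
    paralog_fraction: float = 0.3
    true_mean: float = 400.0
    true_sd: float = 40.0
    paralog_mean: float = 250.0
    paralog_sd: float = 40.0
    noise_mean: float = 80.0
    noise_sd: float = 20.0
    noise_rate: float = 1.0
    n_accessions: int = 8
    dropout: float = 0.05
    chromosomes_per_subgenome: int = 4
    shuffle_blocks: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.genes_per_block < 1:
            raise ValueError("need at least one block and one gene per block")
        if self.subgenome_copies < 1 or self.n_accessions < 0:
            raise ValueError("degenerate subgenome or accession count")
        if self.chromosomes_per_subgenome < 1:
            raise ValueError("need at least one chromosome per subgenome")
        for name in ("p_trap", "paralog_fraction", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        if self.n_blocks < 2 and (self.p_trap > 0 or self.paralog_fraction > 0):
            raise ValueError("cross-block paralogs require at least 2 blocks")


@dataclass(frozen=True)
class TruthSet:
    """Planted ground truth of one simulated instance."""

    orthologs: dict[str, str]
    traps: tuple[str, ...]
    homoeolog_groups: tuple[tuple[str, ...], ...]


@dataclass
class SimulatedGenomes:
    params: SimParams
    order: GeneOrder
    block_map: BlockMap
    membership: HubMembership
    truth: TruthSet
    ref_genes: list[str]
    ref_block: dict[str, str]
    paralog_targets: dict[str, str]
    accessions: list[str]
    #: (accession, reference gene) -> accession gene id, for families that
    #: survived dropout in that accession
    accession_gene: dict[tuple[str, str], str]


@dataclass
class SimulatedDataset:
    genomes: SimulatedGenomes
    fwd_hits: list[HitRecord]
    rev_hits: list[HitRecord]
    query_accession_hits: dict[str, list[HitRecord]]
    reference_accession_hits: dict[str, list[HitRecord]]

    @property
    def truth(self) -> TruthSet:
        return self.genomes.truth


def _tnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (redraw; exceedingly rare at the
    default means)."""
    while True:
        x = float(rng.normal(mean, sd))
        if x > 0:
            return x


def _trap_score(true_score: float, rng: np.random.Generator) -> float:
    """Paralog score forced strictly above the true-ortholog score, by a
    margin that survives the 0.1-unit rounding of emitted bitscores."""
    return max(true_score * float(rng.uniform(1.05, 1.3)), true_score + 1.0)


def simulate_truth(params: SimParams) -> SimulatedGenomes:
    """Build reference/query genomes, block map, hubs and planted truth.

    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, 0])
    n_fam = params.n_blocks * params.genes_per_block

    ref_genes = [f"ref{i:05d}" for i in range(n_fam)]
    ref_block = {
        g: _block_label(i // params.genes_per_block)
        for i, g in enumerate(ref_genes)
    }

    # query genome: block-contiguous subgenome copies, blocks shuffled
    # across a few chromosomes per subgenome
    loci: list[Locus] = []
    orthologs: dict[str, str] = {}
    query_block: dict[str, str] = {}
    homoeologs: dict[str, list[str]] = {g: [] for g in ref_genes}
    for s in range(1, params.subgenome_copies + 1):
        block_order = (
            list(rng.permutation(params.n_blocks))
            if params.shuffle_blocks
            else list(range(params.n_blocks))
        )
        chrom_blocks = np.array_split(block_order, params.chromosomes_per_subgenome)
        for c, blocks in enumerate(chrom_blocks, start=1):
            chrom = f"q{s}_chr{c}"
            pos = 0
            for b in blocks:
                fam_lo = int(b) * params.genes_per_block
                for i in range(fam_lo, fam_lo + params.genes_per_block):
                    ref = ref_genes[i]
                    qid = f"q{s}_{ref}"
                    start = pos * _GENE_SPACING
                    loci.append(
                        Locus(qid, chrom, start, start + _GENE_LENGTH, "+")
                    )
                    orthologs[qid] = ref
                    query_block[qid] = ref_block[ref]
                    homoeologs[ref].append(qid)
                    pos += 1
    order = GeneOrder(loci)
    queries = sorted(orthologs)

    # planted traps and cross-block paralog partners
    trap_draw = rng.random(len(queries))
    paralog_draw = rng.random(len(queries))
    traps: list[str] = []
    paralog_targets: dict[str, str] = {}
    for i, q in enumerate(queries):
        is_trap = trap_draw[i] < params.p_trap
        if is_trap:
            traps.append(q)
        if is_trap or paralog_draw[i] < params.paralog_fraction:
            while True:
                j = int(rng.integers(len(ref_genes)))
                if ref_block[ref_genes[j]] != query_block[q]:
                    paralog_targets[q] = ref_genes[j]
                    break

    # pangenome: one hub per reference gene family; accession copies
    # survive dropout independently per accession
    accessions = [f"acc{a:02d}" for a in range(1, params.n_accessions + 1)]
    membership: dict[str, str] = {}
    accession_gene: dict[tuple[str, str], str] = {}
    keep = rng.random((len(accessions), n_fam)) >= params.dropout
    for a, acc in enumerate(accessions):
        for i, ref in enumerate(ref_genes):
            if keep[a, i]:
                gid = f"{acc}_{ref}"
                membership[gid] = f"hub{i:05d}"
                accession_gene[(acc, ref)] = gid

    truth = TruthSet(
        orthologs=orthologs,
        traps=tuple(traps),
        homoeolog_groups=tuple(
            tuple(v) for v in homoeologs.values() if len(v) > 1
        ),
    )
    return SimulatedGenomes(
        params=params,
        order=order,
        block_map=BlockMap(ref_block),
        membership=HubMembership(membership),
        truth=truth,
        ref_genes=ref_genes,
        ref_block=ref_block,
        paralog_targets=paralog_targets,
        accessions=accessions,
        accession_gene=accession_gene,
    )


def _collapsed(hits: Iterable[HitRecord]) -> list[HitRecord]:
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or h.bitscore > cur.bitscore:
            best[key] = h
    return [best[k] for k in sorted(best)]


def simulate_hits(genomes: SimulatedGenomes) -> SimulatedDataset:
    """Draw forward, reverse and per-accession hit tables.

    Every query gene hits its true ortholog (true-score distribution);
    paralog-bearing genes also hit their cross-block paralog (paralog
    distribution, forced above the true score for trap genes, in the
    forward and query-vs-accession directions); sparse Poisson noise hits
    are added to the bidirectional tables.  All tables are HSP-collapsed
    and canonically sorted.  Deterministic given the seed.
    """
    params = genomes.params
    rng = np.random.default_rng([params.seed, 1])
    truth = genomes.truth
    queries = sorted(truth.orthologs)

    fwd: list[HitRecord] = []
    rev: list[HitRecord] = []
    q_acc: dict[str, list[HitRecord]] = {a: [] for a in genomes.accessions}
    r_acc: dict[str, list[HitRecord]] = {a: [] for a in genomes.accessions}
    trap_set = set(truth.traps)

    for q in queries:
        ref = truth.orthologs[q]
        t = _tnorm(rng, params.true_mean, params.true_sd)
        fwd.append(HitRecord(q, ref, round(t, 1)))
        rev.append(HitRecord(ref, q, round(_tnorm(rng, params.true_mean, params.true_sd), 1)))
        paralog = genomes.paralog_targets.get(q)
        if paralog is not None:
            if q in trap_set:
                p_score = _trap_score(t, rng)
            else:
                p_score = _tnorm(rng, params.paralog_mean, params.paralog_sd)
            fwd.append(HitRecord(q, paralog, round(p_score, 1)))
            rev.append(
                HitRecord(
                    paralog,
                    q,
                    round(_tnorm(rng, params.paralog_mean, params.paralog_sd), 1),
                )
            )
        for k in range(int(rng.poisson(params.noise_rate))):
            subj = genomes.ref_genes[int(rng.integers(len(genomes.ref_genes)))]
            if subj == ref or subj == paralog:
                continue
            fwd.append(
                HitRecord(q, subj, round(_tnorm(rng, params.noise_mean, params.noise_sd), 1))
            )
        # per-accession evidence mirrors the gene's true similarity
        # structure, including the forced paralog preference of traps
        for acc in genomes.accessions:
            true_copy = genomes.accession_gene.get((acc, ref))
            t_a = _tnorm(rng, params.true_mean, params.true_sd)
            if true_copy is not None:
                q_acc[acc].append(HitRecord(q, true_copy, round(t_a, 1)))
            if paralog is not None:
                p_copy = genomes.accession_gene.get((acc, paralog))
                if p_copy is not None:
                    if q in trap_set:
                        pa = _trap_score(t_a, rng)
                    else:
                        pa = _tnorm(rng, params.paralog_mean, params.paralog_sd)
                    q_acc[acc].append(HitRecord(q, p_copy, round(pa, 1)))

    # reverse-direction noise, per reference gene
    if params.noise_rate > 0:
        for ref in genomes.ref_genes:
            for k in range(int(rng.poisson(params.noise_rate))):
                subj = queries[int(rng.integers(len(queries)))]
                if truth.orthologs[subj] == ref:
                    continue
                rev.append(
                    HitRecord(
                        ref, subj, round(_tnorm(rng, params.noise_mean, params.noise_sd), 1)
                    )
                )

    # reference proteome vs each accession: clean within-family evidence
    for ref in genomes.ref_genes:
        for acc in genomes.accessions:
            copy = genomes.accession_gene.get((acc, ref))
            if copy is not None:
                r_acc[acc].append(
                    HitRecord(
                        ref, copy, round(_tnorm(rng, params.true_mean, params.true_sd), 1)
                    )
                )

    return SimulatedDataset(
        genomes=genomes,
        fwd_hits=_collapsed(fwd),
        rev_hits=_collapsed(rev),
        query_accession_hits={a: _collapsed(h) for a, h in q_acc.items()},
        reference_accession_hits={a: _collapsed(h) for a, h in r_acc.items()},
    )


def simulate(params: SimParams) -> SimulatedDataset:
    """Convenience wrapper: genomes + hit tables in one call."""
    return simulate_hits(simulate_truth(params))


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well final calls recover the planted truth.

    ``precision`` is None when no calls were made; ``trap_recovery`` is
    None when no traps were planted.
    """

    precision: float | None
    recall: float
    trap_recovery: float | None
    n_calls: int
    n_correct: int
    n_truth: int
    method_counts: Mapping[str, int] = field(default_factory=dict)


def evaluate(calls: Iterable[OrthologCall], truth: TruthSet) -> RecoveryMetrics:
    """Precision/recall of final calls and recovery of planted traps."""
    called = {c.query_id: c.reference_id for c in calls if c.reference_id is not None}
    methods = Counter(c.method for c in calls)
    correct = sum(
        1 for q, r in called.items() if truth.orthologs.get(q) == r
    )
    n_truth = len(truth.orthologs)
    trap_recovery = None
    if truth.traps:
        trap_recovery = sum(
            1 for q in truth.traps if called.get(q) == truth.orthologs[q]
        ) / len(truth.traps)
    return RecoveryMetrics(
        precision=(correct / len(called)) if called else None,
        recall=(correct / n_truth) if n_truth else 0.0,
        trap_recovery=trap_recovery,
        n_calls=len(called),
        n_correct=correct,
        n_truth=n_truth,
        method_counts=dict(methods),
    )


def write_truth(truth: TruthSet, destination) -> None:
    trap_set = set(truth.traps)
    with open(destination, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("query_id\treference_id\tis_trap\n")
        for q in sorted(truth.orthologs):
            fh.write(f"{q}\t{truth.orthologs[q]}\t{int(q in trap_set)}\n")


def read_truth(source) -> TruthSet:
    orthologs: dict[str, str] = {}
    traps: list[str] = []
    with open(source, "rt", encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields[0] or fields[0] == "query_id" or fields[0].startswith("#"):
                continue
            orthologs[fields[0]] = fields[1]
            if len(fields) > 2 and fields[2] == "1":
                traps.append(fields[0])
    return TruthSet(orthologs, tuple(traps), ())


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Emit every pipeline input (plus the truth table) as text files in
    the reader dialects, so the simulator doubles as a fixture generator."""
    from .io import write_hit_table  # local import to avoid cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes = dataset.genomes
    paths: dict[str, Path] = {}

    p = paths["gene_order"] = outdir / "gene_order.tsv"
    with open(p, "wt", encoding="utf-8", newline="\n") as fh:
        for loc in genomes.order:
            # emit 1-based closed coordinates (the TSV dialect)
            fh.write(
                f"{loc.gene_id}\t{loc.chrom}\t{loc.start + 1}\t{loc.end}\t{loc.strand}\n"
            )

    p = paths["block_map"] = outdir / "block_map.tsv"
    with open(p, "wt", encoding="utf-8", newline="\n") as fh:
        for gene, block in sorted(genomes.block_map.items()):
            fh.write(f"{gene}\t{block}\n")

    p = paths["hub_membership"] = outdir / "hub_membership.tsv"
    with open(p, "wt", encoding="utf-8", newline="\n") as fh:
        for gene, hub in sorted(genomes.membership.items()):
            fh.write(f"{gene}\t{hub}\n")

    paths["fwd_hits"] = outdir / "fwd_hits.tsv"
    write_hit_table(dataset.fwd_hits, paths["fwd_hits"])
    paths["rev_hits"] = outdir / "rev_hits.tsv"
    write_hit_table(dataset.rev_hits, paths["rev_hits"])

    for acc in genomes.accessions:
        qp = outdir / f"query_vs_{acc}.tsv"
        write_hit_table(dataset.query_accession_hits[acc], qp)
        paths[f"query_vs_{acc}"] = qp
        rp = outdir / f"ref_vs_{acc}.tsv"
        write_hit_table(dataset.reference_accession_hits[acc], rp)
        paths[f"ref_vs_{acc}"] = rp

    paths["truth"] = outdir / "truth.tsv"
    write_truth(dataset.truth, paths["truth"])
    return paths
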