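"""Core value types shared across the ortholog-assignment pipeline.

All genomic coordinates are stored 0-based half-open internally, whatever
the input dialect (BED is native; 1-based closed TSV is converted on read).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

#: Sentinel block label for reference genes absent from the block map.
#: Scores landing here are tracked in a shadow bucket but can never define
#: a consensus block.
UNPLACED = "UNPLACED"


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One query->subject alignment with its BIT score.

    The BIT score is the only alignment quantity the pipeline consumes;
    percent identity and alignment length are carried through for
    diagnostics only.
    """

    query_id: str
    subject_id: str
    bitscore: float
    percent_identity: float | None = None
    align_length: int | None = None

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("hit record with empty query or subject id")
        if self.bitscore < 0:
            raise ValueError(
                f"negative bitscore for {self.query_id}->{self.subject_id}"
            )


@dataclass(frozen=True, slots=True)
class Locus:
    """A gene placed on a chromosome, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."


class GeneOrder:
    """Ordered loci of the query genome.

    Entries are sorted by (chromosome, start, gene_id) and each gene receives
    a 0-based ordinal within its chromosome.  The ordinal sequence is the
    traversal order of the decayed running-sum scan; strand is stored but
    never affects ordering.
    """

    def __init__(self, entries: Iterable[Locus]) -> None:
        loci = sorted(entries, key=lambda l: (l.chrom, l.start, l.gene_id))
        index: dict[str, tuple[str, int]] = {}
        by_chrom: dict[str, list[Locus]] = {}
        for loc in loci:
            if loc.start >= loc.end:
                raise ValueError(
                    f"gene {loc.gene_id!r}: start {loc.start} >= end {loc.end}"
                )
            if loc.gene_id in index:
                raise ValueError(f"duplicate gene id {loc.gene_id!r} in gene order")
            by_chrom.setdefault(loc.chrom, []).append(loc)
            index[loc.gene_id] = (loc.chrom, len(by_chrom[loc.chrom]) - 1)
        self._loci = loci
        self._by_chrom = by_chrom
        self._index = index

    @property
    def loci(self) -> list[Locus]:
        return list(self._loci)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chrom: str) -> list[str]:
        """Gene ids on one chromosome, in ordinal order."""
        return [l.gene_id for l in self._by_chrom[chrom]]

    def gene_ids(self) -> list[str]:
        return [l.gene_id for l in self._loci]

    def ordinal(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, 0-based ordinal) of a gene."""
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self._loci)


class BlockMap:
    """Reference gene -> synteny block label (e.g. ancestral-karyotype
    block letters), with an :data:`UNPLACED` sentinel for unmapped genes."""

    def __init__(self, mapping: Mapping[str, str]) -> None:
        self._map = dict(mapping)

    def lookup(self, gene_id: str) -> str:
        return self._map.get(gene_id, UNPLACED)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._map.items()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def __len__(self) -> int:
        return len(self._map)


class HubMembership:
    """Accession gene -> pangenome hub id."""

    def __init__(self, mapping: Mapping[str, str]) -> None:
        self._map = dict(mapping)

    def hub_of(self, gene_id: str) -> str | None:
        return self._map.get(gene_id)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._map.items()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def __len__(self) -> int:
        return len(self._map)


@dataclass(frozen=True, slots=True)
class InitialAssignment:
    """A query gene's best-hit reference gene with its block label."""

    query_id: str
    reference_id: str
    bitscore: float
    block: str


@dataclass(frozen=True, slots=True)
class DecayParams:
    """Parameters of the decayed running-sum consensus scan.

    decay
        Multiplier applied to every accumulated block score at each step
        of the scan; 0.9 by default.  0 forgets all context, 1 never
        forgets.
    scan_mode
        ``forward`` scans 5'->3' by coordinate only; ``forward_plus_backward``
        (default) additionally scans 3'->5' and sums both passes, subtracting
        the focal gene's own contribution once so it is not double counted.
        The symmetric scan is the default because a one-directional sum
        systematically lags block boundaries by several loci (the upstream
        block's decayed total still dominates), mislabelling the context of
        every gene in those transition zones.
    step_rule
        ``every_locus`` applies the decay at every gene in the order,
        including genes without a hit (positional decay);
        ``hit_loci_only`` steps only at genes that have a best hit.
    """

    decay: float = 0.9
    scan_mode: str = "forward_plus_backward"
    step_rule: str = "every_locus"

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError(f"decay must be in [0, 1], got {self.decay}")
        if self.scan_mode not in ("forward", "forward_plus_backward"):
            raise ValueError(f"unknown scan mode {self.scan_mode!r}")
        if self.step_rule not in ("every_locus", "hit_loci_only"):
            raise ValueError(f"unknown step rule {self.step_rule!r}")


@dataclass(frozen=True, slots=True)
class ConsensusResult:
    """Decayed block sums and the consensus block at one locus.

    ``flag`` is ``syntenic`` when the gene's initial block equals the
    consensus, ``non_syntenic`` when it differs, and ``unblocked`` when the
    gene has no hit or its initial block is :data:`UNPLACED`.
    """

    query_id: str
    sums: Mapping[str, float]
    consensus: str | None
    flag: str


@dataclass(frozen=True, slots=True)
class SyntenyCall:
    """Final synteny-stage ortholog for one query gene."""

    query_id: str
    reference_id: str | None
    corrected: bool
    consensus: str | None
    flag: str


@dataclass(frozen=True, slots=True)
class HubAssignment:
    """A gene's winning pangenome hub by total BIT score."""

    gene_id: str
    hub_id: str
    total: float
    runner_up_id: str | None = None
    runner_up_total: float = 0.0


@dataclass(frozen=True, slots=True)
class PangenomeCall:
    """Pangenome-stage ortholog candidate for one query gene.

    ``co_orthologs`` lists every reference gene sharing the query's hub;
    ``representative`` is the single member fed to conflict resolution.
    """

    query_id: str
    representative: str | None
    co_orthologs: tuple[str, ...] = field(default=())


#: Conflict-resolution method tags, in the order the decision tree applies.
METHOD_TAGS = (
    "agree",
    "synteny_only",
    "pangenome_only",
    "syntenic_override",
    "bbh_fallback",
    "none",
)


@dataclass(frozen=True, slots=True)
class OrthologCall:
    """Final per-query ortholog with its resolution provenance."""

    query_id: str
    reference_id: str | None
    method: str
    syntenic_flag: str
    consensus_block: str | None
    synteny_candidate: str | None = None
    pangenome_candidate: str | None = None
    bbh_candidate: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {self.method!r}")
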