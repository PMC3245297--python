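"""Context-gated propagation of function annotations.

Homology alone is a weak basis for assigning substrate specificity at 30%
identity; carbohydrate-utilisation genes, however, tend to sit in operons
with their pathway partners (isomerases, epimerases, transporters).  A
candidate annotation is therefore confirmed only when the best-matching
reference protein passes the identity threshold AND at least one pathway
partner of that function lies in the candidate's operon.  The genome-wide
partner count ("functional context") is reported alongside but, by default,
does not confirm on its own.

Operons are reconstructed from gene coordinates with a standard prokaryotic
heuristic: consecutive same-strand genes on one contig with intergenic gaps
below a threshold (default 300 bp).  Regulon evidence is not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .family_io import SequenceRecord, pairwise_identity

__all__ = [
    "GeneRecord",
    "PathwayContextMap",
    "ContextReport",
    "infer_operons",
    "context_support",
    "propagate_annotation",
    "read_gene_table",
]

DEFAULT_OPERON_GAP_BP = 300


@dataclass(frozen=True)
class GeneRecord:
    """One gene's coordinates and (possibly empty) function label."""

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    function_label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        GeneRecord(
            gene_id=r["gene_id"],
            genome_id=r["genome_id"],
            contig=r["contig"],
            start=int(r["start"]),
            end=int(r["end"]),
            strand=r["strand"],
            function_label=r.get("function_label", ""),
        )
        for _, r in frame.iterrows()
    ]


def write_gene_table(genes, path: str | Path) -> None:
    pd.DataFrame([g.__dict__ for g in genes]).to_csv(path, sep="\t", index=False)


@dataclass
class PathwayContextMap:
    """function abbreviation -> pathway-partner function labels."""

    partners: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for fn, ps in self.partners.items():
            ps = frozenset(ps)
            if not ps:
                raise ValueError(f"{fn}: empty partner set")
            if fn in ps:
                raise ValueError(f"{fn}: a function cannot partner itself")
            clean[fn] = ps
        self.partners = clean

    def __getitem__(self, fn: str) -> frozenset[str]:
        if fn not in self.partners:
            raise KeyError(f"no pathway context defined for function {fn!r}")
        return self.partners[fn]

    def __contains__(self, fn: str) -> bool:
        return fn in self.partners

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayContextMap":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(partners={k: frozenset(v) for k, v in raw.items()})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: sorted(v) for k, v in self.partners.items()}, fh,
                      indent=2)


def infer_operons(
    genes, max_gap_bp: int = DEFAULT_OPERON_GAP_BP
) -> dict[str, str]:
    """Assign operon ids from coordinates within one genome.

    Consecutive genes on the same contig and strand whose intergenic gap is
    at most ``max_gap_bp`` share an operon.  Ids are deterministic
    (``contig:strand:leftmost_start``) and invariant under input order.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be non-negative")
    genes = list(genes)
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    out: dict[str, str] = {}
    by_track: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_track.setdefault((g.contig, g.strand), []).append(g)
    for (contig, strand), track in by_track.items():
        track.sort(key=lambda g: (g.start, g.gene_id))
        block: list[GeneRecord] = []
        prev_end = None
        for g in track:
            if prev_end is not None and g.start - prev_end > max_gap_bp:
                oid = f"{contig}:{strand}:{block[0].start}"
                out.update({m.gene_id: oid for m in block})
                block = []
            block.append(g)
            prev_end = max(prev_end or g.end, g.end)
        if block:
            oid = f"{contig}:{strand}:{block[0].start}"
            out.update({m.gene_id: oid for m in block})
    return out


def context_support(
    candidate: GeneRecord,
    genes,
    fn: str,
    ctx: PathwayContextMap,
    max_gap_bp: int = DEFAULT_OPERON_GAP_BP,
) -> tuple[int, int]:
    """Count pathway partners of ``fn`` in the candidate's operon and genome.

    Returns ``(genomic_count, functional_count)``; the operon count is
    always bounded by the genome-wide count.
    """
    partners = ctx[fn]
    genome_genes = [g for g in genes if g.genome_id == candidate.genome_id]
    if candidate.gene_id not in {g.gene_id for g in genome_genes}:
        genome_genes.append(candidate)
    operons = infer_operons(genome_genes, max_gap_bp)
    my_operon = operons[candidate.gene_id]
    genomic = sum(
        1
        for g in genome_genes
        if g.gene_id != candidate.gene_id
        and operons[g.gene_id] == my_operon
        and g.function_label in partners
    )
    functional = sum(
        1
        for g in genome_genes
        if g.gene_id != candidate.gene_id and g.function_label in partners
    )
    return genomic, functional


@dataclass
class ContextReport:
    """Outcome of one context-gated annotation attempt."""

    candidate_id: str
    best_reference_id: str
    identity: float
    function_candidate: str
    genomic_context_count: int
    functional_context_count: int
    confirmed: bool
    assigned_function: str | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def propagate_annotation(
    candidate: SequenceRecord,
    candidate_gene: GeneRecord,
    references,
    genes,
    ctx: PathwayContextMap,
    identity_threshold: float = 0.30,
    max_gap_bp: int = DEFAULT_OPERON_GAP_BP,
    require_genomic: bool = True,
) -> ContextReport:
    """Propagate a reference annotation to a candidate, gated by context.

    The candidate is confirmed only if its best-identity reference reaches
    ``identity_threshold`` and at least one operon partner of the
    reference's function is present (``require_genomic=False`` relaxes the
    operon requirement to genome-wide functional context).
    """
    references = list(references)
    if not references or any(not r.function_label for r in references):
        raise ValueError("references must be non-empty and function-labeled")
    best, best_ident = None, -1.0
    for ref in references:
        ident = pairwise_identity(candidate.residues, ref.residues)
        if ident > best_ident:
            best, best_ident = ref, ident
    fn = best.function_label
    genomic, functional = context_support(
        candidate_gene, genes, fn, ctx, max_gap_bp
    )
    context_ok = genomic >= 1 if require_genomic else functional >= 1
    confirmed = best_ident >= identity_threshold and context_ok
    return ContextReport(
        candidate_id=candidate.id,
        best_reference_id=best.id,
        identity=best_ident,
        function_candidate=fn,
        genomic_context_count=genomic,
        functional_context_count=functional,
        confirmed=confirmed,
        assigned_function=fn if confirmed else None,
    )
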