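"""Ortholog pairing, gene-family grouping, and taxonomy of top homology hits.

Operates purely on precomputed tabular homology-search results (BLAST
outfmt-6-like TSVs with appended phylum/kingdom columns); no sequence search
is performed here. Families are connected components of the bidirectional
best hit (BBH) graph — a deliberately simple orthogroup stand-in validated
against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

KINGDOMS = ("Bacteria", "Fungi", "other Eukaryota", "Archaea", "unknown")

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "qcovhsp",
    "phylum",
    "kingdom",
]


@dataclass(frozen=True)
class TaxHit:
    """One homology-search record with taxonomic annotation of the subject."""

    query_id: str
    subject_id: str
    genome_or_db: str
    bitscore: float
    evalue: float
    identity_pct: float
    qcov_pct: float
    phylum: str = "unknown"
    kingdom: str = "unknown"

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")


@dataclass(frozen=True)
class OrthoPair:
    gene_a: str
    gene_b: str


@dataclass
class GeneFamily:
    family_id: str
    members: list[tuple[str, str]]  # (genome, gene id)


def read_hit_table(path: str, genome_or_db: str = "") -> list[TaxHit]:
    """Read an outfmt-6-style TSV (+ phylum, kingdom columns) into TaxHits."""
    df = pd.read_csv(path, sep="\t", comment="#", names=HIT_COLUMNS, header=None)
    return [
        TaxHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            genome_or_db=genome_or_db,
            bitscore=float(r.bitscore),
            evalue=float(r.evalue),
            identity_pct=float(r.pident),
            qcov_pct=float(r.qcovhsp),
            phylum=str(r.phylum),
            kingdom=str(r.kingdom),
        )
        for r in df.itertuples(index=False)
    ]


def _top_hits(hits: list[TaxHit], max_evalue: float) -> dict[str, TaxHit]:
    """Best hit per query: largest bitscore, ties by lower evalue then subject id."""
    best: dict[str, TaxHit] = {}
    for h in sorted(hits, key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_id)):
        if h.evalue > max_evalue:
            continue
        best.setdefault(h.query_id, h)
    return best


def bidirectional_best_hits(
    hits_ab: list[TaxHit], hits_ba: list[TaxHit], max_evalue: float = 1e-5
) -> list[OrthoPair]:
    """Bidirectional top-scoring hit pairs between two genomes.

    A pair (a, b) is emitted iff b is a's highest-bitscore hit at
    E-value <= ``max_evalue`` and a is b's, ties broken by lower evalue and
    then lexicographic subject id. Output is sorted and deterministic under
    permutation of the input hit lists.
    """
    best_ab = _top_hits(hits_ab, max_evalue)
    best_ba = _top_hits(hits_ba, max_evalue)
    pairs = [
        OrthoPair(a, hit.subject_id)
        for a, hit in sorted(best_ab.items())
        if best_ba.get(hit.subject_id) is not None
        and best_ba[hit.subject_id].subject_id == a
    ]
    return pairs


def group_families(
    pairs: list[OrthoPair], all_genes: list[tuple[str, str]]
) -> list[GeneFamily]:
    """Group genes into families as connected components of the BBH graph.

    ``all_genes`` is a list of (genome, gene id); genes without any pair form
    singleton families. Family ids are deterministic: ``fam_<smallest member>``
    on the sorted component, and families are returned sorted by id.
    """
    graph: nx.Graph = nx.Graph()
    gene_to_genome = {gene: genome for genome, gene in all_genes}
    graph.add_nodes_from(gene for _, gene in all_genes)
    for p in pairs:
        graph.add_edge(p.gene_a, p.gene_b)
    families = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        families.append(
            GeneFamily(
                family_id=f"fam_{members[0]}",
                members=[(gene_to_genome.get(g, ""), g) for g in members],
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families


def classify_top_hits(
    clusters: list[tuple[str, list[str]]],
    hits: list[TaxHit],
    max_evalue: float = 1e-8,
    min_identity: float = 30.0,
    min_qcov: float = 25.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Taxonomic classification of the top homology hit per query, per cluster.

    For each query the top hit is the largest-bitscore hit with
    E-value < ``max_evalue``, identity > ``min_identity`` and HSP query
    coverage > ``min_qcov`` (all strict comparisons). Within a cluster, each
    distinct top-hit phylum is counted once, however many queries share it.
    Returns the per-cluster phylum tally and the kingdom fractions over all
    counted results. The caller is expected to have excluded hits from the
    query's own clade beforehand.
    """
    eligible = [
        h
        for h in hits
        if h.evalue < max_evalue and h.identity_pct > min_identity and h.qcov_pct > min_qcov
    ]
    top = _top_hits(eligible, max_evalue=float("inf"))

    rows = []
    kingdom_counts: dict[str, int] = {}
    for cluster_id, queries in clusters:
        seen_phyla: dict[str, str] = {}
        for q in queries:
            hit = top.get(q)
            if hit is None:
                continue
            seen_phyla.setdefault(hit.phylum, hit.kingdom)
        for phylum, kingdom in sorted(seen_phyla.items()):
            rows.append({"cluster_id": cluster_id, "phylum": phylum, "kingdom": kingdom})
            kingdom_counts[kingdom] = kingdom_counts.get(kingdom, 0) + 1
    tally = pd.DataFrame(rows, columns=["cluster_id", "phylum", "kingdom"])
    total = sum(kingdom_counts.values())
    fractions = {
        k: (kingdom_counts.get(k, 0) / total if total else 0.0) for k in KINGDOMS
    }
    return tally, fractions
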