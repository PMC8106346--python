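"""Per-gene activity evidence and cluster delineation for core biosynthetic genes.

A core (backbone) biosynthetic gene is called *active* if any of three
independent evidence streams supports it: RNA-seq transcription, a dense
6mA methylated-adenine cluster (MAC) within 500 bp of its transcription
start site, or detection of its protein product. Clusters are delineated by
greedy bidirectional extension from the core gene: a neighbor joins while it
is transcribed and within 10 kbp intergenic distance of the current
outermost member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from npomics.genome import CoverageTrack, Gene, MacSet, is_transcribed


@dataclass
class GeneCluster:
    core_id: str
    members: list[str]
    scaffold: str
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.core_id not in self.members:
            raise ValueError(f"core {self.core_id} not among cluster members")


@dataclass(frozen=True)
class EvidenceRecord:
    gene_id: str
    transcribed: bool
    promoter_methylated: bool
    protein_detected: bool
    active_any: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "active_any",
            self.transcribed or self.promoter_methylated or self.protein_detected,
        )


@dataclass(frozen=True)
class TranscriptHit:
    """One transcript-to-gene homology HSP from a tabular search report."""

    query_id: str
    evalue: float
    similarity_pct: float
    hsp_over_query: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")


def intergenic_distance(prev: Gene, nxt: Gene) -> int:
    """Bases strictly between two genes: next.start - prev.end - 1."""
    return nxt.start - prev.end - 1


def delineate_cluster(
    core: Gene,
    scaffold_genes: list[Gene],
    track: CoverageTrack,
    max_gap_bp: int = 10_000,
    min_depth: int = 5,
    min_fraction: float = 0.95,
    strict: bool = True,
) -> GeneCluster:
    """Delineate the gene cluster seeded by one core biosynthetic gene.

    Extension is greedy and stops in each direction at the first neighbor
    that is either more than ``max_gap_bp`` away from the current outermost
    member or fails the transcription filter; genes beyond a failed neighbor
    are never reconsidered. The core seeds its cluster regardless of its own
    coverage.
    """
    ids = [g.id for g in scaffold_genes]
    if core.id not in ids:
        raise KeyError(f"core gene {core.id} not on scaffold gene list")
    order = sorted(scaffold_genes, key=lambda g: (g.start, g.id))
    idx = [g.id for g in order].index(core.id)

    def passes(g: Gene) -> bool:
        return is_transcribed(
            g, track, min_depth=min_depth, min_fraction=min_fraction, strict=strict
        )

    left = idx
    while left > 0:
        cand = order[left - 1]
        if intergenic_distance(cand, order[left]) > max_gap_bp or not passes(cand):
            break
        left -= 1
    right = idx
    while right < len(order) - 1:
        cand = order[right + 1]
        if intergenic_distance(order[right], cand) > max_gap_bp or not passes(cand):
            break
        right += 1

    members = order[left : right + 1]
    return GeneCluster(
        core_id=core.id,
        members=[g.id for g in members],
        scaffold=core.scaffold,
        span=(min(g.start for g in members), max(g.end for g in members)),
    )


def classify_backbone(cluster: GeneCluster) -> str:
    """'clustered' if the delineated cluster holds two or more genes, else 'isolated'."""
    return "clustered" if len(cluster.members) >= 2 else "isolated"


def promoter_methylated(gene: Gene, macs: MacSet, window_bp: int = 500) -> bool:
    """True iff a MAC lies within ``window_bp`` of the gene's TSS (inclusive)."""
    if gene.scaffold != macs.scaffold:
        raise ValueError(
            f"gene {gene.id} on {gene.scaffold}, MAC set is {macs.scaffold}"
        )
    tss = gene.tss
    return any(abs(p - tss) <= window_bp for p in macs.positions)


def is_transcript_matched(
    hits: list[TranscriptHit],
    gene: Gene,
    max_evalue: float = 1e-3,
    min_similarity_pct: float = 95.0,
    min_hsp_over_query: float = 0.95,
    min_domains: int = 3,
    min_length_aa: int = 100,
) -> bool | None:
    """Transcript-evidence call for one gene, or None if the gene is ineligible.

    Eligibility requires >= ``min_domains`` catalytic domains and a protein of
    at least ``min_length_aa`` residues; ineligible genes return ``None`` so
    callers can exclude them from denominators rather than count them silent.
    A hit passes at E-value <= 1e-3, similarity > 95% and HSP/query > 0.95.
    """
    eligible = gene.n_domains >= min_domains and (gene.length_aa or 0) >= min_length_aa
    if not eligible:
        return None
    return any(
        h.evalue <= max_evalue
        and h.similarity_pct > min_similarity_pct
        and h.hsp_over_query > min_hsp_over_query
        for h in hits
    )


def read_transcript_hits(path: str) -> dict[str, list[TranscriptHit]]:
    """Read a transcript-hit TSV (query, evalue, similarity_pct, hsp_len, query_len)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[TranscriptHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.query, []).append(
            TranscriptHit(
                query_id=row.query,
                evalue=float(row.evalue),
                similarity_pct=float(row.similarity_pct),
                hsp_over_query=float(row.hsp_len) / float(row.query_len),
            )
        )
    return out


def integrate_evidence(
    genes: list[Gene],
    transcribed_flags: dict[str, bool],
    methylation_flags: dict[str, bool],
    protein_flags: dict[str, bool],
    strain_of: dict[str, str] | None = None,
) -> tuple[list[EvidenceRecord], pd.DataFrame]:
    """Combine the three evidence streams into per-gene records and summaries.

    Returns the records plus a summary table of evidence fractions per strain
    (when ``strain_of`` is given) and overall; a gene is active if any single
    metric supports it.
    """
    records: list[EvidenceRecord] = []
    for g in genes:
        for flags, name in (
            (transcribed_flags, "transcribed"),
            (methylation_flags, "methylation"),
            (protein_flags, "protein"),
        ):
            if g.id not in flags:
                raise ValueError(f"missing {name} flag for gene {g.id}")
        records.append(
            EvidenceRecord(
                gene_id=g.id,
                transcribed=transcribed_flags[g.id],
                promoter_methylated=methylation_flags[g.id],
                protein_detected=protein_flags[g.id],
            )
        )

    rows = []
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "transcribed": [r.transcribed for r in records],
            "promoter_methylated": [r.promoter_methylated for r in records],
            "protein_detected": [r.protein_detected for r in records],
            "active_any": [r.active_any for r in records],
        }
    )
    groups: list[tuple[str, pd.DataFrame]] = [("overall", df)]
    if strain_of:
        df["strain"] = df["gene_id"].map(strain_of)
        groups = [(s, sub) for s, sub in df.groupby("strain")] + groups
    for label, sub in groups:
        n = len(sub)
        rows.append(
            {
                "strain": label,
                "n_genes": n,
                "frac_transcribed": sub["transcribed"].mean() if n else 0.0,
                "frac_methylated": sub["promoter_methylated"].mean() if n else 0.0,
                "frac_detected": sub["protein_detected"].mean() if n else 0.0,
                "frac_active_any": sub["active_any"].mean() if n else 0.0,
            }
        )
    return records, pd.DataFrame(rows)


def region_overlap_agreement(
    set_a: list[tuple[str, int, int]], set_b_genes: list[Gene]
) -> float:
    """Fraction of genes in set B overlapping any region of set A.

    Overlap means at least one shared base on the same scaffold, intervals
    1-based inclusive. Used to compare two cluster-prediction tools' regions.
    """
    if not set_b_genes:
        return 0.0
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for scaffold, start, end in set_a:
        by_scaffold.setdefault(scaffold, []).append((start, end))
    n_hit = sum(
        1
        for g in set_b_genes
        if any(
            g.start <= e and g.end >= s for s, e in by_scaffold.get(g.scaffold, [])
        )
    )
    return n_hit / len(set_b_genes)
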