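"""Seeded synthetic-data generators with planted ground truth.

Every input format the pipeline consumes (GFF3, bedGraph, BED, homology
TSVs, newick trees, MGF spectra, feature tables) can be generated here as a
pure function of (seed, spec), with the planted truth — which genes are
transcribed/methylated/detected, the cluster memberships, ortholog
families, tree placements, compound families and feature ratios — recorded
in a :class:`TruthBundle` alongside. Each generator draws from its own
named pseudo-random stream, so adding a generator never perturbs another's
output for the same seed.

Negative cases are planted near the decision boundaries (silent-gene
coverage just under the cut, blocked decoy genes past an untranscribed
neighbor, sub-70 bootstrap branches) to exercise the rules, not just the
easy interior.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from npomics.families import TaxHit
from npomics.genome import CoverageTrack, Gene, MacSet
from npomics.specnet import Feature, Spectrum

# Named sub-streams: one per generator, so outputs are independent.
_STREAM = {
    "genome": 11,
    "coverage": 12,
    "macs": 13,
    "protein": 14,
    "transcript": 15,
    "homology": 16,
    "taxonomy": 17,
    "trees": 18,
    "spectra": 19,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


@dataclass
class TruthBundle:
    """Planted ground truth accompanying generated inputs."""

    transcribed: dict[str, bool] = field(default_factory=dict)
    methylated: dict[str, bool] = field(default_factory=dict)
    detected: dict[str, bool] = field(default_factory=dict)
    clusters: dict[str, list[str]] = field(default_factory=dict)
    backbone_class: dict[str, str] = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    families: dict[str, list[str]] = field(default_factory=dict)
    kingdom_fractions: dict[str, float] = field(default_factory=dict)
    placements: dict[str, list] = field(default_factory=dict)
    compound_of: dict[str, str] = field(default_factory=dict)
    family_of_compound: dict[str, str] = field(default_factory=dict)
    feature_ratio_pass: dict[str, bool] = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "TruthBundle":
        with open(path) as handle:
            return cls(**json.load(handle))


@dataclass(frozen=True)
class ClusterSpec:
    """Layout of one planted cluster: the core gene plus neighbors.

    ``n_members`` includes the core (1 = isolated backbone).
    ``add_blocked_decoy`` plants, past the cluster edge, an untranscribed
    neighbor at a small gap followed by a transcribed gene — delineation
    must stop at the first failure and exclude both.
    """

    n_members: int = 4
    core_index: int = 0
    methylated_fraction: float = 0.5
    detected_fraction: float = 0.3
    core_methylated: bool = False
    core_detected: bool = False
    core_transcribed: bool = True
    add_blocked_decoy: bool = False
    strain: str = "strainA"


def gen_genome(
    seed: int, cluster_specs: list[ClusterSpec], gene_len_range: tuple[int, int] = (1500, 3000)
) -> tuple[list[Gene], TruthBundle]:
    """Generate gene models realizing the planted cluster layouts.

    Each cluster occupies its own scaffold: intra-cluster intergenic gaps
    are drawn in [1200, 8000] bp (always joinable), the flanking genes past
    the cluster sit > 10 kbp away, and core genes carry >= 3 domains and
    >= 100 aa so they are eligible for every downstream filter.
    """
    rng = _rng(seed, "genome")
    genes: list[Gene] = []
    truth = TruthBundle()
    for ci, spec in enumerate(cluster_specs):
        scaffold = f"scaffold_{ci}"
        pos = int(rng.integers(5_000, 20_000))
        members: list[str] = []
        meth_flags = rng.random(spec.n_members) < spec.methylated_fraction
        det_flags = rng.random(spec.n_members) < spec.detected_fraction
        for gi in range(spec.n_members):
            is_core = gi == spec.core_index
            gid = f"c{ci}_g{gi}" + ("_core" if is_core else "")
            length = int(rng.integers(*gene_len_range))
            gene = Gene(
                id=gid,
                scaffold=scaffold,
                start=pos,
                end=pos + length - 1,
                strand="+",
                is_core=is_core,
                n_domains=int(rng.integers(3, 7)) if is_core else int(rng.integers(0, 3)),
                length_aa=length // 3,
            )
            genes.append(gene)
            members.append(gid)
            truth.transcribed[gid] = bool(spec.core_transcribed) if is_core else True
            truth.methylated[gid] = bool(spec.core_methylated if is_core else meth_flags[gi])
            truth.detected[gid] = bool(spec.core_detected if is_core else det_flags[gi])
            pos = gene.end + 1 + int(rng.integers(1200, 8000))
        core_id = members[spec.core_index]
        truth.clusters[core_id] = members
        truth.backbone_class[core_id] = "clustered" if len(members) >= 2 else "isolated"
        if spec.add_blocked_decoy:
            # untranscribed blocker at a joinable gap, then a transcribed gene
            # at a small gap beyond it: both must stay out of the cluster.
            for tag, transcribed, gap in (("blocker", False, 2000), ("beyond", True, 1000)):
                length = int(rng.integers(*gene_len_range))
                start = genes[-1].end + 1 + gap
                gid = f"c{ci}_{tag}"
                genes.append(
                    Gene(id=gid, scaffold=scaffold, start=start, end=start + length - 1,
                         strand="+", length_aa=length // 3)
                )
                truth.transcribed[gid] = transcribed
                truth.methylated[gid] = False
                truth.detected[gid] = False
        # a distant transcribed gene > 10 kbp away never joins
        length = int(rng.integers(*gene_len_range))
        start = genes[-1].end + 1 + 10_001 + int(rng.integers(0, 5000))
        gid = f"c{ci}_far"
        genes.append(
            Gene(id=gid, scaffold=scaffold, start=start, end=start + length - 1,
                 strand="+", length_aa=length // 3)
        )
        truth.transcribed[gid] = True
        truth.methylated[gid] = False
        truth.detected[gid] = False
        truth.scaffold_lengths[scaffold] = genes[-1].end + 5_000
    genes.sort(key=lambda g: (g.scaffold, g.start, g.id))
    return genes, truth


def gen_coverage(
    genes: list[Gene],
    truth: TruthBundle,
    seed: int,
    hi_depth: int = 20,
    lo_depth: int = 2,
) -> list[CoverageTrack]:
    """Per-base coverage realizing the planted transcription flags.

    Transcribed genes are covered at ``hi_depth`` over 97-100% of their
    length (a short uncovered stub at the 3' end); silent genes over about
    40-48%, comfortably under the cut but nonzero. Blocked-decoy genes get
    near-threshold 90-94% coverage to exercise the boundary. Light sub-5x
    noise is scattered outside genes.
    """
    rng = _rng(seed, "coverage")
    depths = {s: np.zeros(n, dtype=np.int64) for s, n in truth.scaffold_lengths.items()}
    for g in sorted(genes, key=lambda g: g.id):
        if truth.transcribed.get(g.id):
            frac = rng.uniform(0.97, 1.0)
        elif g.id.endswith("_blocker"):
            frac = rng.uniform(0.90, 0.94)
        else:
            frac = rng.uniform(0.40, 0.48)
        n_cov = int(np.ceil(frac * g.length))
        depths[g.scaffold][g.start - 1 : g.start - 1 + n_cov] += hi_depth
    for scaffold in sorted(depths):
        for _ in range(3):
            start = int(rng.integers(0, max(1, truth.scaffold_lengths[scaffold] - 500)))
            depths[scaffold][start : start + 300] += int(rng.integers(1, lo_depth + 1))
    return [CoverageTrack(s, depths[s]) for s in sorted(depths)]


def gen_macs(genes: list[Gene], truth: TruthBundle, seed: int) -> dict[str, MacSet]:
    """MAC positions: methylated promoters get one MAC within 500 bp of the
    TSS (inside the gene body, so it cannot stray near a neighbor's TSS);
    unmethylated genes get nothing within 600 bp."""
    rng = _rng(seed, "macs")
    per_scaffold: dict[str, list[int]] = {s: [] for s in truth.scaffold_lengths}
    for g in sorted(genes, key=lambda g: g.id):
        if truth.methylated.get(g.id):
            offset = int(rng.integers(0, 501))
            pos = g.tss + offset if g.strand == "+" else g.tss - offset
            per_scaffold[g.scaffold].append(pos)
    return {s: MacSet(s, sorted(set(p))) for s, p in per_scaffold.items()}


def gen_protein_hits(genes: list[Gene], truth: TruthBundle, seed: int, k: int = 1):
    """Peptide-detection rows: detected genes get >= k distinct peptides."""
    rng = _rng(seed, "protein")
    rows = []
    for g in sorted(genes, key=lambda g: g.id):
        if truth.detected.get(g.id):
            for p in range(k + int(rng.integers(0, 3))):
                rows.append({"gene_id": g.id, "peptide": f"{g.id}_pep{p}", "sample": "cytosolic"})
    return rows


def gen_transcript_hits(genes: list[Gene], truth: TruthBundle, seed: int):
    """Transcript homology rows: planted-transcribed genes pass the
    0.001 / >95% similarity / >0.95 HSP-over-query filter; others fail on
    one randomly chosen criterion (near-miss values)."""
    rng = _rng(seed, "transcript")
    rows = []
    for g in sorted(genes, key=lambda g: g.id):
        qlen = g.length_aa or g.length // 3
        if truth.transcribed.get(g.id):
            rows.append(
                {
                    "query": g.id,
                    "evalue": float(10.0 ** -rng.uniform(10, 50)),
                    "similarity_pct": float(rng.uniform(95.5, 99.9)),
                    "hsp_len": int(np.ceil(qlen * rng.uniform(0.96, 1.0))),
                    "query_len": qlen,
                }
            )
        else:
            mode = int(rng.integers(0, 3))
            rows.append(
                {
                    "query": g.id,
                    "evalue": float(rng.uniform(0.01, 0.5)) if mode == 0 else float(10.0 ** -rng.uniform(10, 50)),
                    "similarity_pct": float(rng.uniform(90.0, 94.9)) if mode == 1 else float(rng.uniform(95.5, 99.9)),
                    "hsp_len": int(qlen * rng.uniform(0.5, 0.9)) if mode == 2 else qlen,
                    "query_len": qlen,
                }
            )
    return rows


# ------------------------------------------------- homology / taxonomy


def gen_homology_tables(
    seed: int,
    n_families: int = 6,
    genomes: tuple[str, ...] = ("gA", "gB", "gC", "gD"),
    decoys_per_genome: int = 5,
) -> tuple[dict[tuple[str, str], list[TaxHit]], list[tuple[str, str]], TruthBundle]:
    """Pairwise homology tables planting ``n_families`` cross-genome families.

    Family members are each other's top bitscore hits in both directions;
    cross-family hits exist at lower bitscores, and decoy genes only carry
    hits above the E-value threshold, so they stay singletons.
    """
    rng = _rng(seed, "homology")
    truth = TruthBundle()
    all_genes: list[tuple[str, str]] = []
    fam_gene = {}
    for f in range(n_families):
        members = []
        for genome in genomes:
            gid = f"{genome}_fam{f}"
            fam_gene[(genome, f)] = gid
            all_genes.append((genome, gid))
            members.append(gid)
        truth.families[f"fam{f}"] = sorted(members)
    for genome in genomes:
        for d in range(decoys_per_genome):
            all_genes.append((genome, f"{genome}_dec{d}"))

    hits: dict[tuple[str, str], list[TaxHit]] = {}
    for ga in genomes:
        for gb in genomes:
            if ga == gb:
                continue
            table: list[TaxHit] = []
            for f in range(n_families):
                table.append(
                    TaxHit(
                        query_id=fam_gene[(ga, f)],
                        subject_id=fam_gene[(gb, f)],
                        genome_or_db=gb,
                        bitscore=float(800 + rng.integers(0, 200)),
                        evalue=float(10.0 ** -rng.uniform(60, 120)),
                        identity_pct=float(rng.uniform(60, 95)),
                        qcov_pct=float(rng.uniform(80, 100)),
                    )
                )
                other = (f + 1) % n_families  # weaker cross-family hit
                table.append(
                    TaxHit(
                        query_id=fam_gene[(ga, f)],
                        subject_id=fam_gene[(gb, other)],
                        genome_or_db=gb,
                        bitscore=float(100 + rng.integers(0, 100)),
                        evalue=float(10.0 ** -rng.uniform(10, 20)),
                        identity_pct=float(rng.uniform(25, 40)),
                        qcov_pct=float(rng.uniform(30, 60)),
                    )
                )
            for d in range(decoys_per_genome):
                table.append(
                    TaxHit(
                        query_id=f"{ga}_dec{d}",
                        subject_id=fam_gene[(gb, d % n_families)],
                        genome_or_db=gb,
                        bitscore=float(50 + rng.integers(0, 30)),
                        evalue=float(rng.uniform(1e-4, 1e-2)),  # above the 1e-5 cut
                        identity_pct=float(rng.uniform(20, 30)),
                        qcov_pct=float(rng.uniform(10, 30)),
                    )
                )
            hits[(ga, gb)] = table
    return hits, all_genes, truth


_PHYLA = {
    "Bacteria": ["Firmicutes", "Proteobacteria", "Bacteroidetes"],
    "Fungi": ["Basidiomycota", "Ascomycota", "Chytridiomycota"],
    "other Eukaryota": ["Streptophyta", "Ciliophora"],
    "Archaea": ["Euryarchaeota"],
}


def gen_taxonomy_hits(
    seed: int,
    n_queries: int = 100,
    kingdom_fractions: dict[str, float] | None = None,
) -> tuple[list[tuple[str, list[str]]], list[TaxHit], TruthBundle]:
    """Top-hit taxonomy fixture: one single-query cluster per query, with the
    planted kingdom assignment realized exactly by deterministic rounding.

    Default fractions mirror a bacteria-dominated homology landscape
    (63% bacterial, 20% fungal, the rest other eukaryotes). Each query gets
    one passing top hit of its planted kingdom, one lower-bitscore passing
    hit of a different kingdom, and one hit failing the identity cut.
    """
    fractions = kingdom_fractions or {"Bacteria": 0.63, "Fungi": 0.20, "other Eukaryota": 0.17}
    rng = _rng(seed, "taxonomy")
    counts = {k: int(round(v * n_queries)) for k, v in fractions.items()}
    drift = n_queries - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    assignment: list[str] = []
    for k in sorted(counts):
        assignment.extend([k] * counts[k])

    clusters, hits = [], []
    truth = TruthBundle()
    for q in range(n_queries):
        qid = f"query_{q:03d}"
        clusters.append((f"cluster_{q:03d}", [qid]))
        kingdom = assignment[q]
        phyla = _PHYLA[kingdom]
        phylum = phyla[int(rng.integers(0, len(phyla)))]
        hits.append(
            TaxHit(qid, f"{qid}_top", "nr", float(500 + rng.integers(0, 100)),
                   float(10.0 ** -rng.uniform(20, 80)), float(rng.uniform(35, 70)),
                   float(rng.uniform(40, 95)), phylum, kingdom)
        )
        alt = sorted(set(_PHYLA) - {kingdom})[int(rng.integers(0, 3))]
        hits.append(
            TaxHit(qid, f"{qid}_alt", "nr", float(200 + rng.integers(0, 100)),
                   float(10.0 ** -rng.uniform(10, 20)), float(rng.uniform(31, 50)),
                   float(rng.uniform(30, 60)), _PHYLA[alt][0], alt)
        )
        hits.append(  # fails the >30% identity cut
            TaxHit(qid, f"{qid}_lowid", "nr", float(900 + rng.integers(0, 100)),
                   1e-60, float(rng.uniform(20, 29.9)), 90.0, "Firmicutes", "Bacteria")
        )
    total = len(assignment)
    truth.kingdom_fractions = {k: assignment.count(k) / total for k in sorted(set(assignment))}
    return clusters, hits, truth


# --------------------------------------------------------------- trees


def _nwk(children: list[str], support: int | None) -> str:
    label = "" if support is None else str(support)
    return "(" + ",".join(children) + ")" + label + ":0.1"


def gen_trees(
    seed: int,
    placement_spec: list[tuple[str, str | None, str]] | None = None,
) -> tuple[list[tuple[str, str, dict[str, str]]], TruthBundle]:
    """Newick trees realizing planted placements.

    ``placement_spec`` is a list of (verdict, group, support_regime) where
    support_regime is ``high`` (all supports in [70, 100]) or ``low`` (one
    internal branch in [50, 69], which must force verdict ``none``). The
    default spec plants 50 trees of which 22 are prokaryote sister-or-nested
    (a 44% combined fraction). Returns (tree_id, newick, leaf->group) plus
    the truth placements.
    """
    if placement_spec is None:
        placement_spec = (
            [("sister", "prokaryote", "high")] * 12
            + [("nested", "prokaryote", "high")] * 10
            + [("sister", "nonfungal_eukaryote", "high")] * 4
            + [("nested", "nonfungal_eukaryote", "high")] * 4
            + [("none", None, "mixed")] * 12
            + [("none", None, "low")] * 8
        )
    rng = _rng(seed, "trees")
    trees = []
    truth = TruthBundle()

    for ti, (verdict, group, regime) in enumerate(placement_spec):
        tree_id = f"tree_{ti:03d}"
        sup = lambda: int(rng.integers(70, 101))
        low = int(rng.integers(50, 70))
        g = group or "prokaryote"
        leaves = {
            "q": f"{tree_id}_q",
            **{f"g{i}": f"{tree_id}_{g[:4]}{i}" for i in range(1, 5)},
            **{f"f{i}": f"{tree_id}_fun{i}" for i in range(1, 3)},
        }
        group_of = {leaves["q"]: "query"}
        for i in range(1, 5):
            group_of[leaves[f"g{i}"]] = g
        for i in range(1, 3):
            group_of[leaves[f"f{i}"]] = "fungi_other"
        L = lambda k: f"{leaves[k]}:0.1"

        if verdict == "sister":
            inner = _nwk([L("g1"), L("g2"), L("g3")], sup())
            parent = _nwk([L("q"), inner], sup())
            out = _nwk([L("f1"), L("f2")], sup())
            newick = f"({parent},{out});"
        elif verdict == "nested":
            s2 = low if regime == "low" else sup()
            sib = _nwk([L("g1"), L("g2")], sup())
            parent = _nwk([L("q"), sib], s2)
            flank = _nwk([L("g3"), L("g4")], sup())
            grand = _nwk([parent, flank], sup())
            out = _nwk([L("f1"), L("f2")], sup())
            newick = f"({grand},{out});"
        elif regime == "low":
            # topologically nested but support-broken: planted verdict none
            sib = _nwk([L("g1"), L("g2")], low)
            parent = _nwk([L("q"), sib], sup())
            flank = _nwk([L("g3"), L("g4")], sup())
            grand = _nwk([parent, flank], sup())
            out = _nwk([L("f1"), L("f2")], sup())
            newick = f"({grand},{out});"
        else:  # mixed sibling clade: no homogeneous foreign group
            sib = _nwk([L("g1"), L("f1")], sup())
            parent = _nwk([L("q"), sib], sup())
            out = _nwk([L("g2"), L("f2")], sup())
            newick = f"({parent},{out});"

        trees.append((tree_id, newick, group_of))
        truth.placements[tree_id] = [verdict, group]
    return trees, truth


# ------------------------------------------------------------- spectra


def gen_spectra(
    seed: int,
    n_families: int = 3,
    compounds_per_family: int = 3,
    replicates: int = 3,
    n_decoys: int = 20,
    strains: tuple[str, ...] = ("strainA", "strainB"),
    control: str = "control",
    baumin_like: bool = True,
) -> tuple[list[Spectrum], list[Feature], TruthBundle]:
    """MS/MS spectra with planted compound families, plus a feature table.

    Each family shares an 8-fragment scaffold; compounds within a family are
    offset by multiples of 14.0157 Da (a CH2 homolog series) on both the
    precursor and every fragment, so modified cosine links them through
    shifted matches. Compounds carry ``replicates`` jittered spectra each
    (>= 2, surviving consensus elimination). Decoys have unique fragments;
    half are singletons eliminated at clustering, half survive as isolated
    nodes. When ``baumin_like``, the feature table plants an m/z 523.1232
    feature at 4.7 min at >= 10-fold intensity over the control, alongside
    features straddling the fourfold cut.
    """
    rng = _rng(seed, "spectra")
    truth = TruthBundle()
    spectra: list[Spectrum] = []
    conditions = list(strains) + [control]

    for f in range(n_families):
        base_frags = np.sort(rng.uniform(120, 400, size=8))
        while np.min(np.diff(base_frags)) < 2.0:  # keep peaks resolvable
            base_frags = np.sort(rng.uniform(120, 400, size=8))
        base_int = rng.uniform(30, 100, size=8)
        base_prec = float(rng.uniform(520, 700))
        for c in range(compounds_per_family):
            comp_id = f"fam{f}_c{c}"
            offset = c * 14.0157
            cond = strains[(f + c) % len(strains)]
            truth.family_of_compound[comp_id] = f"fam{f}"
            for r in range(replicates):
                sid = f"{comp_id}_r{r}"
                scale = rng.uniform(0.9, 1.1)
                peaks = [
                    (float(m + offset + rng.uniform(-0.01, 0.01)), float(i * scale))
                    for m, i in zip(base_frags, base_int)
                ]
                spectra.append(
                    Spectrum(sid, base_prec + offset, 1, float(rng.uniform(2, 12)),
                             peaks, condition=cond, sample_id=f"{cond}_s{r}")
                )
                truth.compound_of[sid] = comp_id

    for d in range(n_decoys):
        comp_id = f"dec{d}"
        frags = np.sort(rng.uniform(120, 400, size=7))
        ints = rng.uniform(20, 80, size=7)
        prec = float(rng.uniform(450, 750))
        cond = conditions[d % len(conditions)]
        n_rep = 1 if d % 2 == 0 else 2  # half eliminated, half isolated nodes
        for r in range(n_rep):
            sid = f"{comp_id}_r{r}"
            peaks = [
                (float(m + rng.uniform(-0.01, 0.01)), float(i * rng.uniform(0.9, 1.1)))
                for m, i in zip(frags, ints)
            ]
            spectra.append(
                Spectrum(sid, prec, 1, float(rng.uniform(2, 12)), peaks,
                         condition=cond, sample_id=f"{cond}_s{r}")
            )
            truth.compound_of[sid] = comp_id

    features: list[Feature] = []
    if baumin_like:
        features.append(
            Feature("feat_baumin_like", 523.1232, 4.7,
                    {strains[0]: 5200.0, control: 400.0})
        )
        truth.feature_ratio_pass["feat_baumin_like"] = True
    for i, ratio in enumerate([8.0, 4.0, 3.9, 1.0, 0.5]):
        fid = f"feat_{i}"
        control_int = float(rng.uniform(80, 120))
        features.append(
            Feature(fid, float(rng.uniform(150, 800)), float(rng.uniform(1, 14)),
                    {strains[0]: control_int * ratio, control: control_int})
        )
        truth.feature_ratio_pass[fid] = ratio >= 4.0
    zid = "feat_zero_control"
    features.append(Feature(zid, float(rng.uniform(150, 800)), 3.3, {strains[0]: 77.0, control: 0.0}))
    truth.feature_ratio_pass[zid] = True
    return spectra, features, truth


# ---------------------------------------------------- recovery metrics


def partition_pair_metrics(
    found: dict[str, set[str]], planted: dict[str, set[str]]
) -> tuple[float, float]:
    """Pairwise precision/recall of a found partition against a planted one.

    A pair of items counts as co-grouped when both fall in the same block;
    precision is over found co-pairs, recall over planted co-pairs. Blocks
    of size one contribute no pairs.
    """
    def pairs(partition: dict[str, set[str]]) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()
        for block in partition.values():
            members = sorted(block)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    out.add(frozenset((a, b)))
        return out

    fp, pp = pairs(found), pairs(planted)
    precision = len(fp & pp) / len(fp) if fp else 1.0
    recall = len(fp & pp) / len(pp) if pp else 1.0
    return precision, recall
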