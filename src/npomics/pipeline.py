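"""Stage orchestration: file-level runs chaining the library modules.

Each ``run_*`` function reads the standard input formats, executes one wing
of the analysis with the documented defaults, writes TSV/GraphML outputs,
and returns its in-memory results. Every run also writes a machine-readable
manifest (parameters, SHA-256 input/output hashes, package version) so a
rerun can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from npomics import evidence as ev
from npomics import families as fam
from npomics import genome as gm
from npomics import hgt as hg
from npomics import masscalc as mc
from npomics import specnet as sn
from npomics import synth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path], outputs: list[Path]) -> Path:
    from npomics import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


# ------------------------------------------------------------ simulate


def default_cluster_specs(n_clusters: int = 10) -> list[synth.ClusterSpec]:
    """A small genome layout: mixed cluster sizes, isolated backbones, and
    two blocked-decoy layouts exercising the greedy stop rule."""
    sizes = [4, 3, 5, 2, 4, 1, 3, 1, 6, 2]
    specs = []
    for i in range(n_clusters):
        size = sizes[i % len(sizes)]
        specs.append(
            synth.ClusterSpec(
                n_members=size,
                core_index=size // 2 if size > 2 else 0,
                core_transcribed=i % 3 != 2,
                core_methylated=i % 4 == 1,
                core_detected=i % 5 == 2,
                add_blocked_decoy=i in (0, 4),
                strain=("strainA", "strainB")[i % 2],
            )
        )
    return specs


def simulate(seed: int, outdir: str | Path, n_clusters: int = 10) -> dict[str, Path]:
    """Generate every synthetic input the pipeline consumes, plus the truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    specs = default_cluster_specs(n_clusters)
    genes, truth = synth.gen_genome(seed, specs)
    tracks = synth.gen_coverage(genes, truth, seed)
    macs = synth.gen_macs(genes, truth, seed)
    protein_rows = synth.gen_protein_hits(genes, truth, seed)
    transcript_rows = synth.gen_transcript_hits(genes, truth, seed)

    paths["gff"] = out / "genes.gff3"
    gm.write_gff(genes, str(paths["gff"]))
    paths["bedgraph"] = out / "coverage.bedgraph"
    gm.write_bedgraph(tracks, str(paths["bedgraph"]))
    paths["macs"] = out / "macs.bed"
    with open(paths["macs"], "w") as handle:
        for scaffold in sorted(macs):
            for pos in macs[scaffold].positions:
                handle.write(f"{scaffold}\t{pos - 1}\t{pos}\n")
    paths["protein"] = out / "protein_detections.tsv"
    pd.DataFrame(protein_rows, columns=["gene_id", "peptide", "sample"]).to_csv(
        paths["protein"], sep="\t", index=False
    )
    paths["transcript"] = out / "transcript_hits.tsv"
    pd.DataFrame(transcript_rows).to_csv(paths["transcript"], sep="\t", index=False)
    paths["scaffolds"] = out / "scaffold_lengths.tsv"
    pd.DataFrame(
        sorted(truth.scaffold_lengths.items()), columns=["scaffold", "length"]
    ).to_csv(paths["scaffolds"], sep="\t", index=False)
    strain_of = {}  # cluster index encodes the strain
    for ci, spec in enumerate(specs):
        for g in genes:
            if g.id.startswith(f"c{ci}_"):
                strain_of[g.id] = spec.strain
    paths["strains"] = out / "strain_map.tsv"
    pd.DataFrame(sorted(strain_of.items()), columns=["gene_id", "strain"]).to_csv(
        paths["strains"], sep="\t", index=False
    )

    hits, all_genes, fam_truth = synth.gen_homology_tables(seed)
    truth.families = fam_truth.families
    for (ga, gb), table in sorted(hits.items()):
        p = out / f"homology_{ga}_{gb}.tsv"
        pd.DataFrame(
            [
                {
                    "qseqid": h.query_id, "sseqid": h.subject_id, "pident": h.identity_pct,
                    "length": 0, "evalue": h.evalue, "bitscore": h.bitscore,
                    "qcovhsp": h.qcov_pct, "phylum": h.phylum, "kingdom": h.kingdom,
                }
                for h in table
            ]
        ).to_csv(p, sep="\t", index=False, header=False)
        paths[f"homology_{ga}_{gb}"] = p
    paths["genome_map"] = out / "genome_map.tsv"
    pd.DataFrame(all_genes, columns=["genome", "gene_id"]).to_csv(
        paths["genome_map"], sep="\t", index=False
    )

    tax_clusters, tax_hits, tax_truth = synth.gen_taxonomy_hits(seed)
    truth.kingdom_fractions = tax_truth.kingdom_fractions
    paths["taxonomy"] = out / "taxonomy_hits.tsv"
    pd.DataFrame(
        [
            {
                "qseqid": h.query_id, "sseqid": h.subject_id, "pident": h.identity_pct,
                "length": 0, "evalue": h.evalue, "bitscore": h.bitscore,
                "qcovhsp": h.qcov_pct, "phylum": h.phylum, "kingdom": h.kingdom,
            }
            for h in tax_hits
        ]
    ).to_csv(paths["taxonomy"], sep="\t", index=False, header=False)
    paths["tax_clusters"] = out / "taxonomy_clusters.tsv"
    pd.DataFrame(
        [{"cluster_id": c, "query_id": q} for c, qs in tax_clusters for q in qs]
    ).to_csv(paths["tax_clusters"], sep="\t", index=False)

    trees, tree_truth = synth.gen_trees(seed)
    truth.placements = tree_truth.placements
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    group_rows = []
    for tree_id, newick, group_of in trees:
        (tree_dir / f"{tree_id}.nwk").write_text(newick + "\n")
        group_rows.extend({"leaf": l, "group": g} for l, g in sorted(group_of.items()))
    paths["tree_groups"] = out / "tree_groups.tsv"
    pd.DataFrame(group_rows).to_csv(paths["tree_groups"], sep="\t", index=False)
    paths["trees"] = tree_dir

    spectra, features, spec_truth = synth.gen_spectra(seed)
    truth.compound_of = spec_truth.compound_of
    truth.family_of_compound = spec_truth.family_of_compound
    truth.feature_ratio_pass = spec_truth.feature_ratio_pass
    paths["mgf"] = out / "spectra.mgf"
    sn.write_mgf(spectra, str(paths["mgf"]))
    paths["conditions"] = out / "spectrum_conditions.tsv"
    pd.DataFrame(
        [{"spectrum_id": s.id, "condition": s.condition, "sample": s.sample_id} for s in spectra]
    ).to_csv(paths["conditions"], sep="\t", index=False)
    paths["features"] = out / "features.tsv"
    conds = sorted({c for f in features for c in f.intensities})
    pd.DataFrame(
        [
            {"feature_id": f.feature_id, "mz": f.mz, "rt_min": f.rt_min,
             **{c: f.intensities.get(c, 0.0) for c in conds}}
            for f in features
        ]
    ).to_csv(paths["features"], sep="\t", index=False)

    paths["truth"] = out / "truth.json"
    truth.save(str(paths["truth"]))
    write_manifest(out, "simulate", {"seed": seed, "n_clusters": n_clusters},
                   [], [p for p in paths.values() if p.is_file()])
    return paths


# ----------------------------------------------------------------- bgc


def run_bgc(
    indir: str | Path,
    outdir: str | Path,
    max_gap_bp: int = 10_000,
    min_depth: int = 5,
    min_fraction: float = 0.95,
    strict: bool = True,
    mac_window_bp: int = 500,
    min_peptides: int = 1,
) -> dict:
    """Genomic wing: delineate clusters and integrate the three evidence streams."""
    ind, out = Path(indir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes = gm.read_gff(str(ind / "genes.gff3"))
    lengths = dict(
        pd.read_csv(ind / "scaffold_lengths.tsv", sep="\t").itertuples(index=False)
    )
    tracks = {t.scaffold: t for t in gm.read_bedgraph(str(ind / "coverage.bedgraph"), lengths)}
    macs = {m.scaffold: m for m in gm.read_mac_bed(str(ind / "macs.bed"))}
    protein = pd.read_csv(ind / "protein_detections.tsv", sep="\t")
    peptide_counts = protein.groupby("gene_id")["peptide"].nunique().to_dict()
    strain_path = ind / "strain_map.tsv"
    strain_of = (
        dict(pd.read_csv(strain_path, sep="\t").itertuples(index=False))
        if strain_path.exists()
        else None
    )

    by_scaffold: dict[str, list[gm.Gene]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    cores = [g for g in genes if g.is_core]
    clusters = [
        ev.delineate_cluster(
            core, by_scaffold[core.scaffold], tracks[core.scaffold],
            max_gap_bp=max_gap_bp, min_depth=min_depth,
            min_fraction=min_fraction, strict=strict,
        )
        for core in cores
    ]
    cluster_df = pd.DataFrame(
        [
            {
                "core_id": c.core_id, "scaffold": c.scaffold,
                "span_start": c.span[0], "span_end": c.span[1],
                "n_members": len(c.members), "members": ",".join(c.members),
                "backbone_class": ev.classify_backbone(c),
            }
            for c in clusters
        ]
    )
    cluster_path = out / "clusters.tsv"
    cluster_df.to_csv(cluster_path, sep="\t", index=False)

    transcribed = {
        g.id: gm.is_transcribed(g, tracks[g.scaffold], min_depth, min_fraction, strict)
        for g in cores
    }
    methylated = {
        g.id: ev.promoter_methylated(g, macs[g.scaffold], mac_window_bp)
        if g.scaffold in macs
        else False
        for g in cores
    }
    detected = {g.id: peptide_counts.get(g.id, 0) >= min_peptides for g in cores}
    records, summary = ev.integrate_evidence(cores, transcribed, methylated, detected, strain_of)
    evidence_df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "transcribed": r.transcribed,
                "promoter_methylated": r.promoter_methylated,
                "protein_detected": r.protein_detected, "active_any": r.active_any,
            }
            for r in records
        ]
    )
    evidence_path = out / "evidence.tsv"
    evidence_df.to_csv(evidence_path, sep="\t", index=False)
    summary_path = out / "evidence_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6f")

    write_manifest(
        out, "bgc",
        {"max_gap_bp": max_gap_bp, "min_depth": min_depth, "min_fraction": min_fraction,
         "strict": strict, "mac_window_bp": mac_window_bp, "min_peptides": min_peptides},
        [ind / "genes.gff3", ind / "coverage.bedgraph", ind / "macs.bed",
         ind / "protein_detections.tsv", ind / "scaffold_lengths.tsv"],
        [cluster_path, evidence_path, summary_path],
    )
    return {"clusters": clusters, "records": records, "summary": summary}


# ------------------------------------------------------------ families


def run_families(indir: str | Path, outdir: str | Path, max_evalue: float = 1e-5) -> dict:
    """Homology wing: BBH pairing across genome pairs, family grouping,
    and top-hit taxonomy classification."""
    ind, out = Path(indir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome_map = pd.read_csv(ind / "genome_map.tsv", sep="\t")
    all_genes = [(r.genome, r.gene_id) for r in genome_map.itertuples(index=False)]
    genomes = sorted(genome_map["genome"].unique())

    pairs: list[fam.OrthoPair] = []
    inputs = [ind / "genome_map.tsv"]
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            pab, pba = ind / f"homology_{ga}_{gb}.tsv", ind / f"homology_{gb}_{ga}.tsv"
            if not (pab.exists() and pba.exists()):
                continue
            inputs += [pab, pba]
            pairs.extend(
                fam.bidirectional_best_hits(
                    fam.read_hit_table(str(pab), gb),
                    fam.read_hit_table(str(pba), ga),
                    max_evalue=max_evalue,
                )
            )
    families = fam.group_families(pairs, all_genes)
    fam_path = out / "families.tsv"
    pd.DataFrame(
        [
            {"family_id": f.family_id, "genome": genome, "gene_id": gene}
            for f in families
            for genome, gene in f.members
        ]
    ).to_csv(fam_path, sep="\t", index=False)

    tax_path = ind / "taxonomy_hits.tsv"
    outputs = [fam_path]
    fractions = None
    if tax_path.exists():
        hits = fam.read_hit_table(str(tax_path), "nr")
        cl = pd.read_csv(ind / "taxonomy_clusters.tsv", sep="\t")
        clusters = [
            (cid, sub["query_id"].tolist()) for cid, sub in cl.groupby("cluster_id")
        ]
        tally, fractions = fam.classify_top_hits(clusters, hits)
        tally_path = out / "taxonomy_tally.tsv"
        tally.to_csv(tally_path, sep="\t", index=False)
        frac_path = out / "kingdom_fractions.tsv"
        pd.DataFrame(
            sorted(fractions.items()), columns=["kingdom", "fraction"]
        ).to_csv(frac_path, sep="\t", index=False, float_format="%.6f")
        inputs += [tax_path, ind / "taxonomy_clusters.tsv"]
        outputs += [tally_path, frac_path]

    write_manifest(out, "families", {"max_evalue": max_evalue}, inputs, outputs)
    return {"families": families, "kingdom_fractions": fractions}


# ----------------------------------------------------------------- hgt


def run_hgt(
    indir: str | Path, outdir: str | Path, min_support: float = 70.0,
    support_scope: str = "whole_tree",
) -> dict:
    ind, out = Path(indir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    groups = pd.read_csv(ind / "tree_groups.tsv", sep="\t")
    group_of = dict(zip(groups["leaf"], groups["group"]))
    calls = []
    tree_paths = sorted((ind / "trees").glob("*.nwk"))
    for tp in tree_paths:
        tree = hg.read_tree(str(tp))
        calls.append(
            hg.classify_placement(tree, group_of, tree_id=tp.stem,
                                  min_support=min_support, support_scope=support_scope)
        )
    calls_path = out / "placements.tsv"
    pd.DataFrame(
        [
            {"tree_id": c.tree_id, "verdict": c.verdict, "group": c.group or "",
             "support_ok": c.support_ok}
            for c in calls
        ]
    ).to_csv(calls_path, sep="\t", index=False)
    summary = hg.summarize_placements(calls)
    summary_path = out / "placement_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6f")
    write_manifest(out, "hgt", {"min_support": min_support, "support_scope": support_scope},
                   tree_paths + [ind / "tree_groups.tsv"], [calls_path, summary_path])
    return {"calls": calls, "summary": summary}


# ------------------------------------------------------------- network


def run_network(
    indir: str | Path, outdir: str | Path,
    precursor_window: float = 17.0, top_peaks: int = 6, peak_half_window: float = 50.0,
    frag_tol: float = 0.5, parent_tol: float = 2.0, min_members: int = 2,
    min_score: float = 0.7, min_matched: int = 6, top_k: int = 10,
    min_ratio: float = 4.0, control: str = "control",
) -> dict:
    """Metabolomics wing in the workflow's order: precursor filter, windowed
    top-k filter, consensus clustering, network, library match, condition
    attribution; plus the fold-ratio feature filter."""
    ind, out = Path(indir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cond = pd.read_csv(ind / "spectrum_conditions.tsv", sep="\t")
    condition_of = {
        r.spectrum_id: (r.condition, r.sample) for r in cond.itertuples(index=False)
    }
    spectra = sn.read_mgf(str(ind / "spectra.mgf"), condition_of)
    spectra = [sn.preprocess(s, precursor_window, top_peaks, peak_half_window) for s in spectra]
    consensus = sn.cluster_spectra(spectra, frag_tol, parent_tol, min_members)
    graph = sn.build_network(consensus, frag_tol, min_score, min_matched, top_k)

    lib_path = ind / "library.mgf"
    annotations = {}
    if lib_path.exists():
        library = [sn.preprocess(s, precursor_window, top_peaks, peak_half_window)
                   for s in sn.read_mgf(str(lib_path))]
        annotations = sn.library_match(consensus, library, frag_tol, min_score, min_matched)
    sn.attribute_conditions(graph, consensus, {control})

    graph_path = out / "network.graphml"
    sn.write_graphml(graph, str(graph_path), annotations)
    members_path = out / "consensus_members.tsv"
    pd.DataFrame(
        [
            {"consensus_id": c.id, "member_id": m, "precursor_mz": round(c.precursor_mz, 5)}
            for c in consensus
            for m in c.member_ids
        ]
    ).to_csv(members_path, sep="\t", index=False)

    inputs = [ind / "spectra.mgf", ind / "spectrum_conditions.tsv"]
    outputs = [graph_path, members_path]
    retained = None
    feat_path = ind / "features.tsv"
    if feat_path.exists():
        features = sn.read_feature_table(str(feat_path))
        sample_conds = sorted(
            {c for f in features for c in f.intensities if c != control}
        )
        retained = [
            f
            for f in features
            if any(
                f in sn.condition_filter([f], sc, control, min_ratio)
                for sc in sample_conds
                if sc in f.intensities and control in f.intensities
            )
        ]
        feat_out = out / "retained_features.tsv"
        pd.DataFrame(
            [{"feature_id": f.feature_id, "mz": f.mz, "rt_min": f.rt_min} for f in retained]
        ).to_csv(feat_out, sep="\t", index=False)
        inputs.append(feat_path)
        outputs.append(feat_out)

    write_manifest(
        out, "network",
        {"precursor_window": precursor_window, "top_peaks": top_peaks,
         "peak_half_window": peak_half_window, "frag_tol": frag_tol,
         "parent_tol": parent_tol, "min_members": min_members, "min_score": min_score,
         "min_matched": min_matched, "top_k": top_k, "min_ratio": min_ratio},
        inputs, outputs,
    )
    return {"consensus": consensus, "graph": graph, "annotations": annotations,
            "retained_features": retained}


# ---------------------------------------------------------------- mass


def run_mass(formula: str, adduct: str, observed_mz: float, outdir: str | Path) -> mc.MassError:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    f = mc.parse_formula(formula)
    err = mc.mass_error(observed_mz, f, adduct)
    path = out / "mass_error.tsv"
    pd.DataFrame(
        [
            {
                "formula": str(f), "adduct": adduct,
                "observed_mz": observed_mz,
                "theoretical_mz": round(err.theoretical_mz, 5),
                "delta_mda": round(err.delta_mda, 3),
                "delta_ppm": round(err.delta_ppm, 3),
            }
        ]
    ).to_csv(path, sep="\t", index=False)
    write_manifest(out, "mass",
                   {"formula": formula, "adduct": adduct, "observed_mz": observed_mz},
                   [], [path])
    return err
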