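"""Cluster delineation and multi-omics activity calls on a small synthetic genome.

Generates a genome with planted clusters, realizes RNA-seq coverage and 6mA
MAC positions from the planted flags, then delineates each core gene's
cluster and integrates the evidence streams.
"""

from npomics import evidence as ev
from npomics import genome as gm
from npomics import synth

specs = [
    synth.ClusterSpec(n_members=4, core_methylated=True),
    synth.ClusterSpec(n_members=3, core_transcribed=False),
    synth.ClusterSpec(n_members=1),  # an isolated backbone gene
]
genes, truth = synth.gen_genome(seed=42, cluster_specs=specs)
tracks = {t.scaffold: t for t in synth.gen_coverage(genes, truth, seed=42)}
macs = synth.gen_macs(genes, truth, seed=42)

by_scaffold = {}
for g in genes:
    by_scaffold.setdefault(g.scaffold, []).append(g)

cores = [g for g in genes if g.is_core]
for core in cores:
    cluster = ev.delineate_cluster(core, by_scaffold[core.scaffold], tracks[core.scaffold])
    print(f"{core.id}: {ev.classify_backbone(cluster):>9}  members={cluster.members}")
# Each line is one core biosynthetic gene with the genes co-delineated into
# its cluster (transcribed neighbors within 10 kbp of each other).

transcribed = {g.id: gm.is_transcribed(g, tracks[g.scaffold]) for g in cores}
methylated = {g.id: ev.promoter_methylated(g, macs[g.scaffold]) for g in cores}
detected = {g.id: truth.detected[g.id] for g in cores}  # proteomics input flag
records, summary = ev.integrate_evidence(cores, transcribed, methylated, detected)
print()
print(summary.to_string(index=False))
# frac_active_any is the fraction of core genes supported by at least one of
# transcription, promoter methylation, or protein detection.
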