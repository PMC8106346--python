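"""Genomic data model: genes, per-base coverage tracks, 6mA MAC positions.

Coordinates are GFF3-style 1-based inclusive everywhere inside the package;
bedGraph/BED inputs (0-based half-open starts) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GffParseError(ValueError):
    """Malformed GFF3 input; message names the offending line."""


@dataclass(frozen=True, order=True)
class Gene:
    """An annotated single-interval gene model on a scaffold.

    ``is_core`` marks core (backbone) biosynthetic genes — the PKS/NRPS-type
    scaffold-building enzymes a cluster is seeded from. ``n_domains`` counts
    predicted catalytic domains (eligibility for the transcript-match filter
    requires >= 3); ``length_aa`` is the protein length in residues.
    """

    id: str = field(compare=False)
    scaffold: str
    start: int
    end: int
    strand: str = field(default="+", compare=False)
    is_core: bool = field(default=False, compare=False)
    n_domains: int = field(default=0, compare=False)
    length_aa: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.id}: end ({self.end}) < start ({self.start})"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.id}: start must be >= 1 (1-based)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.n_domains < 0:
            raise ValueError(f"gene {self.id}: n_domains must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        """Transcription start site: the 5' end on the gene's strand."""
        return self.start if self.strand == "+" else self.end


@dataclass
class CoverageTrack:
    """Per-base read depth for one scaffold, index 0 = base 1."""

    scaffold: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError(f"{self.scaffold}: negative depth")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class MacSet:
    """Sorted 1-based positions of dense methylated-adenine clusters (MACs)."""

    scaffold: str
    positions: list[int]

    def __post_init__(self) -> None:
        self.positions = sorted(self.positions)
        if self.positions and self.positions[0] < 1:
            raise ValueError("MAC positions are 1-based; got position < 1")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate MAC positions")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff(path: str) -> list[Gene]:
    """Read gene features from a GFF3 file.

    Only rows whose feature type is ``gene`` are returned, one :class:`Gene`
    each, sorted by (scaffold, start, id). Attributes ``core=true`` /
    ``n_domains=<int>`` / ``length_aa=<int>``, when present, populate the
    corresponding fields.
    """
    genes: list[Gene] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            scaffold, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            attrs = _parse_gff_attributes(attrs_s)
            if "ID" not in attrs:
                raise GffParseError(f"{path}: line {lineno}: gene without ID attribute")
            try:
                genes.append(
                    Gene(
                        id=attrs["ID"],
                        scaffold=scaffold,
                        start=start,
                        end=end,
                        strand=strand if strand in ("+", "-") else "+",
                        is_core=attrs.get("core", "").lower() == "true",
                        n_domains=int(attrs.get("n_domains", 0)),
                        length_aa=int(attrs["length_aa"]) if "length_aa" in attrs else None,
                    )
                )
            except ValueError as exc:
                raise GffParseError(f"{path}: line {lineno}: {exc}") from exc
    genes.sort(key=lambda g: (g.scaffold, g.start, g.id))
    return genes


def write_gff(genes: list[Gene], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.start, g.id)):
            attrs = f"ID={g.id}"
            if g.is_core:
                attrs += ";core=true"
            if g.n_domains:
                attrs += f";n_domains={g.n_domains}"
            if g.length_aa is not None:
                attrs += f";length_aa={g.length_aa}"
            handle.write(
                f"{g.scaffold}\tnpomics\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_bedgraph(path: str, scaffold_lengths: dict[str, int]) -> list[CoverageTrack]:
    """Read a bedGraph file into per-base coverage tracks.

    Intervals are 0-based half-open per the bedGraph standard; overlapping
    intervals sum. Every scaffold named in ``scaffold_lengths`` yields a
    track (all-zero if no record touches it).
    """
    depths = {s: np.zeros(n, dtype=np.int64) for s, n in scaffold_lengths.items()}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            scaffold, start, end, value = parts[0], int(parts[1]), int(parts[2]), int(float(parts[3]))
            if scaffold not in depths:
                raise ValueError(f"{path}: line {lineno}: unknown scaffold {scaffold!r}")
            if end > scaffold_lengths[scaffold]:
                raise ValueError(
                    f"{path}: line {lineno}: interval end {end} exceeds "
                    f"scaffold length {scaffold_lengths[scaffold]}"
                )
            depths[scaffold][start:end] += value
    return [CoverageTrack(s, depths[s]) for s in sorted(depths)]


def write_bedgraph(tracks: list[CoverageTrack], path: str) -> None:
    """Serialize tracks as bedGraph, run-length encoding constant stretches."""
    with open(path, "w") as handle:
        for track in sorted(tracks, key=lambda t: t.scaffold):
            d = track.depth
            if len(d) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(d)]))
            for s, e in zip(starts, ends):
                if d[s] != 0:
                    handle.write(f"{track.scaffold}\t{s}\t{e}\t{int(d[s])}\n")


def read_mac_bed(path: str) -> list[MacSet]:
    """Read MAC positions from BED (0-based start converted to 1-based)."""
    per_scaffold: dict[str, list[int]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            scaffold, start = parts[0], int(parts[1])
            per_scaffold.setdefault(scaffold, []).append(start + 1)
    return [MacSet(s, p) for s, p in sorted(per_scaffold.items())]


def gene_coverage_fraction(
    gene: Gene, track: CoverageTrack, min_depth: int = 5
) -> float:
    """Fraction of the gene's bases covered at >= ``min_depth``.

    Counts every base of the interval [start, end]; gene models here are
    single-interval, so no exon-aware handling is applied.
    """
    if gene.scaffold != track.scaffold:
        raise ValueError(
            f"gene {gene.id} on {gene.scaffold}, track is {track.scaffold}"
        )
    if gene.end > len(track):
        raise IndexError(
            f"gene {gene.id} [{gene.start},{gene.end}] exceeds track length {len(track)}"
        )
    window = track.depth[gene.start - 1 : gene.end]
    return float(np.count_nonzero(window >= min_depth)) / gene.length


def is_transcribed(
    gene: Gene,
    track: CoverageTrack,
    min_depth: int = 5,
    min_fraction: float = 0.95,
    strict: bool = True,
) -> bool:
    """Transcription call: >= 5x RNA-seq depth over more than 95% of the gene.

    ``strict`` selects ">" (the default, reading the threshold as "more than
    95%") versus ">=" ("at least 95%"); both phrasings occur in practice and
    the boundary is configurable for that reason.
    """
    frac = gene_coverage_fraction(gene, track, min_depth=min_depth)
    return frac > min_fraction if strict else frac >= min_fraction
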