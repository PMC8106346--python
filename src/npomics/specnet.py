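"""Molecular networking over MS/MS spectra, GNPS-style.

The wing mirrors the classic GNPS workflow: precursor-window and windowed
top-k noise filters, greedy consensus clustering under a parent-mass
tolerance, modified-cosine similarity (fragment matches allowed either
directly or shifted by the precursor mass difference, so structural analogs
link), network edges gated by score, matched-peak count and mutual top-k
rank, optional spectral-library annotation, and condition attribution of
nodes. Feature tables are filtered by sample/control fold ratio.

Similarity semantics follow the GNPS convention: intensities are
square-rooted, each spectrum is scaled to unit Euclidean norm, and matched
peak pairs are chosen greedily one-to-one by descending intensity product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor, retention time, peak list, provenance."""

    id: str
    precursor_mz: float
    charge: int
    rt_min: float
    peaks: list[tuple[float, float]]
    condition: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.id}: precursor_mz must be > 0")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"spectrum {self.id}: negative intensity")
        self.peaks = sorted(self.peaks)

    @property
    def total_intensity(self) -> float:
        return sum(i for _, i in self.peaks)


@dataclass
class ConsensusSpectrum:
    """Merged representative of clustered spectra of one putative ion."""

    id: str
    member_ids: list[str]
    precursor_mz: float
    peaks: list[tuple[float, float]]
    condition_set: frozenset[str] = field(default_factory=frozenset)

    @property
    def rank_intensity(self) -> float:
        return sum(i for _, i in self.peaks)


@dataclass
class Feature:
    """An LC-MS feature: m/z, retention time, intensity per condition."""

    feature_id: str
    mz: float
    rt_min: float
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError(f"feature {self.feature_id}: negative intensity")


# ---------------------------------------------------------------- I/O


def read_mgf(path: str, condition_of: dict[str, tuple[str, str]] | None = None) -> list[Spectrum]:
    """Read spectra from MGF; ``condition_of`` maps spectrum id -> (condition, sample)."""
    spectra = []
    with _mgf.MGF(path) as reader:
        for entry in reader:
            sid = entry["params"].get("title", f"scan_{len(spectra)}")
            cond, sample = (condition_of or {}).get(sid, ("", ""))
            charge = entry["params"].get("charge", [1])
            spectra.append(
                Spectrum(
                    id=sid,
                    precursor_mz=float(entry["params"]["pepmass"][0]),
                    charge=int(charge[0]),
                    rt_min=float(entry["params"].get("rtinseconds", 0.0)) / 60.0,
                    peaks=list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())),
                    condition=cond,
                    sample_id=sample,
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path: str) -> None:
    entries = [
        {
            "m/z array": np.array([m for m, _ in s.peaks]),
            "intensity array": np.array([i for _, i in s.peaks]),
            "params": {
                "title": s.id,
                "pepmass": s.precursor_mz,
                "charge": s.charge,
                "rtinseconds": round(s.rt_min * 60.0, 4),
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, output=path, file_mode="w")


def read_feature_table(path: str) -> list[Feature]:
    """Read a feature TSV: feature_id, mz, rt_min, then one intensity column per condition."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cond_cols = [c for c in df.columns if c not in ("feature_id", "mz", "rt_min")]
    return [
        Feature(
            feature_id=str(row["feature_id"]),
            mz=float(row["mz"]),
            rt_min=float(row["rt_min"]),
            intensities={c: float(row[c]) for c in cond_cols},
        )
        for _, row in df.iterrows()
    ]


# ------------------------------------------------------- preprocessing


def filter_precursor_window(s: Spectrum, window: float = 17.0) -> Spectrum:
    """Drop fragment peaks within +/- ``window`` Da of the precursor (inclusive)."""
    kept = [(m, i) for m, i in s.peaks if abs(m - s.precursor_mz) > window]
    return replace(s, peaks=kept)


def window_top_k(s: Spectrum, k: int = 6, half_window: float = 50.0) -> Spectrum:
    """Keep a peak iff it ranks in the top ``k`` by intensity within its own
    +/- ``half_window`` Da neighborhood; ties rank lower-m/z peaks first."""
    kept = []
    for mz, inten in s.peaks:
        neighborhood = [p for p in s.peaks if abs(p[0] - mz) <= half_window]
        neighborhood.sort(key=lambda p: (-p[1], p[0]))
        if (mz, inten) in neighborhood[:k]:
            kept.append((mz, inten))
    return replace(s, peaks=kept)


def preprocess(s: Spectrum, window: float = 17.0, k: int = 6, half_window: float = 50.0) -> Spectrum:
    return window_top_k(filter_precursor_window(s, window), k, half_window)


# ----------------------------------------------------- modified cosine


def _normalized(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
    weights = np.sqrt([i for _, i in peaks])
    norm = float(np.linalg.norm(weights))
    if norm == 0:
        return [(m, 0.0) for m, _ in peaks]
    return [(m, w / norm) for (m, _), w in zip(peaks, weights)]


def candidate_pairs(
    a: Spectrum | ConsensusSpectrum,
    b: Spectrum | ConsensusSpectrum,
    frag_tol: float = 0.5,
) -> list[tuple[int, int, float]]:
    """All (i, j, product) peak pairings allowed directly or precursor-shifted."""
    pa, pb = _normalized(a.peaks), _normalized(b.peaks)
    shift = b.precursor_mz - a.precursor_mz
    out = []
    for i, (ma, wa) in enumerate(pa):
        for j, (mb, wb) in enumerate(pb):
            d = mb - ma
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                out.append((i, j, wa * wb))
    return out


def modified_cosine(
    a: Spectrum | ConsensusSpectrum,
    b: Spectrum | ConsensusSpectrum,
    frag_tol: float = 0.5,
) -> tuple[float, int]:
    """Modified cosine score in [0, 1] and the number of matched peak pairs.

    Peaks match directly (|Δm/z| <= ``frag_tol``) or shifted by the precursor
    mass difference; the one-to-one matching is chosen greedily by descending
    product of the unit-normalized sqrt intensities.
    """
    if not a.peaks or not b.peaks:
        return 0.0, 0
    pairs = sorted(candidate_pairs(a, b, frag_tol), key=lambda t: (-t[2], t[0], t[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for i, j, prod in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += prod
        matched += 1
    return min(score, 1.0), matched


# ------------------------------------------------------- clustering


def _merge_peaks(
    members: list[Spectrum], frag_tol: float
) -> list[tuple[float, float]]:
    """Merge member peaks in frag_tol-wide m/z bins, summing intensities;
    each bin's m/z is the intensity-weighted mean of its peaks."""
    bins: dict[int, list[tuple[float, float]]] = {}
    for s in members:
        for mz, inten in s.peaks:
            bins.setdefault(int(mz // frag_tol), []).append((mz, inten))
    merged = []
    for _, peaks in sorted(bins.items()):
        total = sum(i for _, i in peaks)
        if total == 0:
            mz = float(np.mean([m for m, _ in peaks]))
        else:
            mz = sum(m * i for m, i in peaks) / total
        merged.append((mz, total))
    return merged


def cluster_spectra(
    spectra: list[Spectrum],
    frag_tol: float = 0.5,
    parent_tol: float = 2.0,
    min_members: int = 2,
    join_score: float = 0.7,
) -> list[ConsensusSpectrum]:
    """Greedy centroid clustering into consensus spectra.

    Spectra are processed in descending total-intensity order (ties by id);
    each joins the best-scoring existing consensus with |Δ precursor| <=
    ``parent_tol`` and modified cosine >= ``join_score``, else seeds a new
    one. Consensus spectra with fewer than ``min_members`` members are
    eliminated from the output.
    """
    order = sorted(spectra, key=lambda s: (-s.total_intensity, s.id))
    clusters: list[list[Spectrum]] = []
    consensi: list[ConsensusSpectrum] = []

    def rebuild(members: list[Spectrum], idx: int) -> ConsensusSpectrum:
        total = sum(m.total_intensity for m in members)
        if total > 0:
            prec = sum(m.precursor_mz * m.total_intensity for m in members) / total
        else:
            prec = float(np.mean([m.precursor_mz for m in members]))
        return ConsensusSpectrum(
            id=f"consensus_{idx}",
            member_ids=[m.id for m in members],
            precursor_mz=prec,
            peaks=_merge_peaks(members, frag_tol),
            condition_set=frozenset(m.condition for m in members if m.condition),
        )

    for s in order:
        best_idx, best_score = -1, -1.0
        for idx, cons in enumerate(consensi):
            if abs(s.precursor_mz - cons.precursor_mz) > parent_tol:
                continue
            score, _ = modified_cosine(s, cons, frag_tol)
            if score >= join_score and score > best_score:
                best_idx, best_score = idx, score
        if best_idx >= 0:
            clusters[best_idx].append(s)
            consensi[best_idx] = rebuild(clusters[best_idx], best_idx)
        else:
            clusters.append([s])
            consensi.append(rebuild([s], len(consensi)))

    return [c for c in consensi if len(c.member_ids) >= min_members]


# ------------------------------------------------------- networking


def build_network(
    consensus: list[ConsensusSpectrum],
    frag_tol: float = 0.5,
    min_score: float = 0.7,
    min_matched: int = 6,
    top_k: int = 10,
) -> nx.Graph:
    """Build the molecular network over consensus spectra.

    A candidate edge requires cosine > ``min_score`` and >= ``min_matched``
    matched peaks; it is retained only if each endpoint ranks within the
    other's ``top_k`` most cosine-similar nodes (ties broken toward the
    lower node id). Nodes carry precursor m/z and condition attributes.
    """
    graph = nx.Graph()
    for c in consensus:
        graph.add_node(
            c.id,
            precursor_mz=c.precursor_mz,
            n_members=len(c.member_ids),
            conditions=",".join(sorted(c.condition_set)),
        )
    sims: dict[tuple[str, str], tuple[float, int]] = {}
    for a, b in itertools.combinations(consensus, 2):
        score, matched = modified_cosine(a, b, frag_tol)
        sims[(a.id, b.id)] = (score, matched)

    neighbors: dict[str, list[tuple[float, str]]] = {c.id: [] for c in consensus}
    for (ida, idb), (score, _) in sims.items():
        neighbors[ida].append((score, idb))
        neighbors[idb].append((score, ida))
    top: dict[str, set[str]] = {}
    for node, scored in neighbors.items():
        scored.sort(key=lambda t: (-t[0], t[1]))
        top[node] = {other for _, other in scored[:top_k]}

    for (ida, idb), (score, matched) in sorted(sims.items()):
        if score > min_score and matched >= min_matched:
            if idb in top[ida] and ida in top[idb]:
                graph.add_edge(ida, idb, cosine=round(score, 6), matched_peaks=matched)
    return graph


def library_match(
    consensus: list[ConsensusSpectrum],
    library_spectra: list[Spectrum],
    frag_tol: float = 0.5,
    min_score: float = 0.7,
    min_matched: int = 6,
) -> dict[str, tuple[str, float]]:
    """Annotate each node with its best library spectrum passing both
    thresholds (score > ``min_score``, matched >= ``min_matched``), if any."""
    annotations: dict[str, tuple[str, float]] = {}
    for c in consensus:
        best: tuple[str, float] | None = None
        for lib in library_spectra:
            score, matched = modified_cosine(c, lib, frag_tol)
            if score > min_score and matched >= min_matched:
                if best is None or score > best[1]:
                    best = (lib.id, score)
        if best is not None:
            annotations[c.id] = best
    return annotations


def write_graphml(graph: nx.Graph, path: str, annotations: dict[str, tuple[str, float]] | None = None) -> None:
    if annotations:
        for node, (lib_id, score) in annotations.items():
            graph.nodes[node]["library_annotation"] = lib_id
            graph.nodes[node]["library_score"] = round(score, 6)
    nx.write_graphml(graph, path)


# ------------------------------------------- features and conditions


def condition_filter(
    features: list[Feature],
    sample_cond: str,
    control_cond: str,
    min_ratio: float = 4.0,
) -> list[Feature]:
    """Keep features at >= ``min_ratio``-fold intensity over the control.

    A zero-intensity control with a positive sample reads as an infinite
    ratio and is retained. ``min_ratio=10`` gives the stricter tenfold
    variant used for high-confidence compound calls.
    """
    kept = []
    for f in features:
        if sample_cond not in f.intensities or control_cond not in f.intensities:
            raise KeyError(
                f"feature {f.feature_id}: missing condition "
                f"{sample_cond!r} or {control_cond!r}"
            )
        sample, control = f.intensities[sample_cond], f.intensities[control_cond]
        if control == 0:
            if sample > 0:
                kept.append(f)
        elif sample / control >= min_ratio:
            kept.append(f)
    return kept


def attribute_conditions(
    graph: nx.Graph,
    consensus: list[ConsensusSpectrum],
    control_conditions: frozenset[str] | set[str] = frozenset({"control"}),
) -> dict[str, str]:
    """Label each node by where its member spectra were observed.

    Categories: ``<strain> only``, ``shared fungal: a+b``, ``control only``,
    and ``fungal supernatant and control``; written to the graph as the
    ``condition_label`` node attribute and returned as a mapping.
    """
    control_conditions = frozenset(control_conditions)
    labels: dict[str, str] = {}
    for c in consensus:
        if c.id not in graph:
            continue
        strains = sorted(c.condition_set - control_conditions)
        has_control = bool(c.condition_set & control_conditions)
        if strains and has_control:
            label = "fungal supernatant and control"
        elif not strains and has_control:
            label = "control only"
        elif len(strains) == 1:
            label = f"{strains[0]} only"
        elif len(strains) > 1:
            label = "shared fungal: " + "+".join(strains)
        else:
            label = "unassigned"
        labels[c.id] = label
        graph.nodes[c.id]["condition_label"] = label
    return labels
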