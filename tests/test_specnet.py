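"""Spectral preprocessing, modified cosine, clustering, networking, features."""

import numpy as np
import pytest

from npomics.specnet import (
    Feature,
    Spectrum,
    attribute_conditions,
    build_network,
    cluster_spectra,
    condition_filter,
    filter_precursor_window,
    library_match,
    modified_cosine,
    window_top_k,
)


def spec(sid, precursor, peaks, **kw):
    return Spectrum(sid, precursor, 1, 5.0, peaks, **kw)


def random_spectrum(rng, sid, n_peaks=None):
    n = n_peaks or int(rng.integers(3, 9))
    mz = np.sort(rng.uniform(100, 500, size=n))
    inten = rng.uniform(1, 100, size=n)
    return spec(sid, float(rng.uniform(400, 800)), list(zip(mz.tolist(), inten.tolist())))


def optimal_assignment_score(a, b, frag_tol=0.5):
    """Exhaustive optimal one-to-one matching via the Hungarian algorithm."""
    from scipy.optimize import linear_sum_assignment

    from npomics.specnet import candidate_pairs

    pairs = candidate_pairs(a, b, frag_tol)
    if not pairs:
        return 0.0
    n, m = len(a.peaks), len(b.peaks)
    weights = np.zeros((n, m))
    for i, j, prod in pairs:
        weights[i, j] = max(weights[i, j], prod)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return float(min(weights[rows, cols].sum(), 1.0))


class TestPreprocessing:
    def test_precursor_window_removes_near_peaks(self):
        s = spec("a", 500.0, [(490.0, 10.0), (520.0, 10.0)])
        out = filter_precursor_window(s)
        assert [m for m, _ in out.peaks] == [520.0]

    def test_precursor_window_boundary_inclusive(self):
        s = spec("a", 500.0, [(483.0, 10.0), (482.9, 10.0)])
        out = filter_precursor_window(s)
        assert [m for m, _ in out.peaks] == [482.9]  # exactly 17 Da removed

    def test_all_peaks_within_window_empties_spectrum(self):
        s = spec("a", 500.0, [(490.0, 1.0), (510.0, 2.0)])
        assert filter_precursor_window(s).peaks == []

    def test_top_k_few_peaks_unchanged(self):
        s = spec("a", 500.0, [(100.0, 1.0), (110.0, 2.0), (120.0, 3.0)])
        assert window_top_k(s).peaks == s.peaks

    def test_top_k_dense_window_keeps_most_intense(self):
        peaks = [(100.0 + 5 * i, float(i + 1)) for i in range(8)]
        out = window_top_k(spec("a", 500.0, peaks))
        kept = {m for m, _ in out.peaks}
        assert kept == {100.0 + 5 * i for i in range(2, 8)}  # 6 most intense

    def test_distant_regions_do_not_interact(self):
        region1 = [(100.0 + 2 * i, float(i + 1)) for i in range(6)]
        region2 = [(300.0 + 2 * i, float(i + 1)) for i in range(6)]
        out = window_top_k(spec("a", 500.0, region1 + region2))
        assert len(out.peaks) == 12


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        s = random_spectrum(rng, "a", 7)
        score, matched = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 7

    def test_global_shift_matches_through_precursor_delta(self):
        rng = np.random.default_rng(1)
        a = random_spectrum(rng, "a", 6)
        b = spec("b", a.precursor_mz + 14.0, [(m + 14.0, i) for m, i in a.peaks])
        score, matched = modified_cosine(a, b)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 6

    def test_disjoint_peaks_score_zero(self):
        a = spec("a", 500.0, [(100.0, 10.0), (200.0, 10.0)])
        b = spec("b", 500.0, [(150.0, 10.0), (250.7, 10.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_empty_spectrum(self):
        a = spec("a", 500.0, [])
        b = spec("b", 500.0, [(100.0, 1.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_symmetry_and_matched_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = random_spectrum(rng, "a"), random_spectrum(rng, "b")
            sab, mab = modified_cosine(a, b)
            sba, mba = modified_cosine(b, a)
            assert sab == pytest.approx(sba, abs=1e-9)
            assert mab == mba <= min(len(a.peaks), len(b.peaks))

    def test_removing_a_peak_never_increases_matches(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a, b = random_spectrum(rng, "a"), random_spectrum(rng, "b")
            _, matched = modified_cosine(a, b)
            for k in range(len(a.peaks)):
                thinned = spec("a2", a.precursor_mz, a.peaks[:k] + a.peaks[k + 1:])
                if not thinned.peaks:
                    continue
                _, m2 = modified_cosine(thinned, b)
                assert m2 <= matched

    def test_greedy_agrees_with_optimal_assignment(self):
        rng = np.random.default_rng(4)
        worst = 0.0
        for _ in range(300):
            a = random_spectrum(rng, "a", int(rng.integers(2, 9)))
            b = random_spectrum(rng, "b", int(rng.integers(2, 9)))
            greedy, _ = modified_cosine(a, b)
            worst = max(worst, abs(greedy - optimal_assignment_score(a, b)))
        assert worst <= 0.02

    def test_agrees_with_matchms_reference(self):
        """Independent cross-check against the matchms ModifiedCosine scorer.

        matchms weights raw intensities, so passing sqrt-scaled intensities
        reproduces this package's sqrt weighting.
        """
        import matchms
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(5)
        scorer = ModifiedCosine(tolerance=0.5)
        for _ in range(25):
            a, b = random_spectrum(rng, "a"), random_spectrum(rng, "b")
            ours, _ = modified_cosine(a, b)
            ma, mb = (
                matchms.Spectrum(
                    mz=np.array([m for m, _ in s.peaks]),
                    intensities=np.sqrt([i for _, i in s.peaks]),
                    metadata={"precursor_mz": s.precursor_mz},
                    metadata_harmonization=False,
                )
                for s in (a, b)
            )
            theirs = float(scorer.pair(ma, mb)["score"])
            assert ours == pytest.approx(theirs, abs=0.02)


class TestClustering:
    def test_identical_spectra_form_one_consensus(self):
        peaks = [(100.0, 10.0), (200.0, 20.0), (300.0, 30.0)]
        spectra = [spec(f"s{i}", 500.0, list(peaks)) for i in range(3)]
        (consensus,) = cluster_spectra(spectra)
        assert sorted(consensus.member_ids) == ["s0", "s1", "s2"]

    def test_singleton_eliminated(self):
        peaks = [(100.0, 10.0), (200.0, 20.0)]
        spectra = [spec("s0", 500.0, list(peaks)), spec("s1", 500.0, list(peaks)),
                   spec("odd", 700.0, [(350.0, 5.0)])]
        out = cluster_spectra(spectra)
        assert len(out) == 1 and "odd" not in out[0].member_ids

    def test_parent_tolerance_splits_distant_precursors(self):
        peaks = [(100.0, 10.0), (200.0, 20.0)]
        spectra = [spec("s0", 500.0, list(peaks)), spec("s1", 503.0, list(peaks))]
        assert cluster_spectra(spectra) == []  # two singleton clusters, both dropped

    def test_consensus_precursor_is_intensity_weighted(self):
        a = spec("a", 500.0, [(100.0, 30.0)])
        b = spec("b", 501.0, [(100.0, 10.0)])
        (consensus,) = cluster_spectra([a, b], join_score=0.0)
        assert consensus.precursor_mz == pytest.approx(500.25)

    def test_condition_set_is_union_of_members(self):
        peaks = [(100.0, 10.0), (200.0, 20.0)]
        spectra = [spec("s0", 500.0, list(peaks), condition="strainA"),
                   spec("s1", 500.0, list(peaks), condition="control")]
        (consensus,) = cluster_spectra(spectra)
        assert consensus.condition_set == {"strainA", "control"}


def family_consensus(n_nodes=3, offset=20.0, n_peaks=8, seed=0):
    """Consensus spectra forming one planted analog family."""
    from npomics.specnet import ConsensusSpectrum

    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(100, 400, n_peaks))
    while np.min(np.diff(base)) < 2:
        base = np.sort(rng.uniform(100, 400, n_peaks))
    inten = rng.uniform(10, 100, n_peaks)
    return [
        ConsensusSpectrum(
            f"node{k}", [f"m{k}a", f"m{k}b"], 500.0 + k * offset,
            [(float(m + k * offset), float(i)) for m, i in zip(base, inten)],
            frozenset({"strainA"}),
        )
        for k in range(n_nodes)
    ]


class TestNetwork:
    def test_family_fully_connected(self):
        graph = build_network(family_consensus())
        assert graph.number_of_edges() == 3
        for _, _, d in graph.edges(data=True):
            assert d["cosine"] > 0.7 and d["matched_peaks"] >= 6

    def test_low_score_pair_has_no_edge(self):
        rng = np.random.default_rng(7)
        nodes = family_consensus(2)
        from npomics.specnet import ConsensusSpectrum
        unrelated = ConsensusSpectrum(
            "odd", ["x", "y"], 611.3,
            [(float(m), 10.0) for m in np.arange(101.3, 401.0, 37.7)], frozenset()
        )
        graph = build_network(nodes + [unrelated])
        assert graph.degree("odd") == 0

    def test_matched_peak_floor(self):
        # only 5 shared peaks: similarity is high but the edge is refused
        from npomics.specnet import ConsensusSpectrum
        base = [(100.0 + 30 * i, 50.0) for i in range(5)]
        a = ConsensusSpectrum("a", ["1", "2"], 500.0, list(base), frozenset())
        b = ConsensusSpectrum("b", ["3", "4"], 500.0, list(base), frozenset())
        graph = build_network([a, b])
        score, matched = modified_cosine(a, b)
        assert score > 0.7 and matched == 5
        assert graph.number_of_edges() == 0

    def test_mutual_top_k_required(self):
        nodes = family_consensus(4, offset=15.0)
        full = build_network(nodes, top_k=10)
        starved = build_network(nodes, top_k=1)
        assert starved.number_of_edges() <= full.number_of_edges()
        for u, v in starved.edges():
            assert full.has_edge(u, v)


class TestLibraryMatch:
    def test_identical_library_spectrum_annotated(self):
        nodes = family_consensus(1)
        lib = spec("lib_compound", 500.0, list(nodes[0].peaks))
        ann = library_match(nodes, [lib])
        assert ann["node0"][0] == "lib_compound"
        assert ann["node0"][1] == pytest.approx(1.0, abs=1e-6)

    def test_five_matched_peaks_rejected(self):
        nodes = family_consensus(1, n_peaks=5)
        lib = spec("lib", 500.0, list(nodes[0].peaks))
        assert library_match(nodes, [lib]) == {}

    def test_empty_library_annotates_nothing(self):
        assert library_match(family_consensus(3), []) == {}


class TestConditionHandling:
    def test_fourfold_boundary(self):
        feats = [
            Feature("keep", 200.0, 1.0, {"s": 400.0, "c": 100.0}),
            Feature("drop", 201.0, 1.0, {"s": 390.0, "c": 100.0}),
        ]
        kept = condition_filter(feats, "s", "c")
        assert [f.feature_id for f in kept] == ["keep"]

    def test_zero_control_retained(self):
        feats = [Feature("f", 200.0, 1.0, {"s": 50.0, "c": 0.0})]
        assert condition_filter(feats, "s", "c") == feats

    def test_zero_sample_zero_control_dropped(self):
        feats = [Feature("f", 200.0, 1.0, {"s": 0.0, "c": 0.0})]
        assert condition_filter(feats, "s", "c") == []

    def test_tenfold_variant(self):
        feats = [Feature("f", 200.0, 1.0, {"s": 900.0, "c": 100.0})]
        assert condition_filter(feats, "s", "c", min_ratio=10.0) == []

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Feature("f", 200.0, 1.0, {"s": -1.0})

    def test_attribution_labels(self):
        import networkx as nx

        from npomics.specnet import ConsensusSpectrum

        nodes = [
            ConsensusSpectrum("a", ["1", "2"], 500.0, [(100.0, 1.0)],
                              frozenset({"strainX"})),
            ConsensusSpectrum("b", ["3", "4"], 510.0, [(100.0, 1.0)],
                              frozenset({"strainX", "control"})),
            ConsensusSpectrum("c", ["5", "6"], 520.0, [(100.0, 1.0)],
                              frozenset({"strainX", "strainY"})),
            ConsensusSpectrum("d", ["7", "8"], 530.0, [(100.0, 1.0)],
                              frozenset({"control"})),
        ]
        graph = nx.Graph()
        graph.add_nodes_from(n.id for n in nodes)
        labels = attribute_conditions(graph, nodes)
        assert labels == {
            "a": "strainX only",
            "b": "fungal supernatant and control",
            "c": "shared fungal: strainX+strainY",
            "d": "control only",
        }
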