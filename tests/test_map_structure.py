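import numpy as np
import pytest

from linkmap.map_structure import (
    DIFFERENT_NONHOMOEOLOGOUS,
    GENE_ISLAND,
    GENERIC,
    HOMOEOLOGOUS,
    RETRO_RICH,
    SAME_CHROMOSOME,
    analyze_duplication,
    bin_density,
    detect_clusters,
    detect_translocation_signals,
)
from linkmap.synthetic_data import generate_map

from conftest import make_map, small_config


class TestDensity:
    def test_boundary_locus_falls_in_last_bin(self):
        gmap = make_map(
            {"A1": [(f"m{i}", "gSSR", float(i)) for i in range(101)]}
        )
        profile = bin_density(gmap, width=10.0)[0]
        assert profile.counts == (10,) * 9 + (11,)  # 100.0 absorbed at the top

    def test_all_loci_at_origin(self):
        gmap = make_map({"A1": [(f"m{i}", "gSSR", 0.0) for i in range(7)]})
        assert bin_density(gmap)[0].counts == (7,)

    def test_counts_conserved_on_random_map(self):
        gmap, _ = generate_map(small_config(seed=5))
        for profile in bin_density(gmap):
            assert sum(profile.counts) == len(gmap[profile.group])

    def test_bad_width(self):
        gmap = make_map({"A1": [("m", "gSSR", 0.0)]})
        with pytest.raises(ValueError):
            bin_density(gmap, width=0.0)


def _cluster_map(entries, group="A5"):
    return make_map({group: entries})


class TestClusters:
    def test_six_essr_in_half_centimorgan_is_gene_island(self):
        # mirrors the 106.83-107.40 cM EST-SSR cluster example
        positions = [106.83, 106.95, 107.05, 107.17, 107.28, 107.40]
        gmap = _cluster_map(
            [(f"e{i}", "eSSR", p) for i, p in enumerate(positions)]
        )
        clusters = detect_clusters(gmap)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.kind == GENE_ISLAND
        assert c.n_loci == 6
        assert c.span == pytest.approx(0.57)

    def test_four_loci_below_threshold(self):
        gmap = _cluster_map([(f"m{i}", "gSSR", 0.1 * i) for i in range(4)])
        assert detect_clusters(gmap) == []

    def test_remap_majority_is_retro_rich(self):
        # 15 loci within 1 cM, 8 of them REMAP
        entries = [(f"r{i}", "REMAP", 50.0 + 0.06 * i) for i in range(8)]
        entries += [(f"g{i}", "gSSR", 50.5 + 0.06 * i) for i in range(7)]
        clusters = detect_clusters(_cluster_map(entries, group="D3"))
        assert len(clusters) == 1
        assert clusters[0].kind == RETRO_RICH
        assert clusters[0].n_loci == 15
        assert clusters[0].n_remap == 8

    def test_mixed_cluster_without_signature_is_generic(self):
        entries = [(f"m{i}", "gSSR", 10.0 + 0.1 * i) for i in range(5)]
        clusters = detect_clusters(_cluster_map(entries))
        assert [c.kind for c in clusters] == [GENERIC]

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = int(rng.integers(5, 50))
            positions = np.sort(rng.uniform(0, 12, n))
            gmap = _cluster_map(
                [(f"m{i}", "gSSR", float(p)) for i, p in enumerate(positions)]
            )
            got = [
                tuple(l.name for l in c.loci)
                for c in detect_clusters(gmap, min_loci=4, window=1.0)
            ]
            # oracle: every O(n^2) subrange with span<=w and size>=k,
            # then union of overlapping index ranges
            qualifying = [
                (i, j)
                for i in range(n)
                for j in range(i, n)
                if j - i + 1 >= 4 and positions[j] - positions[i] <= 1.0
            ]
            merged = []
            for i, j in sorted(qualifying):
                if merged and i <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], j)
                else:
                    merged.append([i, j])
            expected = [
                tuple(f"m{k}" for k in range(i, j + 1)) for i, j in merged
            ]
            assert got == expected, f"trial {trial}"

    def test_every_cluster_contains_a_qualifying_window(self):
        gmap, _ = generate_map(small_config(seed=9))
        for c in detect_clusters(gmap):
            positions = [l.position for l in c.loci]
            assert any(
                positions[j] - positions[i] <= 1.0
                for i in range(len(positions))
                for j in range(i + 4, len(positions))
            )


def _dup_map_from_groups(marker_groups):
    """Build a map + marker_to_loci where each marker maps one locus onto
    each listed group."""
    loci_by_group = {}
    mapping = {}
    for marker, groups in marker_groups.items():
        names = []
        for i, g in enumerate(groups):
            name = f"{marker}.{i}"
            loci_by_group.setdefault(g, []).append(
                (name, "gSSR", float(len(loci_by_group.get(g, []))))
            )
            names.append(name)
        mapping[marker] = names
    return make_map(loci_by_group), mapping


class TestDuplication:
    def test_printed_histogram_accounting(self):
        # 287 duplicated + 37 triplicated + 2 tetraplicated markers:
        # 181 homoeologous pairs, 106 non-homoeologous pairs, triplets
        # A_i/D_i/other, tetrads of two homoeologous pairs
        marker_groups = {}
        k = 0
        for _ in range(181):
            marker_groups[f"M{k}"] = ["A1", "D1"]
            k += 1
        for i in range(106):
            marker_groups[f"M{k}"] = ["A2", "D5"] if i % 2 else ["A3", "A7"]
            k += 1
        for _ in range(37):
            marker_groups[f"M{k}"] = ["A4", "D4", "D9"]
            k += 1
        for _ in range(2):
            marker_groups[f"M{k}"] = ["A6", "D6", "A8", "D8"]
            k += 1
        gmap, mapping = _dup_map_from_groups(marker_groups)
        dup = analyze_duplication(gmap, mapping)
        assert dup.multiplicity_histogram == {2: 287, 3: 37, 4: 2}
        assert dup.n_duplicated_markers == 326
        assert dup.n_duplicated_loci == 693
        counts = dup.class_counts()
        assert counts[HOMOEOLOGOUS] == 444  # 693 - 249 non-homoeologous
        assert dup.class_percent()[HOMOEOLOGOUS] == 64.07

    def test_same_chromosome_pair(self):
        gmap, mapping = _dup_map_from_groups({"M0": ["A1", "A1"]})
        dup = analyze_duplication(gmap, mapping)
        assert set(dup.locus_class.values()) == {SAME_CHROMOSOME}

    def test_class_partition_is_exhaustive(self):
        gmap, mapping = _dup_map_from_groups(
            {"M0": ["A1", "D1"], "M1": ["A2", "A2"], "M2": ["A3", "D9"]}
        )
        dup = analyze_duplication(gmap, mapping)
        counts = dup.class_counts()
        assert sum(counts.values()) == dup.n_duplicated_loci
        assert counts == {
            HOMOEOLOGOUS: 2, SAME_CHROMOSOME: 2, DIFFERENT_NONHOMOEOLOGOUS: 2,
        }
        assert sum(dup.class_percent().values()) == pytest.approx(100.0, abs=0.02)

    def test_singleton_markers_ignored(self):
        gmap, mapping = _dup_map_from_groups({"M0": ["A1"], "M1": ["A1", "D1"]})
        dup = analyze_duplication(gmap, mapping)
        assert dup.n_duplicated_markers == 1

    def test_unknown_locus_rejected(self):
        gmap, mapping = _dup_map_from_groups({"M0": ["A1", "D1"]})
        mapping["M0"].append("ghost")
        with pytest.raises(ValueError, match="unknown locus"):
            analyze_duplication(gmap, mapping)


class TestTranslocation:
    def test_reciprocal_pattern_counts(self):
        marker_groups = {}
        k = 0
        for combo, count in ((("A3", "D2"), 8), (("A2", "D3"), 7),
                             (("A5", "D4"), 9), (("A4", "D5"), 3)):
            for _ in range(count):
                marker_groups[f"T{k}"] = list(combo)
                k += 1
        gmap, mapping = _dup_map_from_groups(marker_groups)
        dup = analyze_duplication(gmap, mapping)
        signals = detect_translocation_signals(dup)
        by_pair = {s.pair: s for s in signals}
        assert by_pair[("A2", "A3")].n_supporting_loci == 15
        assert by_pair[("A4", "A5")].n_supporting_loci == 12
        assert sum(s.n_supporting_loci for s in signals) == 27

    def test_empty_table(self):
        gmap, mapping = _dup_map_from_groups({"M0": ["A1", "D1"]})
        dup = analyze_duplication(gmap, {})
        signals = detect_translocation_signals(dup)
        assert all(s.n_supporting_loci == 0 for s in signals)

    def test_pure_homoeologous_pairs_give_no_signal(self):
        marker_groups = {f"M{i}": [f"A{i + 1}", f"D{i + 1}"] for i in range(5)}
        gmap, mapping = _dup_map_from_groups(marker_groups)
        dup = analyze_duplication(gmap, mapping)
        assert all(
            s.n_supporting_loci == 0 for s in detect_translocation_signals(dup)
        )

    def test_unknown_candidate_group_rejected(self):
        gmap, mapping = _dup_map_from_groups({"M0": ["A1", "D1"]})
        dup = analyze_duplication(gmap, mapping)
        with pytest.raises(ValueError):
            detect_translocation_signals(dup, candidate_pairs=[("LG1", "A2")])
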