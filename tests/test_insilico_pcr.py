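import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from linkmap.insilico_pcr import (
    AnchorTable,
    PrimerPair,
    SeedIndex,
    TemplateSeq,
    anchor_pool,
    compare_product_sizes,
    find_amplicons,
    match_primer_sites,
    reverse_complement,
    seed_extend,
)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(seq, k, rng):
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out)


def naive_sites(primer, template, max_mismatch):
    """Independent full-scan oracle over every offset and both strands."""
    enc = {b: i for i, b in enumerate("ACGTN")}
    t = np.array([enc[b] for b in template], dtype=np.int64)
    sites = []
    for strand, seq in (("+", primer), ("-", reverse_complement(primer))):
        p = np.array([enc[b] for b in seq], dtype=np.int64)
        if len(p) > len(t):
            continue
        windows = sliding_window_view(t, len(p))
        mism = ((windows != p) | (windows == enc["N"])).sum(axis=1)
        for off in np.nonzero(mism <= max_mismatch)[0]:
            sites.append((int(off), strand, int(mism[off])))
    return sorted(sites)


class TestPrimerValidation:
    def test_empty_primer(self):
        with pytest.raises(ValueError, match="empty"):
            PrimerPair("m", "", "ACGT")

    def test_ambiguous_primer(self):
        with pytest.raises(ValueError, match="unambiguous"):
            PrimerPair("m", "ACGN", "ACGT")

    def test_invalid_template_base(self):
        with pytest.raises(ValueError, match="invalid base"):
            TemplateSeq("t", "ACGX")


class TestSiteSearch:
    def test_exact_site(self):
        sites = match_primer_sites("ACGTTACC", "TTACGTTACCTT", max_mismatch=0)
        assert sites == [(2, "+", 0)]

    def test_too_many_substitutions_rejected(self):
        template = "TTACGTACGTTT"
        primer = "TGTAACCT"  # 4 substitutions from the embedded ACGTACGT
        assert match_primer_sites(primer, template, max_mismatch=3) == []

    def test_template_n_counts_as_mismatch(self):
        assert match_primer_sites("ACGTACGT", "TTACGNACGTTT", max_mismatch=0) == []
        sites = match_primer_sites("ACGTACGT", "TTACGNACGTTT", max_mismatch=1)
        assert (2, "+", 1) in sites

    def test_minus_strand_site(self):
        primer = "AACCGGTTAC"
        template = "GG" + reverse_complement(primer) + "AA"
        assert match_primer_sites(primer, template, max_mismatch=0) == [(2, "-", 0)]

    def test_primer_shorter_than_segments_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            match_primer_sites("ACG", "ACGTACGTACGT", max_mismatch=3)

    def test_matches_naive_full_scan_on_random_pool(self):
        # 20 templates x 10 primers = 200 combinations; half the primers
        # are mutated template substrings so hits actually occur
        rng = np.random.default_rng(99)
        templates = [_random_seq(rng, 400) for _ in range(20)]
        primers = []
        for i in range(10):
            if i % 2 == 0:
                src = templates[int(rng.integers(0, len(templates)))]
                start = int(rng.integers(0, len(src) - 20))
                p = _mutate(src[start : start + 20], int(rng.integers(0, 5)), rng)
                if i % 4 == 0:
                    p = reverse_complement(p)
            else:
                p = _random_seq(rng, 20)
            primers.append(p)
        checked_hits = 0
        for t in templates:
            for p in primers:
                got = match_primer_sites(p, t, max_mismatch=3)
                assert got == naive_sites(p, t, 3)
                checked_hits += len(got)
        assert checked_hits > 0  # the fixture must exercise real hits


PAIR = PrimerPair("m1", "ACGTTGCAACGGTTAACCGG", "TTGGCCAATTGGTGCAACGT")


def _planted_template(insert="A" * 25):
    return TemplateSeq(
        "t1", PAIR.forward + insert + reverse_complement(PAIR.reverse)
    )


class TestAmplicons:
    def test_planted_perfect_product(self):
        hits = find_amplicons(PAIR, _planted_template())
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.product_size, h.strand) == (0, 65, 65, "+")
        assert (h.mismatches_forward, h.mismatches_reverse) == (0, 0)

    def test_strand_symmetry(self):
        t = _planted_template()
        rc = TemplateSeq("t1rc", reverse_complement(t.seq))
        hits = find_amplicons(PAIR, rc)
        assert len(hits) == 1
        assert hits[0].product_size == 65
        assert hits[0].strand == "-"

    def test_multiple_products_on_one_template(self):
        unit = PAIR.forward + "C" * 30 + reverse_complement(PAIR.reverse)
        t = TemplateSeq("t2", unit + "G" * 50 + unit)
        hits = find_amplicons(PAIR, t)
        assert len(hits) >= 2
        assert {h.product_size for h in hits} >= {70}

    def test_bad_product_bounds(self):
        with pytest.raises(ValueError):
            find_amplicons(PAIR, _planted_template(), min_product=100, max_product=50)

    def test_mismatch_monotonicity(self):
        rng = np.random.default_rng(5)
        t = TemplateSeq(
            "t3",
            _random_seq(rng, 60)
            + _mutate(PAIR.forward, 2, rng)
            + _random_seq(rng, 40)
            + reverse_complement(_mutate(PAIR.reverse, 1, rng))
            + _random_seq(rng, 60),
        )
        keys = lambda hits: {(h.start, h.end, h.strand) for h in hits}
        h2 = keys(find_amplicons(PAIR, t, max_mismatch=2))
        h3 = keys(find_amplicons(PAIR, t, max_mismatch=3))
        assert h2 <= h3
        wide = keys(find_amplicons(PAIR, t, min_product=40, max_product=5000))
        narrow = keys(find_amplicons(PAIR, t, min_product=90, max_product=120))
        assert narrow <= wide


class TestAnchorPool:
    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            anchor_pool([PAIR], [])

    def test_success_fraction_two_of_four(self):
        rng = np.random.default_rng(8)
        pairs = [
            PrimerPair(f"m{i}", _random_seq(rng, 20), _random_seq(rng, 20))
            for i in range(4)
        ]
        seq = ""
        for p in pairs[:2]:
            seq += p.forward + _random_seq(rng, 60) + reverse_complement(p.reverse)
            seq += _random_seq(rng, 30)
        table = anchor_pool(pairs, [TemplateSeq("t", seq)])
        summary = table.summary()
        assert summary["n_with_hits"] == 2
        assert summary["success_pct"] == 50.0

    def test_decomposes_into_per_pair_scans(self):
        rng = np.random.default_rng(21)
        pairs = [
            PrimerPair(f"m{i}", _random_seq(rng, 18), _random_seq(rng, 18))
            for i in range(6)
        ]
        pool = []
        for i, p in enumerate(pairs[:4]):
            seq = (
                _random_seq(rng, 50)
                + _mutate(p.forward, i % 3, rng)
                + _random_seq(rng, 80)
                + reverse_complement(p.reverse)
                + _random_seq(rng, 50)
            )
            pool.append(TemplateSeq(f"t{i}", seq, species="Gh"))
        pool.append(TemplateSeq("decoy", _random_seq(rng, 300), species="Gr"))
        table = anchor_pool(pairs, pool)
        expected = []
        for t in pool:
            for p in pairs:
                expected.extend(find_amplicons(p, t))
        key = lambda h: (h.marker, h.template_id, h.start, h.end, h.strand,
                         h.mismatches_forward, h.mismatches_reverse)
        assert sorted(map(key, table.hits)) == sorted(map(key, expected))


class TestProductSizes:
    def test_same_and_different_sizes(self):
        from linkmap.insilico_pcr import AmpliconHit

        def hit(marker, template, species, size):
            return AmpliconHit(marker, template, species, "EST", "+", 0, size, 0, 0)

        table = AnchorTable(
            [
                hit("m1", "e1", "Gh", 180), hit("m1", "e2", "Gr", 180),
                hit("m2", "e3", "Gh", 180), hit("m2", "e4", "Gr", 186),
                hit("m3", "e5", "Gh", 150),  # single species: unclassified
            ],
            ["m1", "m2", "m3"],
        )
        report = compare_product_sizes(table)
        assert report["classes"] == {"m1": "same_size", "m2": "different_size"}
        assert report["counts"] == {"same_size": 1, "different_size": 1}


class TestSeedExtend:
    def test_shared_block_found_with_full_identity(self):
        rng = np.random.default_rng(1)
        block = _random_seq(rng, 40)
        q = _random_seq(rng, 50) + block + _random_seq(rng, 50)
        t = _random_seq(rng, 70) + block + _random_seq(rng, 30)
        matches = seed_extend(q, t)
        assert matches
        top = matches[0]
        assert top.score >= 40
        assert top.query_start <= 50 and top.query_end >= 90
        assert top.identity >= 0.95

    def test_no_shared_kmer_is_empty(self):
        q = "A" * 30
        t = "C" * 300
        assert seed_extend(q, t) == []

    def test_small_word_size_rejected(self):
        with pytest.raises(ValueError):
            seed_extend("ACGTACGTACGT", "ACGTACGTACGT", k=3)

    def test_minus_strand_block(self):
        rng = np.random.default_rng(4)
        block = _random_seq(rng, 36)
        q = _random_seq(rng, 20) + block + _random_seq(rng, 20)
        t = _random_seq(rng, 40) + reverse_complement(block) + _random_seq(rng, 40)
        matches = seed_extend(q, t)
        assert matches and matches[0].strand == "-"
        m = matches[0]
        aligned = reverse_complement(t[m.template_start : m.template_end])
        observed = sum(
            a == b for a, b in zip(q[m.query_start : m.query_end], aligned)
        ) / (m.query_end - m.query_start)
        assert observed == pytest.approx(m.identity)

    def test_maxima_match_exhaustive_diagonal_scan(self):
        # 100 random pairs with one planted exact block each; with an
        # unbounded X-drop, the extension from any seed inside the best
        # window reaches exactly the per-diagonal best-window optimum
        rng = np.random.default_rng(123)
        for trial in range(100):
            block = _random_seq(rng, int(rng.integers(32, 64)))
            q = _random_seq(rng, 60) + block + _random_seq(rng, 60)
            t = _random_seq(rng, 80) + block + _random_seq(rng, 40)
            matches = seed_extend(q, t, k=12, xdrop=10**9, min_score=30)
            got = max(m.score for m in matches)
            assert got == _best_diagonal_score(q, t), f"trial {trial}"


def _best_diagonal_score(q, t, match=1, mismatch=-2):
    """Kadane best-window score over every diagonal of both strands."""
    best = 0
    for ts in (t, reverse_complement(t)):
        for d in range(-len(q) + 1, len(ts)):
            run = 0
            for i in range(len(q)):
                j = i + d
                if j < 0 or j >= len(ts):
                    continue
                run = max(0, run + (match if q[i] == ts[j] else mismatch))
                best = max(best, run)
    return best
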