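"""In silico PCR: mismatch-bounded primer-site search and product prediction.

The screen mimics a specific PCR reaction computationally.  A primer pair
amplifies a template wherever the forward and reverse primers bind on
opposite strands in convergent orientation (the FR match pattern) with at
most ``max_mismatch`` substitutions each, and the implied product length
falls inside configured bounds.  Mismatches are substitutions only — no
indels inside a primer site — which keeps the matching model exact Hamming
distance and makes the search amenable to the classic pigeonhole trick:

    split a primer into (max_mismatch + 1) contiguous segments; a site
    with <= max_mismatch substitutions must match at least one segment
    *exactly*, so exact lookups of every segment in a k-mer index of the
    template pool enumerate a complete candidate set, and a full Hamming
    comparison then verifies each candidate.

Template ``N`` bases never match a primer base (they count as mismatches);
primers themselves must be unambiguous A/C/G/T.

For anchoring markers to long genomic templates (BACs) by their source
sequences rather than primers, :func:`seed_extend` provides hash-seeded
ungapped alignment: exact k-mer seeds shared by query and template are
extended in both directions until the running score drops more than
``xdrop`` below the running maximum (X-drop termination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .map_model import round_half_away

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("N")] = 4
_ENC[ord("n")] = 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str, what: str = "sequence") -> np.ndarray:
    codes = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"{what} contains invalid base {bad!r}")
    return codes


@dataclass(frozen=True)
class PrimerPair:
    """A marker's forward/reverse primer sequences (unambiguous A/C/G/T)."""

    marker: str
    forward: str
    reverse: str

    def __post_init__(self):
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{label} primer of {self.marker!r} is empty")
            codes = _encode(seq, f"{label} primer of {self.marker!r}")
            if (codes > 3).any():
                raise ValueError(
                    f"{label} primer of {self.marker!r} must be unambiguous A/C/G/T"
                )


@dataclass(frozen=True)
class TemplateSeq:
    """A pool sequence: an EST read or a BAC insert, tagged with species."""

    id: str
    seq: str
    species: str = ""
    kind: str = "EST"

    def __post_init__(self):
        if self.kind not in ("EST", "BAC"):
            raise ValueError(f"template kind must be EST or BAC, got {self.kind!r}")
        _encode(self.seq, f"template {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product on a template, in plus-strand coordinates.

    ``start``/``end`` are 0-based half-open and include both primer sites;
    ``strand`` is the strand the *forward* primer binds.
    """

    marker: str
    template_id: str
    species: str
    kind: str
    strand: str
    start: int
    end: int
    mismatches_forward: int
    mismatches_reverse: int

    @property
    def product_size(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Seed index and pigeonhole search
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact-lookup k-mer index over a template pool.

    Templates are concatenated into one code array; per word length k a
    sorted table of integer k-mer codes is built lazily (words containing
    N or straddling a template boundary are excluded).  Lookups are binary
    searches returning global start offsets.
    """

    MAX_WORD = 31  # 4**31 < 2**63, keeps integer codes in int64

    def __init__(self, templates: Sequence[TemplateSeq]):
        templates = list(templates)
        if not templates:
            raise ValueError("empty template pool")
        self.templates = templates
        lens = np.array([len(t) for t in templates], dtype=np.int64)
        self.starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
        self.codes = np.concatenate([_encode(t.seq) for t in templates])
        self.tid = np.repeat(np.arange(len(templates)), lens)
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.templates)

    def _table(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if k in self._tables:
            return self._tables[k]
        if not (1 <= k <= self.MAX_WORD):
            raise ValueError(f"word length {k} outside [1, {self.MAX_WORD}]")
        n = len(self.codes)
        if n < k:
            table = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            self._tables[k] = table
            return table
        m = n - k + 1
        kmers = np.zeros(m, dtype=np.int64)
        has_n = np.zeros(m, dtype=bool)
        for j in range(k):  # Horner accumulation, k short vector passes
            col = self.codes[j : j + m]
            kmers = kmers * 4 + np.where(col > 3, 0, col).astype(np.int64)
            has_n |= col > 3
        valid = ~has_n & (self.tid[:m] == self.tid[k - 1 : k - 1 + m])
        pos = np.nonzero(valid)[0].astype(np.int64)
        codes = kmers[pos]
        order = np.argsort(codes, kind="stable")
        table = (codes[order], pos[order])
        self._tables[k] = table
        return table

    def lookup_codes(self, seg: np.ndarray) -> np.ndarray:
        """Global start offsets of exact occurrences of an encoded word."""
        k = len(seg)
        if (seg > 3).any():
            return np.empty(0, dtype=np.int64)
        code = 0
        for c in seg:
            code = code * 4 + int(c)
        sorted_codes, pos = self._table(k)
        lo = np.searchsorted(sorted_codes, code, side="left")
        hi = np.searchsorted(sorted_codes, code, side="right")
        return pos[lo:hi]

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global offsets to (template index, local offset)."""
        tids = self.tid[gpos]
        return tids, gpos - self.starts[tids]


def _pigeonhole_segments(m: int, n_segments: int) -> list[tuple[int, int]]:
    """Split [0, m) into n contiguous segments with near-equal lengths."""
    base, rem = divmod(m, n_segments)
    bounds, start = [], 0
    for i in range(n_segments):
        length = base + (1 if i < rem else 0)
        bounds.append((start, start + length))
        start += length
    return bounds


def _match_sites_global(
    index: SeedIndex, codes: np.ndarray, max_mismatch: int
) -> tuple[np.ndarray, np.ndarray]:
    """All global offsets where ``codes`` matches the pool with Hamming
    distance <= max_mismatch; returns (offsets, mismatch counts)."""
    m = len(codes)
    n_segments = max_mismatch + 1
    if m < n_segments:
        raise ValueError(
            f"primer of length {m} too short for {max_mismatch} mismatches "
            f"(needs >= {n_segments} bases)"
        )
    cands = []
    for st, en in _pigeonhole_segments(m, n_segments):
        seg_len = en - st
        if seg_len > SeedIndex.MAX_WORD:
            # long segment with few allowed mismatches: split further, the
            # pigeonhole bound still holds for any refinement
            for st2, en2 in _pigeonhole_segments(seg_len, -(-seg_len // SeedIndex.MAX_WORD)):
                cands.append(index.lookup_codes(codes[st + st2 : st + en2]) - (st + st2))
        else:
            cands.append(index.lookup_codes(codes[st:en]) - st)
    cand = np.unique(np.concatenate(cands)) if cands else np.empty(0, dtype=np.int64)
    n = len(index.codes)
    cand = cand[(cand >= 0) & (cand + m <= n)]
    if cand.size == 0:
        return cand, cand
    cand = cand[index.tid[cand] == index.tid[cand + m - 1]]
    if cand.size == 0:
        return cand, cand
    window = index.codes[cand[:, None] + np.arange(m)]
    mism = (window != codes).sum(axis=1)
    keep = mism <= max_mismatch
    return cand[keep], mism[keep].astype(np.int64)


def _sites_by_template(
    index: SeedIndex, seq: str, max_mismatch: int
) -> dict[int, list[tuple[int, int]]]:
    """Per-template-index lists of (local offset, mismatches) for ``seq``
    matched on the plus strand of the pool."""
    gpos, mism = _match_sites_global(index, _encode(seq, "primer"), max_mismatch)
    out: dict[int, list[tuple[int, int]]] = {}
    if gpos.size:
        tids, offs = index.locate(gpos)
        for t, o, mm in zip(tids.tolist(), offs.tolist(), mism.tolist()):
            out.setdefault(t, []).append((o, mm))
    return out


def match_primer_sites(
    primer: str,
    template: Union[TemplateSeq, str],
    max_mismatch: int = 3,
    index: Optional[SeedIndex] = None,
) -> list[tuple[int, str, int]]:
    """All binding sites of a primer on both strands of one template.

    Returns (offset, strand, mismatches) triples sorted by offset; the
    offset is the site's leftmost plus-strand coordinate regardless of
    strand.  Complete by the pigeonhole argument: with <= max_mismatch
    substitutions at least one of the max_mismatch+1 primer segments
    matches exactly and seeds the candidate.
    """
    if isinstance(template, str):
        template = TemplateSeq("template", template)
    if index is None:
        index = SeedIndex([template])
        t_idx = 0
    else:
        t_idx = next(
            i for i, t in enumerate(index.templates) if t.id == template.id
        )
    sites = []
    for strand, seq in (("+", primer), ("-", reverse_complement(primer))):
        _encode(seq, "primer")
        for off, mm in _sites_by_template(index, seq, max_mismatch).get(t_idx, []):
            sites.append((off, strand, mm))
    return sorted(sites)


# ---------------------------------------------------------------------------
# Amplicon prediction
# ---------------------------------------------------------------------------

def _combine_orientation(
    left_sites: list[tuple[int, int]],
    right_sites: list[tuple[int, int]],
    left_len: int,
    right_len: int,
    min_product: int,
    max_product: int,
) -> list[tuple[int, int, int, int]]:
    """Convergent placements: a left-primer site at a, a right-site
    (reverse-complemented primer) at b >= a; product is [a, b + right_len).
    Returns (start, end, mm_left, mm_right)."""
    out = []
    for a, mm_l in left_sites:
        for b, mm_r in right_sites:
            if b < a:
                continue
            end = b + right_len
            size = end - a
            if size < max(left_len, right_len):
                continue  # primers not convergent around a real insert
            if min_product <= size <= max_product:
                out.append((a, end, mm_l, mm_r))
    return out


def find_amplicons(
    pair: PrimerPair,
    template: TemplateSeq,
    max_mismatch: int = 3,
    min_product: int = 40,
    max_product: int = 5000,
    index: Optional[SeedIndex] = None,
) -> list[AmpliconHit]:
    """Predict all products of one primer pair on one template.

    Both forward orientations are searched: forward primer on the plus
    strand with the reverse primer downstream on the minus strand, and the
    mirror arrangement.  Hits are deduplicated on (start, end, strand),
    keeping the fewest total mismatches, and sorted by position.
    """
    if min_product > max_product:
        raise ValueError("min_product exceeds max_product")
    own_index = index is None
    if own_index:
        index = SeedIndex([template])
        t_idx = 0
    else:
        t_idx = next(i for i, t in enumerate(index.templates) if t.id == template.id)

    def sites(seq: str) -> list[tuple[int, int]]:
        return _sites_by_template(index, seq, max_mismatch).get(t_idx, [])

    f_len, r_len = len(pair.forward), len(pair.reverse)
    hits: dict[tuple[int, int, str], AmpliconHit] = {}
    # forward on plus strand, reverse annealing on minus strand downstream
    for a, end, mm_f, mm_r in _combine_orientation(
        sites(pair.forward), sites(reverse_complement(pair.reverse)),
        f_len, r_len, min_product, max_product,
    ):
        key = (a, end, "+")
        h = AmpliconHit(pair.marker, template.id, template.species, template.kind,
                        "+", a, end, mm_f, mm_r)
        old = hits.get(key)
        if old is None or mm_f + mm_r < old.mismatches_forward + old.mismatches_reverse:
            hits[key] = h
    # forward on minus strand: reverse primer sits on plus strand upstream
    for a, end, mm_r, mm_f in _combine_orientation(
        sites(pair.reverse), sites(reverse_complement(pair.forward)),
        r_len, f_len, min_product, max_product,
    ):
        key = (a, end, "-")
        h = AmpliconHit(pair.marker, template.id, template.species, template.kind,
                        "-", a, end, mm_f, mm_r)
        old = hits.get(key)
        if old is None or mm_f + mm_r < old.mismatches_forward + old.mismatches_reverse:
            hits[key] = h
    return sorted(hits.values(), key=lambda h: (h.start, h.end, h.strand))


# ---------------------------------------------------------------------------
# Pool-level anchoring
# ---------------------------------------------------------------------------

@dataclass
class AnchorTable:
    """All amplicon hits of a marker set against a template pool."""

    hits: list[AmpliconHit]
    markers: list[str]  # every marker screened, hit or not

    def hits_by_marker(self) -> dict[str, list[AmpliconHit]]:
        out: dict[str, list[AmpliconHit]] = {m: [] for m in self.markers}
        for h in self.hits:
            out[h.marker].append(h)
        return out

    def summary(self) -> dict:
        by_marker = self.hits_by_marker()
        with_hits = [m for m, hs in by_marker.items() if hs]
        ests = {h.template_id for h in self.hits if h.kind == "EST"}
        bacs = {h.template_id for h in self.hits if h.kind == "BAC"}
        n = len(self.markers)
        return {
            "n_markers": n,
            "n_with_hits": len(with_hits),
            "n_without_hits": n - len(with_hits),
            "n_est_templates_hit": len(ests),
            "n_bac_templates_hit": len(bacs),
            "success_pct": round_half_away(100.0 * len(with_hits) / n, 1) if n else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (h.marker, h.template_id, h.species, h.kind, h.strand,
                 h.start, h.end, h.product_size,
                 h.mismatches_forward, h.mismatches_reverse)
                for h in self.hits
            ],
            columns=["marker", "template", "species", "kind", "strand",
                     "start", "end", "product_size", "mm_forward", "mm_reverse"],
        )


def anchor_pool(
    pairs: Sequence[PrimerPair],
    pool: Sequence[TemplateSeq],
    max_mismatch: int = 3,
    min_product: int = 40,
    max_product: int = 5000,
    max_product_bac: int = 20000,
) -> AnchorTable:
    """Screen every primer pair against every pool template.

    One :class:`SeedIndex` is shared across markers; EST and BAC templates
    use separate product-size ceilings (a BAC insert can legitimately host
    a product far larger than any EST read).
    """
    if not pool:
        raise ValueError("empty template pool")
    index = SeedIndex(pool)
    is_bac = [t.kind == "BAC" for t in pool]
    all_hits: list[AmpliconHit] = []
    for pair in pairs:
        f_len, r_len = len(pair.forward), len(pair.reverse)
        site_maps = {
            "f+": _sites_by_template(index, pair.forward, max_mismatch),
            "r-": _sites_by_template(index, reverse_complement(pair.reverse), max_mismatch),
            "r+": _sites_by_template(index, pair.reverse, max_mismatch),
            "f-": _sites_by_template(index, reverse_complement(pair.forward), max_mismatch),
        }
        touched = set().union(*(m.keys() for m in site_maps.values()))
        for t_idx in sorted(touched):
            t = pool[t_idx]
            cap = max_product_bac if is_bac[t_idx] else max_product
            dedup: dict[tuple[int, int, str], AmpliconHit] = {}
            for a, end, mm_f, mm_r in _combine_orientation(
                site_maps["f+"].get(t_idx, []), site_maps["r-"].get(t_idx, []),
                f_len, r_len, min_product, cap,
            ):
                key = (a, end, "+")
                h = AmpliconHit(pair.marker, t.id, t.species, t.kind, "+", a, end, mm_f, mm_r)
                old = dedup.get(key)
                if old is None or mm_f + mm_r < old.mismatches_forward + old.mismatches_reverse:
                    dedup[key] = h
            for a, end, mm_r, mm_f in _combine_orientation(
                site_maps["r+"].get(t_idx, []), site_maps["f-"].get(t_idx, []),
                r_len, f_len, min_product, cap,
            ):
                key = (a, end, "-")
                h = AmpliconHit(pair.marker, t.id, t.species, t.kind, "-", a, end, mm_f, mm_r)
                old = dedup.get(key)
                if old is None or mm_f + mm_r < old.mismatches_forward + old.mismatches_reverse:
                    dedup[key] = h
            all_hits.extend(sorted(dedup.values(), key=lambda h: (h.start, h.end, h.strand)))
    return AnchorTable(all_hits, [p.marker for p in pairs])


SAME_SIZE = "same_size"
DIFFERENT_SIZE = "different_size"


def compare_product_sizes(table: AnchorTable) -> dict:
    """Classify multi-species markers by cross-species product-size equality.

    A marker anchored in >=2 species is ``same_size`` when every predicted
    product across all its hits has the identical length in bp, otherwise
    ``different_size``; single-species markers are left unclassified.
    """
    classes: dict[str, str] = {}
    for marker, hs in table.hits_by_marker().items():
        species = {h.species for h in hs}
        if len(species) < 2:
            continue
        sizes = {h.product_size for h in hs}
        classes[marker] = SAME_SIZE if len(sizes) == 1 else DIFFERENT_SIZE
    counts = {
        SAME_SIZE: sum(c == SAME_SIZE for c in classes.values()),
        DIFFERENT_SIZE: sum(c == DIFFERENT_SIZE for c in classes.values()),
    }
    return {"classes": classes, "counts": counts}


# ---------------------------------------------------------------------------
# Seed-and-extend (hash search with X-drop extension)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtendedMatch:
    """An ungapped local match found by seeded X-drop extension.

    Query and template intervals have equal length; template coordinates
    are on the plus strand regardless of the matched strand.
    """

    query_start: int
    query_end: int
    template_start: int
    template_end: int
    strand: str
    score: int
    identity: float


def _xdrop_extend(qc, tc, qpos, tpos, k, match, mismatch, xdrop):
    """Extend an exact seed [qpos, qpos+k) x [tpos, tpos+k) both ways.

    Returns (qstart, qend, tstart, tend, score) of the best-scoring
    interval reachable without the running score falling more than xdrop
    below its running maximum."""
    score = k * match
    # rightward
    best_gain, gain = 0, 0
    i, j = qpos + k, tpos + k
    right = 0
    while i < len(qc) and j < len(tc):
        gain += match if (qc[i] == tc[j] and qc[i] < 4) else mismatch
        i += 1
        j += 1
        if gain > best_gain:
            best_gain, right = gain, i - (qpos + k)
        elif best_gain - gain > xdrop:
            break
    score += best_gain
    # leftward
    best_gain, gain = 0, 0
    i, j = qpos - 1, tpos - 1
    left = 0
    while i >= 0 and j >= 0:
        gain += match if (qc[i] == tc[j] and qc[i] < 4) else mismatch
        if gain > best_gain:
            best_gain, left = gain, qpos - i
        elif best_gain - gain > xdrop:
            break
        i -= 1
        j -= 1
    score += best_gain
    return qpos - left, qpos + k + right, tpos - left, tpos + k + right, score


def seed_extend(
    query: str,
    template: Union[TemplateSeq, str],
    k: int = 12,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 12,
    min_score: int = 30,
) -> list[ExtendedMatch]:
    """Find ungapped local matches of a query against both template strands.

    Every exact k-mer shared by query and template seeds an extension;
    extensions on the same diagonal landing on overlapping query intervals
    are merged (the higher score wins).  Matches scoring below
    ``min_score`` are dropped.
    """
    if k < 4:
        raise ValueError("word size k must be >= 4")
    if isinstance(template, str):
        template = TemplateSeq("template", template)
    qc = _encode(query, "query")
    if len(qc) < k:
        raise ValueError("query shorter than word size")
    t_len = len(template)
    # index query k-mers by integer code
    qmers: dict[int, list[int]] = {}
    code, valid = 0, 0
    mask = 4 ** (k - 1)
    for i, c in enumerate(qc):
        if c > 3:
            valid = 0
            code = 0
            continue
        code = (code % mask) * 4 + int(c)
        valid += 1
        if valid >= k:
            qmers.setdefault(code, []).append(i - k + 1)
    results: list[ExtendedMatch] = []
    for strand in ("+", "-"):
        tseq = template.seq if strand == "+" else reverse_complement(template.seq)
        tc = _encode(tseq)
        per_diag: dict[int, list[tuple[int, int, int, int, int]]] = {}
        code, valid = 0, 0
        for j, c in enumerate(tc):
            if c > 3:
                valid = 0
                code = 0
                continue
            code = (code % mask) * 4 + int(c)
            valid += 1
            if valid < k:
                continue
            tpos = j - k + 1
            for qpos in qmers.get(code, ()):
                d = tpos - qpos
                spans = per_diag.get(d, [])
                if any(qs <= qpos and qpos + k <= qe for qs, qe, *_ in spans):
                    continue  # seed already inside an extended interval
                qs, qe, ts, te, score = _xdrop_extend(
                    qc, tc, qpos, tpos, k, match, mismatch, xdrop
                )
                spans.append((qs, qe, ts, te, score))
                per_diag[d] = spans
        for d, spans in per_diag.items():
            # merge overlapping intervals on a diagonal, keep best score
            spans.sort()
            kept: list[tuple[int, int, int, int, int]] = []
            for s in spans:
                if kept and s[0] < kept[-1][1]:
                    if s[4] > kept[-1][4]:
                        kept[-1] = s
                else:
                    kept.append(s)
            for qs, qe, ts, te, score in kept:
                if score < min_score:
                    continue
                length = qe - qs
                ident = int(np.count_nonzero(
                    (qc[qs:qe] == tc[ts:te]) & (qc[qs:qe] < 4)
                )) / length
                if strand == "+":
                    t0, t1 = ts, te
                else:
                    t0, t1 = t_len - te, t_len - ts
                results.append(
                    ExtendedMatch(qs, qe, t0, t1, strand, score, ident)
                )
    results.sort(key=lambda m: (-m.score, m.query_start, m.template_start))
    return results


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_primers(path) -> list[PrimerPair]:
    """Read a primer TSV with header ``marker  forward  reverse``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"marker", "forward", "reverse"}
    if missing := required - set(df.columns):
        raise ValueError(f"primer table lacks columns: {sorted(missing)}")
    return [
        PrimerPair(str(r.marker), str(r.forward).upper(), str(r.reverse).upper())
        for r in df.itertuples()
    ]


def write_primers(pairs: Sequence[PrimerPair], path) -> None:
    pd.DataFrame(
        [(p.marker, p.forward, p.reverse) for p in pairs],
        columns=["marker", "forward", "reverse"],
    ).to_csv(path, sep="\t", index=False)


def load_pool(path) -> list[TemplateSeq]:
    """Read a template pool from FASTA; ``species=XX kind=EST|BAC`` tokens
    in the description set the template tags."""
    from Bio import SeqIO

    templates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t
        )
        templates.append(
            TemplateSeq(
                rec.id,
                str(rec.seq).upper(),
                species=tokens.get("species", ""),
                kind=tokens.get("kind", "EST"),
            )
        )
    return templates


def write_pool(pool: Sequence[TemplateSeq], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(
            Seq(t.seq),
            id=t.id,
            description=f"species={t.species} kind={t.kind}",
        )
        for t in pool
    ]
    SeqIO.write(records, str(path), "fasta")


def write_anchors_gff3(table: AnchorTable, path) -> None:
    """Write predicted products as GFF3 ``PCR_product`` features
    (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in table.hits:
            attrs = (
                f"marker={h.marker};product_size={h.product_size};"
                f"mismatches={h.mismatches_forward + h.mismatches_reverse}"
            )
            fh.write(
                f"{h.template_id}\tlinkmap\tPCR_product\t{h.start + 1}\t{h.end}\t"
                f".\t{h.strand}\t.\t{attrs}\n"
            )
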