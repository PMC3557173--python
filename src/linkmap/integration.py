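"""Anchored-sequence clustering, unigene selection and QTL integration.

Once markers are anchored to physical sequences, each marker's hits form a
cluster tied to the marker's map position(s).  A representative "unigene"
per cluster is picked by greedy exact-overlap merging of member sequences
(with a longest-member fallback when nothing overlaps).  Clusters are then
co-localized with previously reported fiber-quality QTL: a QTL interval is
retained only when its flanking markers sit within 20 cM of each other,
and every cluster with a mapped position inside a retained interval is
assigned to that QTL.  The per-chromosome summary mirrors the conventional
trait-by-chromosome table with At/Dt subtotals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .map_model import GeneticMap, subgenome
from .insilico_pcr import AnchorTable

#: The five fiber-quality traits: length, strength, fineness, elongation,
#: uniformity.
TRAITS: tuple[str, ...] = ("FL", "FS", "FF", "FE", "FU")

MERGED_CONSENSUS = "merged_consensus"
LONGEST_MEMBER = "longest_member"


@dataclass(frozen=True)
class QTLRecord:
    """A reported QTL: trait, linkage group and flanking-marker interval."""

    trait: str
    group: str
    start: float
    end: float
    peak: Optional[float] = None
    source: str = ""
    name: str = ""

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ValueError(
                f"unknown trait {self.trait!r}; expected one of {TRAITS}"
            )
        if self.start > self.end:
            raise ValueError(
                f"QTL on {self.group}: start {self.start} > end {self.end}"
            )

    @property
    def width(self) -> float:
        return self.end - self.start

    @property
    def label(self) -> str:
        return self.name or f"q{self.trait}_{self.group}_{self.start:g}-{self.end:g}"


def load_qtls(path) -> list[QTLRecord]:
    """Read a QTL TSV: ``trait  group  start_cM  end_cM  [peak_cM]  [source]``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"trait", "group", "start_cM", "end_cM"}
    if missing := required - set(df.columns):
        raise ValueError(f"QTL table lacks columns: {sorted(missing)}")
    records = []
    for r in df.itertuples():
        peak = getattr(r, "peak_cM", None)
        if peak is not None and pd.isna(peak):
            peak = None
        records.append(
            QTLRecord(
                str(r.trait), str(r.group), float(r.start_cM), float(r.end_cM),
                peak=None if peak is None else float(peak),
                source=str(getattr(r, "source", "")),
            )
        )
    return records


def write_qtls(qtls: Sequence[QTLRecord], path) -> None:
    pd.DataFrame(
        [(q.trait, q.group, q.start, q.end, q.peak, q.source) for q in qtls],
        columns=["trait", "group", "start_cM", "end_cM", "peak_cM", "source"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Anchor clusters
# ---------------------------------------------------------------------------

@dataclass
class AnchorCluster:
    """One anchored marker with its map position(s) and member templates."""

    marker: str
    positions: list[tuple[str, float]]  # (group, cM); multi-locus markers >1
    members: list[tuple[str, str, str]]  # (template id, species, kind)

    @property
    def n_members(self) -> int:
        return len(self.members)


def build_clusters(
    anchors: AnchorTable,
    gmap: GeneticMap,
    marker_to_loci: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[list[AnchorCluster], list[str]]:
    """Group hits per marker and attach map positions.

    ``marker_to_loci`` maps marker name -> mapped locus names; by default
    a marker is matched to the locus of the same name.  Markers with hits
    but no mapped locus are returned in the warning list, not failed.
    """
    clusters, warnings = [], []
    for marker, hits in anchors.hits_by_marker().items():
        if not hits:
            continue
        if marker_to_loci is not None:
            loci = [n for n in marker_to_loci.get(marker, ()) if gmap.has_locus(n)]
        else:
            loci = [marker] if gmap.has_locus(marker) else []
        if not loci:
            warnings.append(marker)
            continue
        positions = [
            (gmap.locus(n).group, gmap.locus(n).position) for n in loci
        ]
        members = sorted({(h.template_id, h.species, h.kind) for h in hits})
        clusters.append(AnchorCluster(marker, positions, members))
    return clusters, warnings


# ---------------------------------------------------------------------------
# Unigene selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Unigene:
    marker: str
    sequence: str
    provenance: str  # merged_consensus / longest_member

    @property
    def length(self) -> int:
        return len(self.sequence)


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Longest suffix(a)/prefix(b) overlap length with identity >= threshold
    (0 when none qualifies)."""
    for length in range(min(len(a), len(b)), min_overlap - 1, -1):
        allowed = int((1.0 - min_identity) * length)
        mism = sum(x != y for x, y in zip(a[-length:], b[:length]))
        if mism <= allowed:
            return length
    return 0


def select_unigene(
    marker: str,
    sequences: Mapping[str, str],
    min_overlap: int = 40,
    min_identity: float = 0.95,
) -> Unigene:
    """Pick the longest representative sequence for a marker's cluster.

    Greedy assembly: repeatedly merge the sequence pair with the longest
    qualifying suffix/prefix overlap (>= min_overlap bases at
    >= min_identity) until no pair overlaps; the merged sequence keeps the
    left member's bases across the junction.  If any merge happened and
    the longest product is a merged sequence, provenance is
    ``merged_consensus``; otherwise the longest original member is
    returned as ``longest_member``.
    """
    if not sequences:
        raise ValueError(f"cluster for {marker!r} has no member sequences")
    seqs = [str(s).upper() for s in sequences.values()]
    merged_flags = [False] * len(seqs)
    while len(seqs) > 1:
        best = (0, -1, -1)  # (overlap, i, j)
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                if i == j:
                    continue
                ov = _best_overlap(a, b, min_overlap, min_identity)
                if ov > best[0]:
                    best = (ov, i, j)
        ov, i, j = best
        if ov == 0:
            break
        merged = seqs[i] + seqs[j][ov:]
        keep = [s for idx, s in enumerate(seqs) if idx not in (i, j)]
        keep_flags = [f for idx, f in enumerate(merged_flags) if idx not in (i, j)]
        seqs = keep + [merged]
        merged_flags = keep_flags + [True]
    top = max(range(len(seqs)), key=lambda idx: len(seqs[idx]))
    provenance = MERGED_CONSENSUS if merged_flags[top] else LONGEST_MEMBER
    return Unigene(marker, seqs[top], provenance)


# ---------------------------------------------------------------------------
# QTL integration
# ---------------------------------------------------------------------------

@dataclass
class IntegrationRecord:
    qtl: QTLRecord
    assigned: list[tuple[str, float]]  # (marker, position inside interval)

    @property
    def n_assigned(self) -> int:
        return len(self.assigned)


def integrate_qtl(
    qtls: Sequence[QTLRecord],
    gmap: GeneticMap,
    clusters: Sequence[AnchorCluster],
    max_interval: float = 20.0,
) -> tuple[list[IntegrationRecord], pd.DataFrame]:
    """Assign anchored clusters to QTL intervals and tabulate by chromosome.

    QTL whose flanking-marker interval is wider than ``max_interval`` cM
    are excluded up front.  A cluster is assigned to a retained QTL when
    any of its mapped positions lies inside the closed interval
    [start, end] on the QTL's group; each (QTL, cluster) pair counts once.
    The summary table has one row per map group with per-trait QTL counts,
    a QTL total, and the number of distinct assigned clusters
    ("ESTs/genes"), plus At / Dt subtotal rows and a grand total.
    """
    for q in qtls:
        if q.group not in gmap:
            raise ValueError(f"QTL group {q.group!r} not in map")
    retained = [q for q in qtls if q.width <= max_interval]
    records = []
    genes_per_group: dict[str, set[str]] = {lbl: set() for lbl in gmap.labels}
    for q in retained:
        assigned = []
        for c in clusters:
            inside = [
                pos for grp, pos in c.positions
                if grp == q.group and q.start <= pos <= q.end
            ]
            if inside:
                assigned.append((c.marker, inside[0]))
                genes_per_group[q.group].add(c.marker)
        records.append(IntegrationRecord(q, assigned))

    col_traits = ("FE", "FL", "FF", "FS", "FU")  # conventional report order
    cols = [f"q{t}" for t in col_traits] + ["QTL_total", "ESTs_genes"]
    rows = {}
    for lbl in gmap.labels:
        counts = {f"q{t}": 0 for t in col_traits}
        for q in retained:
            if q.group == lbl:
                counts[f"q{q.trait}"] += 1
        counts["QTL_total"] = sum(counts[f"q{t}"] for t in col_traits)
        counts["ESTs_genes"] = len(genes_per_group[lbl])
        rows[lbl] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    at = df.loc[[l for l in df.index if subgenome(l) == "At"]].sum()
    dt = df.loc[[l for l in df.index if subgenome(l) == "Dt"]].sum()
    total = df.sum()
    df.loc["At"] = at
    df.loc["Dt"] = dt
    df.loc["Total"] = total
    df.index.name = "chromosome"
    return records, df


def integration_frame(records: Sequence[IntegrationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.qtl.label, r.qtl.trait, r.qtl.group, r.qtl.start, r.qtl.end,
                r.n_assigned, ",".join(m for m, _ in r.assigned),
            )
            for r in records
        ],
        columns=["qtl", "trait", "group", "start_cM", "end_cM",
                 "n_assigned", "assigned_markers"],
    )


# ---------------------------------------------------------------------------
# QTL clustering (interval-overlap single linkage)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTLCluster:
    group: str
    members: tuple[QTLRecord, ...]
    start: float
    end: float

    @property
    def traits(self) -> frozenset[str]:
        return frozenset(q.trait for q in self.members)

    @property
    def multi_trait(self) -> bool:
        return len(self.traits) >= 2


def cluster_qtl(qtls: Sequence[QTLRecord]) -> list[QTLCluster]:
    """Single-linkage grouping of same-chromosome QTL whose closed
    intervals overlap; independent of input order."""
    by_group: dict[str, list[QTLRecord]] = {}
    for q in qtls:
        by_group.setdefault(q.group, []).append(q)
    clusters = []
    for group in sorted(by_group):
        qs = sorted(by_group[group], key=lambda q: (q.start, q.end, q.trait))
        current: list[QTLRecord] = []
        cur_end = float("-inf")
        for q in qs:
            if current and q.start <= cur_end:
                current.append(q)
                cur_end = max(cur_end, q.end)
            else:
                if current:
                    clusters.append(
                        QTLCluster(group, tuple(current),
                                   min(m.start for m in current),
                                   max(m.end for m in current))
                    )
                current, cur_end = [q], q.end
        if current:
            clusters.append(
                QTLCluster(group, tuple(current),
                           min(m.start for m in current),
                           max(m.end for m in current))
            )
    return clusters
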