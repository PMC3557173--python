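"""Locus-density binning, cluster calling and duplicated-locus analysis.

Three structural diagnostics of a dense linkage map:

* **Density profiles** — locus counts in fixed-width (default 10 cM) bins
  per group; density peaks tend to mark recombination-suppressed,
  centromere-proximal regions.
* **Locus clusters** — >=5 loci within a sliding 1-cM window; clusters of
  EST-derived SSR loci are candidate gene islands, clusters dominated by
  retrotransposon-anchored (REMAP) loci flag retrotransposon-rich regions.
* **Duplicated loci** — markers mapping to 2+ positions.  In an
  allotetraploid, a marker hitting both ``A_i`` and ``D_i`` bridges
  homoeologous chromosomes; duplications on the same or non-partner
  chromosomes instead record intra-genome duplication / rearrangement, and
  systematic ``A_i``/``D_j`` cross patterns support reciprocal
  translocations between At chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .map_model import (
    GeneticMap,
    Locus,
    group_index,
    homoeolog_partner,
    round_half_away,
    subgenome,
)

GENERIC = "generic"
GENE_ISLAND = "gene_island"
RETRO_RICH = "retro_rich"

HOMOEOLOGOUS = "homoeologous"
SAME_CHROMOSOME = "same_chromosome"
DIFFERENT_NONHOMOEOLOGOUS = "different_nonhomoeologous"


# ---------------------------------------------------------------------------
# Density binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityProfile:
    group: str
    width: float
    counts: tuple[int, ...]  # bin k covers [k*width, (k+1)*width)

    @property
    def peak_bins(self) -> tuple[int, ...]:
        """Indices of the maximal-count bin(s)."""
        m = max(self.counts)
        return tuple(i for i, c in enumerate(self.counts) if c == m)

    def edges(self) -> list[tuple[float, float]]:
        return [(i * self.width, (i + 1) * self.width) for i in range(len(self.counts))]


def bin_density(gmap: GeneticMap, width: float = 10.0) -> list[DensityProfile]:
    """Count loci in half-open [k*w, (k+1)*w) bins along each group.

    The bins tile [0, group length]; a locus sitting exactly at the group
    maximum is absorbed into the last bin so no locus is lost.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    profiles = []
    for g in gmap:
        if len(g) == 0:
            continue
        top = max(l.position for l in g)
        n_bins = max(1, math.ceil(top / width)) if top > 0 else 1
        counts = [0] * n_bins
        for l in g:
            idx = min(int(l.position // width), n_bins - 1)
            counts[idx] += 1
        profiles.append(DensityProfile(g.label, width, tuple(counts)))
    return profiles


def density_frame(profiles: Sequence[DensityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for (start, end), c in zip(p.edges(), p.counts):
            rows.append((p.group, start, end, c))
    return pd.DataFrame(rows, columns=["group", "bin_start", "bin_end", "count"])


# ---------------------------------------------------------------------------
# Cluster calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusCluster:
    group: str
    loci: tuple[Locus, ...]
    kind: str  # generic / gene_island / retro_rich

    @property
    def start(self) -> float:
        return self.loci[0].position

    @property
    def end(self) -> float:
        return self.loci[-1].position

    @property
    def span(self) -> float:
        return self.end - self.start

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_essr(self) -> int:
        return sum(l.marker_type == "eSSR" for l in self.loci)

    @property
    def n_remap(self) -> int:
        return sum(l.marker_type == "REMAP" for l in self.loci)


def _qualifying_windows(
    positions: Sequence[float], min_loci: int, window: float
) -> list[tuple[int, int]]:
    """Index ranges [i, j] (inclusive) of >=min_loci loci spanning <=window."""
    out = []
    n = len(positions)
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and positions[j + 1] - positions[i] <= window:
            j += 1
        if j - i + 1 >= min_loci:
            out.append((i, j))
    return out


def _merge_index_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of index windows that share at least one locus."""
    merged: list[list[int]] = []
    for i, j in sorted(windows):
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [(i, j) for i, j in merged]


def _has_dense_subwindow(
    positions: Sequence[float], min_loci: int, window: float
) -> bool:
    return bool(_qualifying_windows(positions, min_loci, window))


def detect_clusters(
    gmap: GeneticMap,
    min_loci: int = 5,
    window: float = 1.0,
    island_min_essr: int = 5,
    retro_fraction: float = 0.5,
) -> list[LocusCluster]:
    """Call locus clusters of >=min_loci loci per <=window cM.

    A 1-cM window slides over the position-sorted loci of each group;
    overlapping qualifying windows are merged into one maximal cluster
    (so a merged cluster's overall span may slightly exceed ``window``,
    but it always contains at least one qualifying sub-window).

    Classification: ``gene_island`` when some <=window stretch inside the
    cluster holds >=island_min_essr EST-SSR loci; otherwise ``retro_rich``
    when REMAP loci make up strictly more than ``retro_fraction`` of the
    members; otherwise ``generic``.
    """
    if min_loci < 1:
        raise ValueError("min_loci must be >= 1")
    if window <= 0:
        raise ValueError("window must be positive")
    clusters = []
    for g in gmap:
        positions = g.positions
        windows = _qualifying_windows(positions, min_loci, window)
        for i, j in _merge_index_windows(windows):
            members = tuple(g.loci[i : j + 1])
            essr_pos = [l.position for l in members if l.marker_type == "eSSR"]
            if _has_dense_subwindow(essr_pos, island_min_essr, window):
                kind = GENE_ISLAND
            elif sum(l.marker_type == "REMAP" for l in members) > retro_fraction * len(members):
                kind = RETRO_RICH
            else:
                kind = GENERIC
            clusters.append(LocusCluster(g.label, members, kind))
    return clusters


def cluster_frame(clusters: Sequence[LocusCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.group, c.start, c.end, c.n_loci, c.n_essr, c.n_remap, c.kind)
            for c in clusters
        ],
        columns=["group", "start_cM", "end_cM", "n_loci", "n_eSSR", "n_REMAP", "kind"],
    )


# ---------------------------------------------------------------------------
# Duplicated loci
# ---------------------------------------------------------------------------

@dataclass
class DuplicationTable:
    """Multi-locus markers and the per-locus duplication classification."""

    marker_to_loci: dict[str, list[str]]  # only markers with >=2 loci
    locus_group: dict[str, str]
    locus_class: dict[str, str]

    @property
    def multiplicity_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for loci in self.marker_to_loci.values():
            hist[len(loci)] = hist.get(len(loci), 0) + 1
        return dict(sorted(hist.items()))

    @property
    def n_duplicated_markers(self) -> int:
        return len(self.marker_to_loci)

    @property
    def n_duplicated_loci(self) -> int:
        return sum(len(v) for v in self.marker_to_loci.values())

    def class_counts(self) -> dict[str, int]:
        counts = {HOMOEOLOGOUS: 0, SAME_CHROMOSOME: 0, DIFFERENT_NONHOMOEOLOGOUS: 0}
        for cls in self.locus_class.values():
            counts[cls] += 1
        return counts

    def class_percent(self) -> dict[str, float]:
        total = self.n_duplicated_loci
        return {
            cls: round_half_away(100.0 * n / total, 2) if total else 0.0
            for cls, n in self.class_counts().items()
        }

    def summary(self) -> dict:
        return {
            "multiplicity_histogram": self.multiplicity_histogram,
            "n_duplicated_markers": self.n_duplicated_markers,
            "n_duplicated_loci": self.n_duplicated_loci,
            "class_counts": self.class_counts(),
            "class_percent": self.class_percent(),
        }


def analyze_duplication(
    gmap: GeneticMap, marker_to_loci: Mapping[str, Sequence[str]]
) -> DuplicationTable:
    """Classify every duplicated locus by where its sibling loci map.

    A locus is ``homoeologous`` when the same marker also maps to the
    homoeologous partner group (A_i <-> D_i); failing that,
    ``same_chromosome`` when a sibling maps to the same group; otherwise
    ``different_nonhomoeologous``.  Markers with a single locus are ignored.
    """
    dup: dict[str, list[str]] = {}
    locus_group: dict[str, str] = {}
    locus_class: dict[str, str] = {}
    for marker, loci in marker_to_loci.items():
        loci = list(loci)
        for name in loci:
            if not gmap.has_locus(name):
                raise ValueError(
                    f"marker {marker!r} maps to unknown locus {name!r}"
                )
        if len(loci) < 2:
            continue
        dup[marker] = loci
        groups = [gmap.locus(n).group for n in loci]
        for name, g in zip(loci, groups):
            locus_group[name] = g
            others = [og for n2, og in zip(loci, groups) if n2 != name]
            partner = homoeolog_partner(g)
            if partner is not None and partner in others:
                locus_class[name] = HOMOEOLOGOUS
            elif g in others:
                locus_class[name] = SAME_CHROMOSOME
            else:
                locus_class[name] = DIFFERENT_NONHOMOEOLOGOUS
    return DuplicationTable(dup, locus_group, locus_class)


# ---------------------------------------------------------------------------
# Translocation signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranslocationSignal:
    """Duplicated-locus support for a candidate reciprocal translocation.

    For an At pair (A_i, A_j) suspected of having exchanged segments, the
    tell-tale pattern is markers bridging A_i with D_j (the partner of the
    *other* chromosome) and vice versa; ``counts`` holds the number of
    bridging markers per (A, D) combination.
    """

    pair: tuple[str, str]
    counts: dict[tuple[str, str], int]

    @property
    def n_supporting_loci(self) -> int:
        """Bridging duplicated-locus pairs supporting the translocation
        (one per marker with loci on both chromosomes of a combination)."""
        return sum(self.counts.values())


DEFAULT_CANDIDATE_PAIRS: tuple[tuple[str, str], ...] = (("A2", "A3"), ("A4", "A5"))


def detect_translocation_signals(
    dup: DuplicationTable,
    candidate_pairs: Iterable[tuple[str, str]] = DEFAULT_CANDIDATE_PAIRS,
) -> list[TranslocationSignal]:
    """Count cross-homoeolog bridging markers for candidate At pairs."""
    signals = []
    for ai, aj in candidate_pairs:
        for label in (ai, aj):
            if subgenome(label) is None or group_index(label) is None:
                raise ValueError(f"candidate group {label!r} lacks subgenome/index")
        di = homoeolog_partner(ai)
        dj = homoeolog_partner(aj)
        counts = {(ai, dj): 0, (aj, di): 0}
        for marker, loci in dup.marker_to_loci.items():
            groups = {dup.locus_group[n] for n in loci}
            for a, d in counts:
                if a in groups and d in groups:
                    counts[(a, d)] += 1
        signals.append(TranslocationSignal((ai, aj), counts))
    return signals


def translocation_frame(signals: Sequence[TranslocationSignal]) -> pd.DataFrame:
    rows = []
    for s in signals:
        for (a, d), n in s.counts.items():
            rows.append(("/".join(s.pair), a, d, n))
    return pd.DataFrame(rows, columns=["candidate_pair", "at_group", "dt_group", "n_markers"])
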