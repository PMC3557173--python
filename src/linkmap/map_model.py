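"""Genetic linkage map data model, I/O, summary statistics and gap detection.

A genetic map is an ordered arrangement of marker loci along named linkage
groups, with positions in centimorgans (cM).  For the allotetraploid cotton
maps this package targets, the 26 linkage groups correspond to the 13
A-subgenome (At) and 13 D-subgenome (Dt) chromosomes; group labels such as
``A5`` or ``D8`` carry the subgenome letter and the homoeologous index, and
``A_i``/``D_i`` with the same index are homoeologous partners.

The map is the coordinate system for everything downstream (segregation
scans, density profiles, marker anchoring, QTL integration), so this module
is deliberately strict about validation: positions must be non-negative,
marker types must come from the known catalogue, and duplicate locus rows
are rejected at load time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

#: The eleven marker-type categories of the cotton map, in report order.
MARKER_TYPES: tuple[str, ...] = (
    "eSSR", "gSSR", "REMAP", "RT", "SRAP", "AFLP",
    "SNP", "CAPs", "InDel", "BAC-end", "morphology",
)

#: Marker types backed by a known primer/template sequence, i.e. usable as
#: probes for in silico PCR anchoring (AFLP/SRAP/morphology are anonymous).
SEQUENCE_BASED_TYPES: frozenset[str] = frozenset(MARKER_TYPES) - {
    "AFLP", "SRAP", "morphology",
}

# Conventional chromosome numbers for the cotton linkage groups: A-subgenome
# groups keep their index (A5 = Chr. 5); D-subgenome groups follow the
# cytogenetic numbering of this cross (D3 = Chr. 17, D8 = Chr. 24, ...).
_D_CHROMOSOME = {
    1: 15, 2: 14, 3: 17, 4: 22, 5: 19, 6: 25, 7: 16,
    8: 24, 9: 23, 10: 20, 11: 21, 12: 26, 13: 18,
}

_GROUP_RE = re.compile(r"^([ADad])0*([1-9]\d*)$")
_CHR_RE = re.compile(r"^[Cc]hr\.?\s*0*([1-9]\d*)$")


def round_half_away(x: float, digits: int = 2) -> float:
    """Round to ``digits`` decimals with ties going away from zero.

    Python's builtin ``round`` is banker's rounding; printed map statistics
    use conventional half-away rounding, so we go through :class:`Decimal`
    on the shortest decimal representation of the float.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def subgenome(group: str) -> Optional[str]:
    """Subgenome tag ("At"/"Dt") for a linkage-group label, or None."""
    m = _GROUP_RE.match(group.strip())
    if m is None:
        return None
    return "At" if m.group(1).upper() == "A" else "Dt"


def group_index(group: str) -> Optional[int]:
    """Homoeologous index i of an ``A_i``/``D_i`` style label, or None."""
    m = _GROUP_RE.match(group.strip())
    return int(m.group(2)) if m else None


def homoeolog_partner(group: str) -> Optional[str]:
    """Partner chromosome of a group (A_i <-> D_i), or None if unnamed."""
    sg = subgenome(group)
    idx = group_index(group)
    if sg is None or idx is None:
        return None
    return ("D" if sg == "At" else "A") + str(idx)


def chromosome_number(group: str) -> Optional[int]:
    """Conventional chromosome number for a linkage-group label.

    Accepts ``A5``/``D8`` style labels (translated via the cytogenetic
    numbering) and ``Chr5`` / ``Chr. 5`` style labels (number taken as-is).
    Returns None for labels outside both conventions.
    """
    m = _CHR_RE.match(group.strip())
    if m:
        return int(m.group(1))
    idx = group_index(group)
    if idx is None:
        return None
    if subgenome(group) == "At":
        return idx
    return _D_CHROMOSOME.get(idx)


def _group_sort_key(label: str):
    sg = subgenome(label)
    idx = group_index(label)
    if sg is not None and idx is not None:
        return (0 if sg == "At" else 1, idx, label)
    return (2, 0, label)


@dataclass(frozen=True)
class Locus:
    """A mapped marker locus: name, marker type, linkage group, cM position."""

    name: str
    marker_type: str
    group: str
    position: float

    def __post_init__(self):
        if self.marker_type not in MARKER_TYPES:
            raise ValueError(
                f"unknown marker_type {self.marker_type!r} for locus "
                f"{self.name!r}; expected one of {', '.join(MARKER_TYPES)}"
            )
        if not (self.position >= 0.0):
            raise ValueError(
                f"locus {self.name!r} has negative or non-numeric position "
                f"{self.position!r}"
            )

    @property
    def subgenome(self) -> Optional[str]:
        return subgenome(self.group)


@dataclass
class LinkageGroup:
    """A named linkage group holding its loci sorted by cM position."""

    label: str
    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self):
        self.loci = sorted(self.loci, key=lambda l: (l.position, l.name))

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci)

    @property
    def positions(self) -> list[float]:
        return [l.position for l in self.loci]

    @property
    def length(self) -> float:
        """Map length in cM: max position minus min position (0 if <2 loci)."""
        if len(self.loci) < 2:
            return 0.0
        return self.loci[-1].position - self.loci[0].position


class GeneticMap:
    """An ordered collection of linkage groups with unique labels.

    Groups are kept in natural chromosome order (At by index, then Dt by
    index, then any other labels lexicographically); loci are unique by
    name across the whole map.
    """

    def __init__(self, groups: Iterable[LinkageGroup]):
        ordered = sorted(groups, key=lambda g: _group_sort_key(g.label))
        self._groups: dict[str, LinkageGroup] = {}
        for g in ordered:
            if g.label in self._groups:
                raise ValueError(f"duplicate linkage-group label {g.label!r}")
            self._groups[g.label] = g
        self._by_name: dict[str, Locus] = {}
        for g in ordered:
            for loc in g:
                if loc.name in self._by_name:
                    raise ValueError(f"duplicate locus name {loc.name!r}")
                self._by_name[loc.name] = loc

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[LinkageGroup]:
        return iter(self._groups.values())

    def __getitem__(self, label: str) -> LinkageGroup:
        try:
            return self._groups[label]
        except KeyError:
            raise KeyError(f"no linkage group {label!r} in map") from None

    def __contains__(self, label: str) -> bool:
        return label in self._groups

    @property
    def labels(self) -> list[str]:
        return list(self._groups)

    @property
    def n_groups(self) -> int:
        return len(self._groups)

    @property
    def n_loci(self) -> int:
        return len(self._by_name)

    def loci(self) -> Iterator[Locus]:
        """All loci in (group order, position) order."""
        for g in self:
            yield from g

    def locus(self, name: str) -> Locus:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown locus {name!r}") from None

    def has_locus(self, name: str) -> bool:
        return name in self._by_name

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        required = {"locus", "marker_type", "group", "position_cM"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"map table lacks columns: {sorted(missing)}")
        dup = df.duplicated(subset=["locus", "group"])
        if dup.any():
            bad = df.loc[dup, "locus"].iloc[0]
            raise ValueError(f"duplicate (locus, group) row for {bad!r}")
        groups: dict[str, list[Locus]] = {}
        for row in df.itertuples(index=True):
            try:
                pos = float(row.position_cM)
            except (TypeError, ValueError):
                raise ValueError(
                    f"line {row.Index + 2}: malformed position "
                    f"{row.position_cM!r} for locus {row.locus!r}"
                ) from None
            if pos < 0 or pos != pos:  # negative or NaN
                raise ValueError(
                    f"line {row.Index + 2}: negative or missing position "
                    f"{row.position_cM!r} for locus {row.locus!r}"
                )
            loc = Locus(str(row.locus), str(row.marker_type), str(row.group), pos)
            groups.setdefault(loc.group, []).append(loc)
        return cls(LinkageGroup(lbl, loci) for lbl, loci in groups.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (l.name, l.marker_type, l.group, l.position)
            for l in self.loci()
        ]
        return pd.DataFrame(rows, columns=["locus", "marker_type", "group", "position_cM"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_map(path) -> GeneticMap:
    """Read a genetic map from a TSV with header
    ``locus  marker_type  group  position_cM`` ('#' lines are comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return GeneticMap.from_frame(df)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.write(path)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    label: str
    n_loci: int
    length: float
    mean_interlocus: Optional[float]  # None for singleton groups


@dataclass(frozen=True)
class MapSummary:
    """Whole-map statistics in the conventional printed form.

    ``mean_interlocus`` divides the total length by the number of
    inter-locus *intervals*, ``n_loci - n_groups`` (a chain of n loci has
    n-1 gaps per group), and is rounded half-away-from-zero.
    """

    n_loci: int
    n_groups: int
    total_length: float
    mean_interlocus: float
    mean_loci_per_group: int
    per_group: tuple[GroupSummary, ...]

    def to_dict(self) -> dict:
        d = {
            "n_loci": self.n_loci,
            "n_groups": self.n_groups,
            "total_length_cM": self.total_length,
            "mean_interlocus_cM": self.mean_interlocus,
            "mean_loci_per_group": self.mean_loci_per_group,
            "groups": [
                {
                    "group": g.label,
                    "n_loci": g.n_loci,
                    "length_cM": g.length,
                    "mean_interlocus_cM": g.mean_interlocus,
                }
                for g in self.per_group
            ],
        }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.label, g.n_loci, g.length, g.mean_interlocus)
                for g in self.per_group
            ],
            columns=["group", "n_loci", "length_cM", "mean_interlocus_cM"],
        )


def summarize_map(gmap: GeneticMap, round_digits: int = 2) -> MapSummary:
    """Compute locus counts, lengths and mean inter-locus spacing.

    Raises ValueError when every group is a singleton (no intervals exist,
    so the mean spacing is undefined).
    """
    if gmap.n_groups == 0:
        raise ValueError("empty map")
    n_intervals = gmap.n_loci - gmap.n_groups
    if n_intervals <= 0:
        raise ValueError("mean inter-locus distance undefined: all groups singleton")
    total = sum(g.length for g in gmap)
    per_group = []
    for g in gmap:
        gi = len(g) - 1
        per_group.append(
            GroupSummary(
                g.label,
                len(g),
                round_half_away(g.length, round_digits),
                round_half_away(g.length / gi, round_digits) if gi > 0 else None,
            )
        )
    return MapSummary(
        n_loci=gmap.n_loci,
        n_groups=gmap.n_groups,
        total_length=round_half_away(total, round_digits),
        mean_interlocus=round_half_away(total / n_intervals, round_digits),
        mean_loci_per_group=int(round_half_away(gmap.n_loci / gmap.n_groups, 0)),
        per_group=tuple(per_group),
    )


@dataclass(frozen=True)
class Gap:
    group: str
    left: str
    right: str
    size: float


def detect_gaps(gmap: GeneticMap, threshold: float = 10.0) -> list[Gap]:
    """All adjacent locus pairs strictly farther apart than ``threshold`` cM.

    Returned in (group order, position) order; an exact-threshold spacing is
    not a gap (strict inequality).
    """
    gaps: list[Gap] = []
    for g in gmap:
        for left, right in zip(g.loci, g.loci[1:]):
            size = right.position - left.position
            if size > threshold:
                gaps.append(Gap(g.label, left.name, right.name, size))
    return gaps
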