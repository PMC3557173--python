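"""Segregation-distortion testing and region scanning for BC1 genotypes.

In a first backcross (BC1) population each locus segregates 1:1 between the
recurrent-parent homozygote (scored ``1``) and the heterozygote (scored
``3``); missing calls are ``-``.  Departures from 1:1 are tested per locus
with a one-degree-of-freedom Pearson goodness-of-fit chi-square (no
continuity correction: with ~138 individuals the approximation is good).
Runs of adjacent map loci all distorted in the same direction form
segregation distortion regions (SDRs), named ``SDR<k>_<chromosome>`` with
k numbering the regions across the whole map in map order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .map_model import GeneticMap, MARKER_TYPES, chromosome_number

MISSING = 0  # internal code for a missing call
RECURRENT = 1
HETEROZYGOTE = 3

#: Distortion direction labels.
TOWARD_RECURRENT = "toward_recurrent"
TOWARD_HETEROZYGOTE = "toward_heterozygote"
NONE = "none"


@dataclass
class GenotypeMatrix:
    """Loci x individuals BC1 call matrix with codes {1, 3, 0=missing}."""

    loci: list[str]
    individuals: list[str]
    calls: np.ndarray  # int8, shape (n_loci, n_individuals)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.individuals)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.calls, (MISSING, RECURRENT, HETEROZYGOTE))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at locus {self.loci[i]!r}, "
                f"individual {self.individuals[j]!r}; codes are 1, 3 or missing"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names in genotype matrix are not unique")

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus counts of code-1 and code-3 calls (missing excluded)."""
        n1 = (self.calls == RECURRENT).sum(axis=1)
        n3 = (self.calls == HETEROZYGOTE).sum(axis=1)
        return n1, n3


def load_genotypes(path) -> GenotypeMatrix:
    """Read a genotype TSV: first column locus, then one column per
    individual, cells in {1, 3, -}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    loci = df.iloc[:, 0].tolist()
    individuals = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    calls = np.zeros(raw.shape, dtype=np.int8)
    for code, value in ((RECURRENT, "1"), (HETEROZYGOTE, "3")):
        calls[raw == value] = code
    unknown = ~np.isin(raw, ("1", "3", "-"))
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise ValueError(
            f"line {i + 2}: invalid genotype cell {raw[i, j]!r} "
            f"(expected 1, 3 or -)"
        )
    return GenotypeMatrix(loci, individuals, calls)


def write_genotypes(gt: GenotypeMatrix, path) -> None:
    sym = np.full(gt.calls.shape, "-", dtype=object)
    sym[gt.calls == RECURRENT] = "1"
    sym[gt.calls == HETEROZYGOTE] = "3"
    df = pd.DataFrame(sym, columns=gt.individuals)
    df.insert(0, "locus", gt.loci)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chi-square testing
# ---------------------------------------------------------------------------

def chi_square_1to1(n1: int, n3: int) -> tuple[float, float]:
    """Pearson chi-square for 1:1 segregation from two class counts.

    With expected count e = (n1+n3)/2 in each class the statistic reduces
    to (n1-n3)^2/(n1+n3); the p-value is the chi-square(1 df) survival
    function.  No Yates continuity correction is applied.
    """
    total = n1 + n3
    if total <= 0:
        raise ValueError("untestable locus: no non-missing calls")
    if n1 < 0 or n3 < 0:
        raise ValueError("negative class count")
    chi2 = (n1 - n3) ** 2 / total
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass(frozen=True)
class DistortionResult:
    locus: str
    n1: int
    n3: int
    chi2: float
    p: float
    status: str  # none / toward_recurrent / toward_heterozygote


def classify_loci(
    genotypes: GenotypeMatrix, alpha: float = 0.05
) -> list[DistortionResult]:
    """Test every locus for 1:1 segregation and classify the skew direction.

    A locus is distorted when p < alpha; the direction follows the sign of
    n1 - n3 (toward the recurrent parent when homozygotes are in excess).
    Ties with p < alpha cannot occur since n1 == n3 gives chi2 = 0.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    n1, n3 = genotypes.counts()
    total = n1 + n3
    if (total == 0).any():
        bad = genotypes.loci[int(np.argmax(total == 0))]
        raise ValueError(f"untestable locus {bad!r}: all calls missing")
    chi2 = (n1 - n3) ** 2 / total
    p = stats.chi2.sf(chi2, df=1)
    results = []
    for i, name in enumerate(genotypes.loci):
        if p[i] < alpha and n1[i] > n3[i]:
            status = TOWARD_RECURRENT
        elif p[i] < alpha and n3[i] > n1[i]:
            status = TOWARD_HETEROZYGOTE
        else:
            status = NONE
        results.append(
            DistortionResult(name, int(n1[i]), int(n3[i]), float(chi2[i]), float(p[i]), status)
        )
    return results


def results_frame(results: Sequence[DistortionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.locus, r.n1, r.n3, r.chi2, r.p, r.status) for r in results],
        columns=["locus", "n1", "n3", "chi2", "p", "status"],
    )


def summarize_by_type(
    results: Sequence[DistortionResult], marker_types: Mapping[str, str]
) -> pd.DataFrame:
    """Per-marker-type distortion table (total / distorted / per direction).

    ``marker_types`` maps locus name -> marker type.  Rows follow the
    canonical marker-type order, with a final Total row; types absent from
    the data are omitted.
    """
    rows = []
    by_type: dict[str, list[DistortionResult]] = {}
    for r in results:
        try:
            mt = marker_types[r.locus]
        except KeyError:
            raise KeyError(f"unknown locus {r.locus!r}: no marker type") from None
        by_type.setdefault(mt, []).append(r)
    order = [t for t in MARKER_TYPES if t in by_type] + [
        t for t in by_type if t not in MARKER_TYPES
    ]
    for mt in order:
        rs = by_type[mt]
        rec = sum(r.status == TOWARD_RECURRENT for r in rs)
        het = sum(r.status == TOWARD_HETEROZYGOTE for r in rs)
        rows.append((mt, len(rs), rec + het, rec, het))
    total = (
        "Total",
        sum(r[1] for r in rows),
        sum(r[2] for r in rows),
        sum(r[3] for r in rows),
        sum(r[4] for r in rows),
    )
    rows.append(total)
    return pd.DataFrame(
        rows,
        columns=[
            "marker_type", "total_loci", "distorted",
            "toward_recurrent", "toward_heterozygote",
        ],
    )


# ---------------------------------------------------------------------------
# SDR scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDR:
    """A segregation distortion region: a maximal run of >=min_run adjacent
    map loci all skewed in the same direction."""

    name: str
    group: str
    direction: str
    loci: tuple[str, ...]
    start_cm: float
    end_cm: float

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def scan_sdrs(
    gmap: GeneticMap,
    results: Sequence[DistortionResult],
    min_run: int = 3,
) -> list[SDR]:
    """Scan map-ordered loci for maximal same-direction distorted runs.

    Runs shorter than ``min_run`` are discarded.  Surviving regions are
    numbered 1..K over the whole map in (group order, position) order and
    named ``SDR<k>_<chromosome number>`` (falling back to the group label
    when the label carries no chromosome number).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    by_locus = {r.locus: r for r in results}
    regions: list[tuple[str, str, list]] = []  # (group, direction, loci)
    for g in gmap:
        run: list = []
        direction = NONE

        def flush():
            if len(run) >= min_run:
                regions.append((g.label, direction, list(run)))

        for loc in g:
            try:
                r = by_locus[loc.name]
            except KeyError:
                raise ValueError(
                    f"distortion results do not cover mapped locus {loc.name!r}"
                ) from None
            if r.status == NONE:
                flush()
                run, direction = [], NONE
            elif r.status == direction:
                run.append(loc)
            else:
                flush()
                run, direction = [loc], r.status
        flush()
    sdrs = []
    for k, (group, direction, loci) in enumerate(regions, start=1):
        chrom = chromosome_number(group)
        suffix = str(chrom) if chrom is not None else group
        sdrs.append(
            SDR(
                name=f"SDR{k}_{suffix}",
                group=group,
                direction=direction,
                loci=tuple(l.name for l in loci),
                start_cm=loci[0].position,
                end_cm=loci[-1].position,
            )
        )
    return sdrs


def sdr_frame(sdrs: Sequence[SDR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.name, s.group, s.direction, s.start_cm, s.end_cm, s.n_loci)
            for s in sdrs
        ],
        columns=["name", "group", "direction", "start_cM", "end_cM", "n_loci"],
    )
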