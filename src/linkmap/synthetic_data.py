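"""Seeded generators for every pipeline input, with ground-truth manifests.

The real mapping experiment — a 138-individual BC1 population of
(TM-1 x Hai7124) x TM-1 scored at ~3,400 loci over 26 linkage groups, with
primer pairs screened against public EST/BAC pools — is not available as
machine-readable raw data, so this module fabricates inputs carrying the
same statistical structure: a clustered 26-group map, BC1 genotypes with
planted transmission-bias regions, primer/template pools with planted
amplicons at controlled mismatch counts and cross-species product-size
offsets, multi-locus (duplicated) markers, and fiber-trait QTL intervals.

Every planted feature is recorded in a truth manifest so detector recovery
is exactly scorable.  One global integer seed feeds a hierarchical
per-generator stream (numpy ``SeedSequence`` spawn keys), so adding a
generator never perturbs another's draws, and identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .map_model import (
    GeneticMap,
    LinkageGroup,
    Locus,
    MARKER_TYPES,
    SEQUENCE_BASED_TYPES,
    homoeolog_partner,
    round_half_away,
    write_map,
)
from .segregation import GenotypeMatrix, write_genotypes
from .insilico_pcr import (
    PrimerPair,
    TemplateSeq,
    reverse_complement,
    write_pool,
    write_primers,
)
from .integration import QTLRecord, TRAITS, write_qtls

# Marker-type frequencies of the cotton map (loci per type), used as the
# categorical distribution for synthetic marker types.
TYPE_FREQUENCIES: dict[str, int] = {
    "eSSR": 1450, "gSSR": 1284, "REMAP": 187, "RT": 172, "SRAP": 127,
    "AFLP": 80, "SNP": 73, "CAPs": 19, "InDel": 12, "BAC-end": 8,
    "morphology": 2,
}

_STREAMS = {"map": 0, "bc1": 1, "sequences": 2, "qtl": 3}


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistortionRegion:
    """A map interval whose loci transmit the heterozygote with probability
    ``p_het`` (0.5 = fair; >0.5 skews toward the heterozygote)."""

    group: str
    start: float
    end: float
    p_het: float = 0.70

    def __post_init__(self):
        if not (0.0 <= self.p_het <= 1.0):
            raise ValueError(f"p_het {self.p_het} outside [0, 1]")
        if self.start > self.end:
            raise ValueError("distortion region start > end")


@dataclass(frozen=True)
class ClusterPlant:
    """Loci to pile into a narrow window to create a detectable cluster."""

    group: str
    center: float
    span: float = 0.8
    type_counts: tuple[tuple[str, int], ...] = (("eSSR", 6),)

    @property
    def n_loci(self) -> int:
        return sum(n for _, n in self.type_counts)


@dataclass(frozen=True)
class DuplicationPlan:
    """How many markers map to 2/3/4 loci and how often the duplicate sits
    on the homoeologous partner chromosome."""

    histogram: tuple[tuple[int, int], ...] = ((2, 29), (3, 4), (4, 1))
    homoeolog_fraction: float = 0.64
    same_chromosome_fraction: float = 0.3213  # of the non-homoeologous part


@dataclass(frozen=True)
class AmpliconPlan:
    """Primer/template pool layout.

    ``success_fraction`` of the markers get templates with planted
    convergent primer sites (substitution counts cycling through
    ``mismatch_counts`` per primer); the rest get decoy templates with no
    site.  Cross-species copies of a marker's template either preserve the
    insert (same product size) or carry +``size_offset`` bp insertions.
    """

    n_markers: Optional[int] = 200
    success_fraction: float = 0.635
    primer_length: int = 20
    insert_length: int = 100
    flank_min: int = 100
    flank_max: int = 200
    mismatch_counts: tuple[int, ...] = (0, 1, 2, 3)
    species: tuple[str, ...] = ("Gh", "Gb", "Gr", "Ga")
    extra_species_max: int = 2
    same_size_fraction: float = 0.361
    size_offset: int = 6
    n_bac_markers: int = 5
    bac_length: int = 20000


@dataclass(frozen=True)
class QTLPlan:
    trait: str
    group: str
    start: float
    end: float

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ValueError(f"trait {self.trait!r} not one of {TRAITS}")


def _default_distortion_regions() -> tuple[DistortionRegion, ...]:
    # 12 regions on 11 groups (two on D10): 8 skewed toward the recurrent
    # parent, 4 toward the heterozygote, as in the real map.
    toward_recurrent = [
        ("A2", 30.0), ("A5", 60.0), ("A7", 20.0), ("A9", 90.0),
        ("A11", 45.0), ("D2", 15.0), ("D4", 70.0), ("D10", 10.0),
    ]
    toward_het = [("A13", 55.0), ("D7", 35.0), ("D10", 100.0), ("D12", 80.0)]
    regions = [
        DistortionRegion(g, s, s + 8.0, p_het=0.30) for g, s in toward_recurrent
    ] + [
        DistortionRegion(g, s, s + 8.0, p_het=0.70) for g, s in toward_het
    ]
    return tuple(regions)


def _default_cluster_plants() -> tuple[ClusterPlant, ...]:
    return (
        ClusterPlant("A5", 107.1, 0.57, (("eSSR", 6),)),          # gene island
        ClusterPlant("D3", 50.0, 0.9, (("REMAP", 8), ("gSSR", 7))),  # retro-rich
        ClusterPlant("D8", 70.0, 0.8, (("gSSR", 4), ("RT", 2))),  # generic
    )


def _default_qtl_plans() -> tuple[QTLPlan, ...]:
    return (
        QTLPlan("FL", "A5", 10.0, 24.0),
        QTLPlan("FS", "A5", 18.0, 30.0),   # overlaps the FL QTL -> multi-trait cluster
        QTLPlan("FE", "D8", 40.0, 55.0),
        QTLPlan("FF", "D8", 50.0, 62.0),
        QTLPlan("FL", "D8", 45.0, 58.0),
        QTLPlan("FS", "D3", 20.0, 46.0),   # 26 cM wide: excluded by the 20-cM rule
        QTLPlan("FU", "A8", 5.0, 17.0),
        QTLPlan("FF", "A9", 70.0, 88.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the real design: 26 linkage groups of ~131 loci and
    ~141 cM each, 138 BC1 individuals, 1% missing calls, transmission
    probability 0.70/0.30 inside distortion regions, and a 63.5% anchoring
    plant rate.
    """

    seed: int = 0
    n_groups: int = 26
    loci_per_group: int = 131
    group_length_cm: float = 141.0
    n_individuals: int = 138
    missing_rate: float = 0.01
    distortion_regions: tuple[DistortionRegion, ...] = field(
        default_factory=_default_distortion_regions
    )
    cluster_plants: tuple[ClusterPlant, ...] = field(
        default_factory=_default_cluster_plants
    )
    duplication: Optional[DuplicationPlan] = field(default_factory=DuplicationPlan)
    amplicons: AmpliconPlan = field(default_factory=AmpliconPlan)
    qtl_plans: tuple[QTLPlan, ...] = field(default_factory=_default_qtl_plans)

    def __post_init__(self):
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate outside [0, 1]")
        if not (0.0 <= self.amplicons.success_fraction <= 1.0):
            raise ValueError("success_fraction outside [0, 1]")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_STREAMS[stream],))
    )


def group_labels(n_groups: int) -> list[str]:
    """A/D-paired labels: A1..A{ceil(n/2)}, D1..D{floor(n/2)}."""
    n_a = (n_groups + 1) // 2
    return [f"A{i}" for i in range(1, n_a + 1)] + [
        f"D{i}" for i in range(1, n_groups - n_a + 1)
    ]


# ---------------------------------------------------------------------------
# Map generation
# ---------------------------------------------------------------------------

def generate_map(cfg: SimConfig) -> tuple[GeneticMap, dict]:
    """Generate a clustered multi-group map with planted duplications.

    Background loci are uniform on [0, group length]; cluster plants add
    tight windows of the planned marker-type mix; the duplication plan adds
    multi-locus markers whose loci land on homoeologous partners, the same
    chromosome, or unrelated chromosomes in the planned proportions.
    """
    rng = _rng(cfg, "map")
    labels = group_labels(cfg.n_groups)
    type_names = list(TYPE_FREQUENCIES)
    type_p = np.array(list(TYPE_FREQUENCIES.values()), dtype=float)
    type_p /= type_p.sum()

    loci_by_group: dict[str, list[Locus]] = {lbl: [] for lbl in labels}
    for lbl in labels:
        positions = np.sort(rng.uniform(0.0, cfg.group_length_cm, cfg.loci_per_group))
        types = rng.choice(type_names, size=cfg.loci_per_group, p=type_p)
        for i, (pos, mt) in enumerate(zip(positions, types)):
            loci_by_group[lbl].append(
                Locus(f"{lbl}-{i:03d}", str(mt), lbl, float(round(pos, 2)))
            )

    manifest: dict = {"clusters": [], "duplications": None}
    for pi, plant in enumerate(cfg.cluster_plants):
        if plant.group not in loci_by_group:
            raise ValueError(f"cluster plant group {plant.group!r} not in map")
        lo = plant.center - plant.span / 2.0
        hi = plant.center + plant.span / 2.0
        if lo < 0.0 or hi > cfg.group_length_cm:
            raise ValueError(
                f"cluster plant on {plant.group} at {plant.center} cM falls "
                f"outside [0, {cfg.group_length_cm}]"
            )
        names = []
        i = 0
        for mt, count in plant.type_counts:
            for _ in range(count):
                pos = float(round(lo + plant.span * rng.random(), 2))
                name = f"{plant.group}-p{pi}{chr(ord('a') + i)}"
                loci_by_group[plant.group].append(Locus(name, mt, plant.group, pos))
                names.append(name)
                i += 1
        manifest["clusters"].append(
            {"group": plant.group, "start": lo, "end": hi,
             "n_loci": plant.n_loci, "loci": names}
        )

    if cfg.duplication is not None:
        plan = cfg.duplication
        a_labels = [l for l in labels if l.startswith("A")]
        marker_to_loci: dict[str, list[str]] = {}
        locus_class: dict[str, str] = {}
        midx = 0
        for mult, count in plan.histogram:
            for _ in range(count):
                marker = f"DUP{midx:03d}"
                midx += 1
                groups: list[str] = []
                is_hom = rng.random() < plan.homoeolog_fraction
                if is_hom:
                    gi = str(rng.choice(a_labels))
                    groups = [gi, homoeolog_partner(gi)]
                    if mult == 4:
                        gj = str(rng.choice([a for a in a_labels if a != gi]))
                        groups += [gj, homoeolog_partner(gj)]
                    else:
                        pool = [l for l in labels if l not in groups]
                        groups += [str(g) for g in rng.choice(pool, mult - 2, replace=False)]
                else:
                    if rng.random() < plan.same_chromosome_fraction:
                        g = str(rng.choice(labels))
                        groups = [g] * 2
                    else:
                        g = str(rng.choice(a_labels))
                        partner = homoeolog_partner(g)
                        pool = [l for l in labels if l not in (g, partner)]
                        groups = [g, str(rng.choice(pool))]
                    while len(groups) < mult:
                        used = set(groups) | {homoeolog_partner(g) for g in groups}
                        pool = [l for l in labels if l not in used]
                        if not pool:  # few groups: fall back to any unused label
                            pool = [l for l in labels if l not in groups] or labels
                        groups.append(str(rng.choice(pool)))
                loci = []
                for li, g in enumerate(groups):
                    name = f"{marker}{chr(ord('a') + li)}"
                    pos = float(round(rng.uniform(0.0, cfg.group_length_cm), 2))
                    mt = "eSSR" if rng.random() < 0.5 else "gSSR"
                    loci_by_group[g].append(Locus(name, mt, g, pos))
                    loci.append(name)
                marker_to_loci[marker] = loci
        manifest["duplications"] = {
            "marker_to_loci": marker_to_loci,
            "histogram": {str(m): c for m, c in plan.histogram},
        }

    gmap = GeneticMap(
        LinkageGroup(lbl, loci) for lbl, loci in loci_by_group.items()
    )
    return gmap, manifest


# ---------------------------------------------------------------------------
# BC1 genotypes
# ---------------------------------------------------------------------------

def generate_bc1(gmap: GeneticMap, cfg: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate BC1 calls: each individual is heterozygous at a locus with
    probability 0.5 (fair transmission) or the region-specific ``p_het``
    inside a planted distortion region, independently across individuals;
    a ``missing_rate`` fraction of calls is blanked at random."""
    for region in cfg.distortion_regions:
        if region.group not in gmap:
            raise ValueError(f"distortion region group {region.group!r} not in map")
    rng = _rng(cfg, "bc1")
    loci = [l for l in gmap.loci()]
    p_het = np.full(len(loci), 0.5)
    region_truth = []
    for region in cfg.distortion_regions:
        members = [
            i for i, l in enumerate(loci)
            if l.group == region.group and region.start <= l.position <= region.end
        ]
        p_het[members] = region.p_het
        region_truth.append(
            {
                "group": region.group,
                "start": region.start,
                "end": region.end,
                "p_het": region.p_het,
                "direction": (
                    "toward_heterozygote" if region.p_het > 0.5
                    else "toward_recurrent" if region.p_het < 0.5 else "none"
                ),
                "loci": [loci[i].name for i in members],
            }
        )
    n_ind = cfg.n_individuals
    calls = np.where(
        rng.random((len(loci), n_ind)) < p_het[:, None], 3, 1
    ).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random((len(loci), n_ind)) < cfg.missing_rate] = 0
    gt = GenotypeMatrix(
        [l.name for l in loci],
        [f"BC1-{j:03d}" for j in range(n_ind)],
        calls,
    )
    return gt, {"regions": region_truth}


# ---------------------------------------------------------------------------
# Primer/template pools
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    """Introduce exactly n substitutions at distinct positions."""
    if n == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = str(rng.choice(alternatives))
    return "".join(out)


def generate_sequences(
    cfg: SimConfig, markers: Optional[Sequence[str]] = None
) -> tuple[list[PrimerPair], list[TemplateSeq], dict]:
    """Generate primer pairs and a template pool with planted amplicons.

    A ``success_fraction`` of the markers (exact count, rounded half-up)
    receive one EST template per species copy with the forward primer and
    reverse-complemented reverse primer planted around a random insert;
    substitution counts per primer cycle through the plan and are recorded.
    The first ``n_bac_markers`` successful markers are additionally planted
    into long BAC templates.  Failing markers contribute decoy templates
    with no primer sites.
    """
    plan = cfg.amplicons
    rng = _rng(cfg, "sequences")
    if markers is None:
        n = plan.n_markers if plan.n_markers is not None else 200
        markers = [f"M{i:04d}" for i in range(n)]
    elif plan.n_markers is not None:
        markers = list(markers)[: plan.n_markers]
    else:
        markers = list(markers)
    n = len(markers)
    n_success = int(round_half_away(n * plan.success_fraction, 0))
    success_idx = np.sort(rng.permutation(n)[:n_success])
    success = set(success_idx.tolist())

    pairs: list[PrimerPair] = []
    pool: list[TemplateSeq] = []
    truth: dict[str, dict] = {}
    est_counter = 0
    bac_counter = 0
    n_bac_planted = 0
    mm_cycle = plan.mismatch_counts
    for i, marker in enumerate(markers):
        fwd = _random_seq(rng, plan.primer_length)
        rev = _random_seq(rng, plan.primer_length)
        pairs.append(PrimerPair(marker, fwd, rev))
        entry: dict = {"success": i in success, "templates": [], "size_class": None}
        if i in success:
            mm_f = mm_cycle[i % len(mm_cycle)]
            mm_r = mm_cycle[(i // len(mm_cycle)) % len(mm_cycle)]
            n_extra = int(rng.integers(0, plan.extra_species_max + 1))
            extras = [
                str(s) for s in rng.choice(plan.species[1:], n_extra, replace=False)
            ]
            same_size = bool(rng.random() < plan.same_size_fraction)
            species_inserts = [(plan.species[0], plan.insert_length)]
            for e, sp in enumerate(extras):
                offset = 0 if same_size else plan.size_offset * (e + 1)
                species_inserts.append((sp, plan.insert_length + offset))
            if len(species_inserts) > 1:
                entry["size_class"] = "same" if same_size else "different"
            for sp, insert_len in species_inserts:
                prefix = _random_seq(rng, int(rng.integers(plan.flank_min, plan.flank_max + 1)))
                insert = _random_seq(rng, insert_len)
                suffix = _random_seq(rng, int(rng.integers(plan.flank_min, plan.flank_max + 1)))
                f_site = _mutate(fwd, mm_f, rng)
                r_site = _mutate(rev, mm_r, rng)
                seq = prefix + f_site + insert + reverse_complement(r_site) + suffix
                tid = f"EST{est_counter:05d}"
                est_counter += 1
                pool.append(TemplateSeq(tid, seq, species=sp, kind="EST"))
                entry["templates"].append(
                    {
                        "id": tid, "species": sp, "kind": "EST",
                        "offset_forward": len(prefix),
                        "product_size": len(fwd) + insert_len + len(rev),
                        "mm_forward": mm_f, "mm_reverse": mm_r,
                    }
                )
            if n_bac_planted < plan.n_bac_markers:
                n_bac_planted += 1
                flank = (plan.bac_length - plan.primer_length * 2 - plan.insert_length) // 2
                prefix = _random_seq(rng, flank)
                insert = _random_seq(rng, plan.insert_length)
                suffix = _random_seq(rng, flank)
                seq = prefix + fwd + insert + reverse_complement(rev) + suffix
                tid = f"BAC{bac_counter:03d}"
                bac_counter += 1
                pool.append(TemplateSeq(tid, seq, species=plan.species[0], kind="BAC"))
                entry["templates"].append(
                    {
                        "id": tid, "species": plan.species[0], "kind": "BAC",
                        "offset_forward": flank,
                        "product_size": plan.primer_length * 2 + plan.insert_length,
                        "mm_forward": 0, "mm_reverse": 0,
                    }
                )
        else:
            tid = f"EST{est_counter:05d}"
            est_counter += 1
            pool.append(
                TemplateSeq(
                    tid,
                    _random_seq(rng, int(rng.integers(plan.flank_min * 3, plan.flank_max * 3))),
                    species=str(rng.choice(plan.species)),
                    kind="EST",
                )
            )
        truth[marker] = entry
    manifest = {
        "n_markers": n,
        "n_success": n_success,
        "planted_success_pct": round_half_away(100.0 * n_success / n, 1),
        "markers": truth,
    }
    return pairs, pool, manifest


# ---------------------------------------------------------------------------
# QTL tables
# ---------------------------------------------------------------------------

def generate_qtl(gmap: GeneticMap, cfg: SimConfig) -> tuple[list[QTLRecord], dict]:
    """Materialize the planned QTL intervals against a generated map."""
    qtls = []
    truth = []
    for plan in cfg.qtl_plans:
        if plan.group not in gmap:
            raise ValueError(f"QTL plan group {plan.group!r} not in map")
        length = max((l.position for l in gmap[plan.group]), default=0.0)
        if plan.start < 0 or plan.end > max(length, cfg.group_length_cm):
            raise ValueError(
                f"QTL interval [{plan.start}, {plan.end}] outside group {plan.group}"
            )
        q = QTLRecord(plan.trait, plan.group, plan.start, plan.end, source="sim")
        qtls.append(q)
        inside = [
            l.name for l in gmap[plan.group]
            if plan.start <= l.position <= plan.end
        ]
        truth.append(
            {
                "trait": plan.trait, "group": plan.group,
                "start": plan.start, "end": plan.end,
                "width": plan.end - plan.start,
                "expected_excluded": plan.end - plan.start > 20.0,
                "loci_inside": inside,
            }
        )
    return qtls, {"qtls": truth}


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Everything one coherent synthetic study produces."""

    cfg: SimConfig
    gmap: GeneticMap
    genotypes: GenotypeMatrix
    pairs: list[PrimerPair]
    pool: list[TemplateSeq]
    qtls: list[QTLRecord]
    marker_to_loci: dict[str, list[str]]
    truth: dict


def simulate(cfg: SimConfig) -> SimBundle:
    """Run all generators with one config, wiring markers consistently:
    primer pairs are named after the map's sequence-based marker loci, so
    anchoring results can be placed back on the map."""
    gmap, map_truth = generate_map(cfg)
    genotypes, bc1_truth = generate_bc1(gmap, cfg)
    dup = (map_truth.get("duplications") or {}).get("marker_to_loci", {})
    dup_loci = {n for loci in dup.values() for n in loci}
    marker_to_loci = {
        l.name: [l.name] for l in gmap.loci() if l.name not in dup_loci
    }
    marker_to_loci.update(dup)
    # Markers whose loci fall inside a planted QTL interval go first (the
    # QTL plan is defined to overlap anchored markers); the rest follow in
    # group round-robin order, so a capped amplicon plan still covers every
    # chromosome.
    def _in_qtl(locus) -> bool:
        return any(
            p.group == locus.group and p.start <= locus.position <= p.end
            for p in cfg.qtl_plans
        )

    priority: list[str] = []
    per_group: dict[str, list[str]] = {lbl: [] for lbl in gmap.labels}
    for m, loci in sorted(marker_to_loci.items()):
        locus = gmap.locus(loci[0])
        if locus.marker_type not in SEQUENCE_BASED_TYPES:
            continue
        if any(_in_qtl(gmap.locus(n)) for n in loci):
            priority.append(m)
        else:
            per_group[locus.group].append(m)
    seq_markers = list(priority)
    queues = [q for q in per_group.values() if q]
    while queues:
        for q in queues:
            seq_markers.append(q.pop(0))
        queues = [q for q in queues if q]
    pairs, pool, seq_truth = generate_sequences(cfg, markers=seq_markers)
    qtls, qtl_truth = generate_qtl(gmap, cfg)
    truth = {
        "seed": cfg.seed,
        "map": map_truth,
        "bc1": bc1_truth,
        "sequences": seq_truth,
        "qtl": qtl_truth,
    }
    return SimBundle(cfg, gmap, genotypes, pairs, pool, qtls, marker_to_loci, truth)


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write the bundle in the exact formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": outdir / "map.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "primers": outdir / "primers.tsv",
        "pool": outdir / "pool.fasta",
        "qtl": outdir / "qtl.tsv",
        "markers": outdir / "markers.tsv",
        "truth": outdir / "truth.json",
    }
    write_map(bundle.gmap, paths["map"])
    write_genotypes(bundle.genotypes, paths["genotypes"])
    write_primers(bundle.pairs, paths["primers"])
    write_pool(bundle.pool, paths["pool"])
    write_qtls(bundle.qtls, paths["qtl"])
    with open(paths["markers"], "w") as fh:
        fh.write("marker\tlocus\n")
        for marker, loci in bundle.marker_to_loci.items():
            for locus in loci:
                fh.write(f"{marker}\t{locus}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
    return paths
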