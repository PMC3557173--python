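import numpy as np
import pytest

from linkmap.map_model import GeneticMap, LinkageGroup, Locus
from linkmap.synthetic_data import (
    AmpliconPlan,
    ClusterPlant,
    DistortionRegion,
    DuplicationPlan,
    QTLPlan,
    SimConfig,
)


def make_map(layout: dict) -> GeneticMap:
    """Build a map from {group: [(name, marker_type, position), ...]}."""
    return GeneticMap(
        LinkageGroup(lbl, [Locus(n, t, lbl, p) for n, t, p in loci])
        for lbl, loci in layout.items()
    )


def uniform_map(n_loci: int, n_groups: int, total_length: float) -> GeneticMap:
    """Evenly laid-out map with exactly the given totals (loci spread as
    evenly as possible across groups, equal group lengths)."""
    base, rem = divmod(n_loci, n_groups)
    counts = [base + 1] * rem + [base] * (n_groups - rem)
    length = total_length / n_groups
    n_a = (n_groups + 1) // 2
    labels = [f"A{i}" for i in range(1, n_a + 1)] + [
        f"D{i}" for i in range(1, n_groups - n_a + 1)
    ]
    groups = []
    for lbl, n in zip(labels, counts):
        positions = np.linspace(0.0, length, n)
        groups.append(
            LinkageGroup(
                lbl,
                [
                    Locus(f"{lbl}-{i}", "gSSR", lbl, float(p))
                    for i, p in enumerate(positions)
                ],
            )
        )
    return GeneticMap(groups)


@pytest.fixture
def toy_map() -> GeneticMap:
    return make_map(
        {"A1": [("m1", "gSSR", 0.0), ("m2", "eSSR", 5.0), ("m3", "gSSR", 12.0)]}
    )


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A 4-group scaled-down study for fast end-to-end tests."""
    defaults = dict(
        seed=seed,
        n_groups=4,
        loci_per_group=60,
        group_length_cm=60.0,
        n_individuals=138,
        distortion_regions=(
            DistortionRegion("A1", 10.0, 18.0, p_het=0.70),
            DistortionRegion("D2", 30.0, 38.0, p_het=0.30),
        ),
        cluster_plants=(
            ClusterPlant("A2", 20.0, 0.6, (("eSSR", 6),)),
            ClusterPlant("D1", 40.0, 0.9, (("REMAP", 9), ("gSSR", 3))),
        ),
        duplication=DuplicationPlan(histogram=((2, 8), (3, 2), (4, 1))),
        amplicons=AmpliconPlan(n_markers=40),
        qtl_plans=(
            QTLPlan("FL", "A1", 5.0, 20.0),
            QTLPlan("FS", "A1", 15.0, 28.0),
            QTLPlan("FF", "D2", 10.0, 36.0),  # 26 cM wide -> excluded
            QTLPlan("FU", "D1", 35.0, 50.0),
        ),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
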