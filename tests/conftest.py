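from __future__ import annotations

import numpy as np
import pytest

from sef.synthetic_data import (
    GroupSpec,
    MarkSpec,
    PlantedEcrSpec,
    PlantedMotifSpec,
    SimulationConfig,
    generate_study,
)

# Three groups, planted true ECRs (cross-group resampled), decoys
# (cross-group copied), and shared >= 8 bp motifs with group-specific
# offsets/strands inside the first five true ECRs.
BUNDLE_MOTIFS = ["GATTACAGT", "TTCGCGAAC", "CCATGGATC", "AAGGTCACG", "TGACGTCATT"]


def study_config(seed: int = 11) -> SimulationConfig:
    true_slots = [(0, 0), (0, 2), (1, 1), (2, 0), (2, 2), (3, 1), (4, 0), (4, 2), (5, 1), (5, 2)]
    decoy_slots = [(1, 0), (2, 1), (3, 0), (5, 0)]
    ecrs = [PlantedEcrSpec(g, i, length=200) for g, i in true_slots]
    ecrs += [PlantedEcrSpec(g, i, length=200, mode="copy") for g, i in decoy_slots]
    motifs = [
        PlantedMotifSpec(
            k,
            BUNDLE_MOTIFS[k],
            offsets={"fish": 20 + 11 * k, "rodent": 120 - 9 * k, "bird": 60 + 7 * k},
            strands={"fish": "+", "rodent": "-" if k % 2 else "+", "bird": "+"},
        )
        for k in range(5)
    ]
    return SimulationConfig(
        groups=[
            GroupSpec("fish", "(zfish:0.3,(fugu:0.25,tetra:0.25):0.15,medaka:0.35);"),
            GroupSpec("rodent", "(mouse:0.25,(rat:0.2,gpig:0.25):0.12,rabbit:0.3);"),
            GroupSpec("bird", "(chicken:0.25,finch:0.3,turkey:0.25);"),
        ],
        n_genes=6,
        exons_per_gene=4,
        intron_length=1000,
        planted_ecrs=ecrs,
        planted_motifs=motifs,
        mark_spec=MarkSpec(me1_fraction=1.0, me3_fraction=0.0, groups_with_marks=["fish", "rodent"]),
        intergroup_exon_divergence=0.10,
        seed=seed,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    cfg = study_config()
    return generate_study(cfg, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def bundle_cfg():
    return study_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
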