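from __future__ import annotations

import pytest

from frigg.core import run_grid
from frigg.model import GeneCluster, OrganismRecord, ProteinRecord, make_dataset
from frigg.synth import default_scenarios, generate_dataset


def build_dataset(organisms, families, clusters, sequences=None, validate=True):
    """Compact dataset builder for hand-written examples.

    organisms : {organism_id: section}
    families  : {family_id: [(organism_id, protein_id), ...]} — defines the
                full protein catalog
    clusters  : {cluster_id: (organism_id, [protein_id, ...])}
    """
    sequences = sequences or {}
    org_records = [
        OrganismRecord(organism_id=o, name=o, section=sec) for o, sec in organisms.items()
    ]
    keys = sorted({k for members in families.values() for k in members})
    prot_records = []
    for (org, pid) in keys:
        seq = sequences.get((org, pid))
        prot_records.append(
            ProteinRecord(
                organism_id=org,
                protein_id=pid,
                length_aa=len(seq) if seq else 100,
                sequence=seq,
            )
        )
    cluster_records = [
        GeneCluster(
            cluster_id=cid,
            organism_id=org,
            members=tuple(members),
            backbone_ids=frozenset([members[0]]),
        )
        for cid, (org, members) in clusters.items()
    ]
    return make_dataset(org_records, prot_records, cluster_records, families, validate=validate)


@pytest.fixture(scope="session")
def planted():
    """8-organism dataset with one instance of each scenario kind, seed 7."""
    dataset, manifest = generate_dataset(
        n_organisms=8, n_sections=2, scenarios=default_scenarios(), seed=7
    )
    return dataset, manifest


@pytest.fixture(scope="session")
def planted_grid(planted):
    dataset, _ = planted
    return run_grid(dataset)
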