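"""Deterministic synthetic multi-genome datasets with planted resistance
architectures, decoys, and a ground-truth manifest.

Each scenario kind maps to a fixed expected fate in the pipeline:

===========================   ==========================================
kind                          expected fate
===========================   ==========================================
true_resistance_recurrent     final (survives every setting)
fellutamide_like_singleton    eliminated@step3 (final iff step 3 skipped)
mpa_like_step2_decoy          eliminated@step2 (under both patterns)
nonessential_dup_step4_decoy  eliminated@step4
multicopy_step5_decoy         eliminated@step5
tailoring_large_family        final@alternative (step-2 reject under strict)
===========================   ==========================================

Background content (essential single-copy families, organism-private
singletons, clusters made of singleton-family genes) never produces a
candidate, so a background-only dataset yields zero selections.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import io as frigg_io
from .model import (
    AA_ALPHABET,
    Dataset,
    FriggError,
    GeneCluster,
    OrganismRecord,
    PipelineConfig,
    ProteinKey,
    ProteinRecord,
    make_dataset,
)

PathLike = Union[str, Path]

SCENARIO_KINDS = (
    "true_resistance_recurrent",
    "fellutamide_like_singleton",
    "mpa_like_step2_decoy",
    "nonessential_dup_step4_decoy",
    "multicopy_step5_decoy",
    "tailoring_large_family",
)

FATES = (
    "final",
    "final@alternative",
    "eliminated@step2",
    "eliminated@step3",
    "eliminated@step4",
    "eliminated@step5",
)

KIND_TO_FATE = {
    "true_resistance_recurrent": "final",
    "fellutamide_like_singleton": "eliminated@step3",
    "mpa_like_step2_decoy": "eliminated@step2",
    "nonessential_dup_step4_decoy": "eliminated@step4",
    "multicopy_step5_decoy": "eliminated@step5",
    "tailoring_large_family": "final@alternative",
}

#: number of candidate clusters planted per scenario instance
KIND_N_CLUSTERS = {
    "true_resistance_recurrent": 2,
    "fellutamide_like_singleton": 1,
    "mpa_like_step2_decoy": 1,
    "nonessential_dup_step4_decoy": 2,
    "multicopy_step5_decoy": 2,
    "tailoring_large_family": 2,
}


@dataclass(frozen=True)
class ScenarioSpec:
    kind: str
    n_instances: int = 1
    hosts: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise FriggError(f"unknown scenario kind {self.kind!r}")
        if self.n_instances < 1:
            raise FriggError("n_instances must be >= 1")


@dataclass(frozen=True)
class PlantedInstance:
    """One manifest row: a planted candidate cluster and its expected fate."""

    instance_id: str
    cluster_id: str
    organism_id: str
    resistance_protein_id: str
    family_id: str
    expected_fate: str


@dataclass(frozen=True)
class BackgroundParams:
    n_essential_families: int = 8
    n_private_singletons: int = 3  # per organism
    n_background_clusters: int = 2  # per organism
    cluster_size_range: tuple[int, int] = (4, 19)
    seq_length_range: tuple[int, int] = (120, 300)


def default_scenarios() -> tuple[ScenarioSpec, ...]:
    """One instance of each of the six scenario kinds."""
    return tuple(ScenarioSpec(kind=k) for k in SCENARIO_KINDS)


# ---------------------------------------------------------------------------
# sequence mutation


def _stable_seed(*parts: object) -> int:
    return zlib.crc32(":".join(str(p) for p in parts).encode())


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def random_sequence(length: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(AA_ALPHABET) for _ in range(length))


def mutate_sequence(parent_sequence: str, target_identity: float, seed: int) -> str:
    """Derive a child sequence by point substitutions at an exact identity.

    The number of conserved positions is ``round(target_identity% * length)``
    (half away from zero), so the realized identity is exactly that count over
    the length.  Deterministic for a fixed seed.
    """
    if not parent_sequence:
        raise FriggError("parent sequence must be nonempty")
    if not 0 < target_identity <= 100:
        raise FriggError("target_identity must be in (0, 100]")
    length = len(parent_sequence)
    matches = _round_half_away(target_identity * length / 100.0)
    if matches < 1:
        raise FriggError(
            f"target_identity {target_identity} leaves no conserved position "
            f"for length {length}"
        )
    n_sub = length - matches
    rng = random.Random(seed)
    positions = set(rng.sample(range(length), n_sub))
    out = []
    for i, res in enumerate(parent_sequence):
        if i in positions:
            choices = AA_ALPHABET.replace(res, "")
            out.append(rng.choice(choices))
        else:
            out.append(res)
    return "".join(out)


# ---------------------------------------------------------------------------
# dataset builder


class _Builder:
    """Accumulates proteins, families and clusters with deterministic ids."""

    def __init__(self, organism_ids: Sequence[str]):
        self.organism_ids = list(organism_ids)
        self._prot_counter = {org: 0 for org in organism_ids}
        self._cluster_counter = {org: 0 for org in organism_ids}
        self._fam_counter = 0
        self.protein_keys: list[ProteinKey] = []
        self.families: dict[str, list[ProteinKey]] = {}
        self.clusters: list[GeneCluster] = []
        self.interpro: dict[ProteinKey, frozenset[str]] = {}
        self._host_pointer = 0

    def new_protein(self, org: str) -> str:
        self._prot_counter[org] += 1
        pid = f"g{self._prot_counter[org]:04d}"
        self.protein_keys.append((org, pid))
        return pid

    def new_family(self, members: Sequence[ProteinKey] = ()) -> str:
        self._fam_counter += 1
        fid = f"FAM{self._fam_counter:04d}"
        self.families[fid] = list(members)
        return fid

    def add_member(self, fid: str, key: ProteinKey) -> None:
        self.families[fid].append(key)

    def singleton(self, org: str) -> tuple[str, str]:
        """New protein in its own family; returns (protein_id, family_id)."""
        pid = self.new_protein(org)
        fid = self.new_family([(org, pid)])
        return pid, fid

    def new_cluster(self, org: str, member_pids: Sequence[str], backbone: str) -> str:
        self._cluster_counter[org] += 1
        cid = f"{org}.c{self._cluster_counter[org]:02d}"
        self.clusters.append(
            GeneCluster(
                cluster_id=cid,
                organism_id=org,
                members=tuple(member_pids),
                backbone_ids=frozenset([backbone]),
            )
        )
        return cid

    def next_hosts(self, k: int) -> list[str]:
        """Pick k distinct host organisms, rotating across calls."""
        n = len(self.organism_ids)
        if k > n:
            raise FriggError(f"scenario needs {k} host organisms, dataset has {n}")
        hosts = [self.organism_ids[(self._host_pointer + i) % n] for i in range(k)]
        self._host_pointer = (self._host_pointer + k) % n
        return hosts


def _plant_resistance_family(
    b: _Builder,
    span_orgs: Sequence[str],
    host_orgs: Sequence[str],
    extra_multicopy_orgs: Sequence[str] = (),
) -> tuple[str, dict[str, str]]:
    """Create a resistance-style family.

    Every organism in ``span_orgs`` gets one free-standing (target) copy;
    ``extra_multicopy_orgs`` get a second free copy; each host organism gets
    one additional member reserved for cluster placement.  Returns
    (family_id, {host_org: cluster member protein_id}).
    """
    if not set(host_orgs) <= set(span_orgs):
        raise FriggError("host organisms must be within the family's span")
    fid = b.new_family()
    for org in span_orgs:
        b.add_member(fid, (org, b.new_protein(org)))
    for org in extra_multicopy_orgs:
        b.add_member(fid, (org, b.new_protein(org)))
    cluster_members: dict[str, str] = {}
    for org in host_orgs:
        pid = b.new_protein(org)
        b.add_member(fid, (org, pid))
        cluster_members[org] = pid
    return fid, cluster_members


def _build_scenario_cluster(
    b: _Builder,
    org: str,
    rng: random.Random,
    resistance_pid: str,
    extra_pids: Sequence[str] = (),
    n_fill: Optional[int] = None,
) -> str:
    """Assemble a cluster: singleton backbone, resistance gene, any extra
    planted genes, plus singleton tailoring fill."""
    backbone, _ = b.singleton(org)
    if n_fill is None:
        n_fill = rng.randint(2, 5)
    fill = [b.singleton(org)[0] for _ in range(n_fill)]
    members = [backbone, resistance_pid, *extra_pids, *fill]
    return b.new_cluster(org, members, backbone)


def _plant_scenario(
    b: _Builder,
    kind: str,
    instance_idx: int,
    hosts: Optional[Sequence[str]],
    rng: random.Random,
) -> list[PlantedInstance]:
    all_orgs = b.organism_ids
    n = len(all_orgs)
    n_clusters = KIND_N_CLUSTERS[kind]
    host_list = list(hosts) if hosts else b.next_hosts(n_clusters)
    if len(host_list) != n_clusters:
        raise FriggError(f"{kind}: expected {n_clusters} host organism(s), got {len(host_list)}")
    if len(set(host_list)) != len(host_list):
        raise FriggError(f"{kind}: host organisms must be distinct")

    extra_multicopy: list[str] = []
    if kind == "nonessential_dup_step4_decoy":
        # family present in well under 90% of the organisms
        max_span = -(-9 * n // 10) - 1  # ceil(0.9 n) - 1
        span_count = max(len(host_list), n // 2)
        if span_count > max_span:
            raise FriggError(
                f"{kind}: cannot plant a non-essential family with {n} organisms"
            )
        non_hosts = [o for o in all_orgs if o not in host_list]
        span = sorted(set(host_list) | set(non_hosts[: span_count - len(host_list)]))
    elif kind == "multicopy_step5_decoy":
        span = list(all_orgs)
        need_multi = n // 2 + 1  # strictly more than half
        extra_needed = need_multi - len(host_list)
        if extra_needed > len(all_orgs) - len(host_list):
            raise FriggError(f"{kind}: not enough organisms for a multicopy majority")
        extra_multicopy = [o for o in all_orgs if o not in host_list][: max(extra_needed, 0)]
    else:
        span = list(all_orgs)

    fid, in_cluster = _plant_resistance_family(b, span, host_list, extra_multicopy)

    large_fid: Optional[str] = None
    if kind == "tailoring_large_family":
        # dataset-wide size 3n + n_clusters, strictly above a cutoff of 3n
        large_fid = b.new_family()
        for org in all_orgs:
            for _ in range(3):
                b.add_member(large_fid, (org, b.new_protein(org)))
        for key in b.families[large_fid]:
            b.interpro[key] = frozenset(["IPR900001"])

    rows: list[PlantedInstance] = []
    for j, org in enumerate(host_list, start=1):
        extra_pids: list[str] = []
        if kind == "mpa_like_step2_decoy":
            # a small-family tailoring gene with a free homolog in the host:
            # second multi-copy member, so step 2 rejects under both patterns
            mf = b.new_family()
            mf_pid = b.new_protein(org)
            b.add_member(mf, (org, mf_pid))
            b.add_member(mf, (org, b.new_protein(org)))  # free copy in host
            for other in [o for o in all_orgs if o != org][:2]:
                b.add_member(mf, (other, b.new_protein(other)))
            extra_pids.append(mf_pid)
        if kind == "tailoring_large_family":
            assert large_fid is not None
            lf_pid = b.new_protein(org)
            b.add_member(large_fid, (org, lf_pid))
            b.interpro[(org, lf_pid)] = frozenset(["IPR900001"])
            extra_pids.append(lf_pid)
        cid = _build_scenario_cluster(b, org, rng, in_cluster[org], extra_pids)
        rows.append(
            PlantedInstance(
                instance_id=f"{kind}#{instance_idx}.{j}",
                cluster_id=cid,
                organism_id=org,
                resistance_protein_id=in_cluster[org],
                family_id=fid,
                expected_fate=KIND_TO_FATE[kind],
            )
        )
    return rows


def _plant_background(b: _Builder, params: BackgroundParams, rng: random.Random) -> None:
    for _ in range(params.n_essential_families):
        fid = b.new_family()
        for org in b.organism_ids:
            b.add_member(fid, (org, b.new_protein(org)))
    for org in b.organism_ids:
        for _ in range(params.n_background_clusters):
            size = rng.randint(*params.cluster_size_range)
            pids = [b.singleton(org)[0] for _ in range(size)]
            b.new_cluster(org, pids, backbone=pids[0])
    for org in b.organism_ids:
        for _ in range(params.n_private_singletons):
            b.singleton(org)


def generate_dataset(
    n_organisms: int = 8,
    n_sections: int = 2,
    background: Optional[BackgroundParams] = None,
    scenarios: Sequence[ScenarioSpec] = (),
    seed: int = 0,
    with_sequences: bool = True,
) -> tuple[Dataset, list[PlantedInstance]]:
    """Generate a validated dataset plus its truth manifest.

    Deterministic: the same arguments always produce the same in-memory
    dataset (and therefore byte-identical files via :func:`write_dataset`).
    """
    if n_organisms < 2:
        raise FriggError("n_organisms must be >= 2")
    if n_sections < 1:
        raise FriggError("n_sections must be >= 1")
    background = background or BackgroundParams()
    rng = random.Random(seed)

    organism_ids = [f"org{i:02d}" for i in range(1, n_organisms + 1)]
    sections = {
        org: f"sec{(i % n_sections) + 1:02d}" for i, org in enumerate(organism_ids)
    }

    b = _Builder(organism_ids)
    manifest: list[PlantedInstance] = []
    for spec in scenarios:
        for i in range(1, spec.n_instances + 1):
            manifest.extend(_plant_scenario(b, spec.kind, i, spec.hosts, rng))
    _plant_background(b, background, rng)

    # assign sequences family by family so members are mutually homologous
    sequences: dict[ProteinKey, str] = {}
    if with_sequences:
        lo, hi = background.seq_length_range
        for fid in sorted(b.families):
            fam_rng = random.Random(_stable_seed(seed, fid))
            length = fam_rng.randint(lo, hi)
            members = sorted(b.families[fid])
            parent = random_sequence(length, _stable_seed(seed, fid, "parent"))
            for i, key in enumerate(members):
                if i == 0:
                    sequences[key] = parent
                else:
                    identity = fam_rng.randint(60, 90)
                    sequences[key] = mutate_sequence(
                        parent, identity, _stable_seed(seed, fid, key[0], key[1])
                    )

    per_org_counts = {org: 0 for org in organism_ids}
    for (org, _pid) in b.protein_keys:
        per_org_counts[org] += 1
    organisms = [
        OrganismRecord(
            organism_id=org,
            name=f"Synthovirens_{org}",
            section=sections[org],
            n_proteins=per_org_counts[org],
        )
        for org in organism_ids
    ]
    proteins = []
    for key in b.protein_keys:
        org, pid = key
        seq = sequences.get(key)
        length = len(seq) if seq is not None else 100 + (_stable_seed(seed, org, pid) % 200)
        proteins.append(
            ProteinRecord(
                organism_id=org,
                protein_id=pid,
                length_aa=length,
                interpro_ids=b.interpro.get(key, frozenset()),
                sequence=seq,
            )
        )
    dataset = make_dataset(
        organisms,
        proteins,
        b.clusters,
        families={fid: frozenset(m) for fid, m in b.families.items()},
    )
    return dataset, manifest


# ---------------------------------------------------------------------------
# serialization


MANIFEST_COLUMNS = [
    "instance_id",
    "cluster_id",
    "organism_id",
    "resistance_protein_id",
    "family_id",
    "expected_fate",
]


def write_manifest(manifest: Sequence[PlantedInstance], path: PathLike) -> None:
    import pandas as pd

    rows = [
        {c: getattr(m, c) for c in MANIFEST_COLUMNS}
        for m in sorted(manifest, key=lambda m: m.instance_id)
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> list[PlantedInstance]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FriggError(f"manifest {path} missing column(s): {missing}")
    return [
        PlantedInstance(**{c: str(getattr(r, c)) for c in MANIFEST_COLUMNS})
        for r in df.itertuples(index=False)
    ]


def write_blast_hits(dataset: Dataset, path: PathLike, seed: int = 0) -> None:
    """Emit a synthetic BLAST-tabular hit file consistent with the family
    partition: chains of reciprocal full-coverage hits inside each family
    (exercising single-linkage transitivity) plus sub-threshold noise."""
    assert dataset.families is not None
    lines: list[str] = []

    def fmt(q: ProteinKey, s: ProteinKey, pident: float, qfrac: float = 1.0) -> str:
        ql = dataset.proteins[q].length_aa
        sl = dataset.proteins[s].length_aa
        qe = max(1, int(ql * qfrac))
        se = max(1, int(sl * qfrac))
        aln = max(qe, se)
        return "\t".join(
            [
                f"{q[0]}|{q[1]}",
                f"{s[0]}|{s[1]}",
                f"{pident:.1f}",
                str(aln),
                "0",
                "0",
                "1",
                str(qe),
                "1",
                str(se),
                "1e-50",
                "200.0",
            ]
        )

    fam_ids = sorted(dataset.families)
    firsts: list[ProteinKey] = []
    for fid in fam_ids:
        members = sorted(dataset.families[fid])
        firsts.append(members[0])
        for a, b2 in zip(members, members[1:]):
            lines.append(fmt(a, b2, 80.0))
            lines.append(fmt(b2, a, 80.0))
    # noise: sub-identity and sub-coverage cross-family hits, plus a self-hit
    rng = random.Random(seed)
    for i in range(0, len(firsts) - 1, 7):
        a, b2 = firsts[i], firsts[i + 1]
        lines.append(fmt(a, b2, rng.uniform(20.0, 40.0)))
        lines.append(fmt(b2, a, rng.uniform(20.0, 40.0)))
    if len(firsts) >= 4:
        a, b2 = firsts[0], firsts[3]
        lines.append(fmt(a, b2, 90.0, qfrac=0.3))
        lines.append(fmt(b2, a, 90.0, qfrac=0.3))
    if firsts:
        lines.append(fmt(firsts[0], firsts[0], 100.0))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_dataset(
    dataset: Dataset,
    manifest: Sequence[PlantedInstance],
    out_dir: PathLike,
    with_fasta: bool = True,
    with_hits: bool = False,
    seed: int = 0,
) -> dict[str, Path]:
    """Write the dataset in the canonical schemas; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.tsv",
        "clusters": out / "clusters.tsv",
        "families": out / "families.tsv",
        "manifest": out / "manifest.tsv",
    }
    frigg_io.write_protein_table(dataset, paths["proteins"])
    frigg_io.write_cluster_table(dataset, paths["clusters"])
    assert dataset.families is not None
    frigg_io.write_family_table(dataset.families, paths["families"])
    write_manifest(manifest, paths["manifest"])
    if with_fasta:
        paths["fasta"] = out / "proteins.faa"
        frigg_io.write_sequences_fasta(dataset, paths["fasta"])
    if with_hits:
        paths["hits"] = out / "hits.tsv"
        write_blast_hits(dataset, paths["hits"], seed=seed)
    return paths


# ---------------------------------------------------------------------------
# fate semantics


def expected_presence(fate: str, config: PipelineConfig) -> dict[str, bool]:
    """Whether a planted cluster should be present after each applied step.

    Keys are the steps applied under ``config`` (step3 omitted when skipped,
    step5 omitted when not applied).
    """
    if fate not in FATES:
        raise FriggError(f"unknown fate {fate!r}")
    selected = fate != "eliminated@step2" and not (
        fate == "final@alternative" and config.pattern == "strict"
    )
    out: dict[str, bool] = {"step2": selected}
    alive = selected
    if not config.skip_step3:
        if fate == "eliminated@step3":
            alive = False
        out["step3"] = alive
    if fate == "eliminated@step4":
        alive = False
    out["step4"] = alive
    if config.apply_step5:
        if fate == "eliminated@step5":
            alive = False
        out["step5"] = alive
    return out


def expected_in_final(fate: str, config: PipelineConfig) -> bool:
    presence = expected_presence(fate, config)
    last = "step5" if config.apply_step5 else "step4"
    return presence[last]
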