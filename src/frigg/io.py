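"""Readers and writers for the canonical TSV schemas, FASTA, and YAML config.

Canonical schemas
-----------------
protein table   organism_id, protein_id, length_aa, section, interpro_ids
                (interpro_ids semicolon-joined, may be empty)
cluster table   cluster_id, organism_id, member_rank, protein_id, is_backbone
family table    family_id, organism_id, protein_id
FASTA export    ><organism_name>|<section>|<protein_id>|<copies>|<label>

Proteins absent from a supplied family table are completed into singleton
families with deterministic ``FS``-prefixed ids so that a loaded dataset
always carries a full partition.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Dataset,
    FormatError,
    GeneCluster,
    IntegrityError,
    OrganismRecord,
    PipelineConfig,
    ProteinKey,
    ProteinRecord,
    make_dataset,
)

PROTEIN_COLUMNS = ["organism_id", "protein_id", "length_aa", "section", "interpro_ids"]
CLUSTER_COLUMNS = ["cluster_id", "organism_id", "member_rank", "protein_id", "is_backbone"]
FAMILY_COLUMNS = ["family_id", "organism_id", "protein_id"]

CONTEXT_LABELS = ("StrictClust", "Clust", "0", "outsideSC")

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{what} table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table {path} is missing column(s): {missing}")
    return df


def read_protein_table(path: PathLike) -> tuple[list[OrganismRecord], list[ProteinRecord]]:
    """Parse the protein table; organisms are derived from its rows."""
    df = _read_tsv(path, PROTEIN_COLUMNS, "protein")
    proteins: list[ProteinRecord] = []
    sections: dict[str, str] = {}
    per_org: dict[str, int] = {}
    for row in df.itertuples(index=False):
        org = str(row.organism_id)
        try:
            length = int(row.length_aa)
        except ValueError as exc:
            raise FormatError(
                f"protein table: non-integer length_aa {row.length_aa!r} "
                f"for {org}/{row.protein_id}"
            ) from exc
        ipr = frozenset(t for t in str(row.interpro_ids).split(";") if t)
        proteins.append(
            ProteinRecord(
                organism_id=org,
                protein_id=str(row.protein_id),
                length_aa=length,
                interpro_ids=ipr,
            )
        )
        prev = sections.setdefault(org, str(row.section))
        if prev != str(row.section):
            raise IntegrityError(
                f"organism {org!r} listed with conflicting sections "
                f"{prev!r} and {row.section!r}"
            )
        per_org[org] = per_org.get(org, 0) + 1
    organisms = [
        OrganismRecord(organism_id=o, name=o, section=sections[o], n_proteins=per_org[o])
        for o in sorted(sections)
    ]
    return organisms, proteins


def read_cluster_table(path: PathLike) -> list[GeneCluster]:
    df = _read_tsv(path, CLUSTER_COLUMNS, "cluster")
    if df.empty:
        return []
    clusters: list[GeneCluster] = []
    for (cid, org), grp in df.groupby(["cluster_id", "organism_id"], sort=True):
        grp = grp.copy()
        grp["member_rank"] = grp["member_rank"].astype(int)
        grp = grp.sort_values("member_rank")
        members = tuple(grp["protein_id"])
        backbone = frozenset(
            p for p, b in zip(grp["protein_id"], grp["is_backbone"]) if str(b) == "1"
        )
        clusters.append(
            GeneCluster(
                cluster_id=str(cid),
                organism_id=str(org),
                members=members,
                backbone_ids=backbone,
            )
        )
    ids = [c.cluster_id for c in clusters]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"cluster id(s) span multiple organisms: {dupes}")
    return clusters


def read_family_table(path: PathLike) -> dict[str, frozenset[ProteinKey]]:
    df = _read_tsv(path, FAMILY_COLUMNS, "family")
    families: dict[str, set[ProteinKey]] = {}
    for row in df.itertuples(index=False):
        families.setdefault(str(row.family_id), set()).add(
            (str(row.organism_id), str(row.protein_id))
        )
    return {fid: frozenset(m) for fid, m in families.items()}


def _complete_partition(
    families: dict[str, frozenset[ProteinKey]], proteins: Iterable[ProteinKey]
) -> dict[str, frozenset[ProteinKey]]:
    """Add deterministic singleton families for uncovered proteins."""
    covered: set[ProteinKey] = set()
    for members in families.values():
        covered |= members
    out = dict(families)
    for i, key in enumerate(sorted(set(proteins) - covered), start=1):
        out[f"FS{i:06d}"] = frozenset([key])
    return out


def attach_sequences(proteins: dict[ProteinKey, ProteinRecord], fasta_paths: Iterable[PathLike]) -> dict[ProteinKey, ProteinRecord]:
    """Attach sequences from FASTA files.

    Record ids are matched as ``organism_id|protein_id`` or, failing that, as
    a bare protein id when that id is unique dataset-wide.
    """
    by_pair = {f"{o}|{p}": (o, p) for (o, p) in proteins}
    by_bare: dict[str, Optional[ProteinKey]] = {}
    for (o, p) in proteins:
        by_bare[p] = None if p in by_bare else (o, p)

    updated = dict(proteins)
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            token = rec.id
            key = by_pair.get(token)
            if key is None:
                key = by_bare.get(token)
            if key is None:
                raise IntegrityError(f"FASTA id {token!r} does not resolve to a catalog protein")
            old = updated[key]
            seq = str(rec.seq)
            if len(seq) != old.length_aa:
                raise IntegrityError(
                    f"FASTA sequence for {key} has length {len(seq)}, "
                    f"catalog says {old.length_aa}"
                )
            updated[key] = ProteinRecord(
                organism_id=old.organism_id,
                protein_id=old.protein_id,
                length_aa=old.length_aa,
                interpro_ids=old.interpro_ids,
                sequence=seq,
            )
    return updated


def load_dataset(
    protein_table_path: PathLike,
    cluster_table_path: PathLike,
    family_table_path: Optional[PathLike] = None,
    fasta_paths: Optional[Sequence[PathLike]] = None,
) -> Dataset:
    """Load and cross-validate a dataset from the canonical tables.

    Returns a validated :class:`~frigg.model.Dataset`; when a family table is
    supplied the partition is completed with singleton families for any
    uncovered proteins.
    """
    organisms, proteins = read_protein_table(protein_table_path)
    clusters = read_cluster_table(cluster_table_path)
    families = None
    if family_table_path is not None:
        families = read_family_table(family_table_path)
        families = _complete_partition(families, (p.key for p in proteins))
    prot_map = {p.key: p for p in proteins}
    if fasta_paths:
        prot_map = attach_sequences(prot_map, fasta_paths)
    return make_dataset(organisms, prot_map.values(), clusters, families)


# ---------------------------------------------------------------------------
# writers


def write_protein_table(dataset: Dataset, path: PathLike) -> None:
    rows = []
    for key in sorted(dataset.proteins):
        p = dataset.proteins[key]
        rows.append(
            {
                "organism_id": p.organism_id,
                "protein_id": p.protein_id,
                "length_aa": p.length_aa,
                "section": dataset.organisms[p.organism_id].section,
                "interpro_ids": ";".join(sorted(p.interpro_ids)),
            }
        )
    pd.DataFrame(rows, columns=PROTEIN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cluster_table(dataset: Dataset, path: PathLike) -> None:
    rows = []
    for cid in sorted(dataset.clusters):
        cl = dataset.clusters[cid]
        for rank, pid in enumerate(cl.members):
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "organism_id": cl.organism_id,
                    "member_rank": rank,
                    "protein_id": pid,
                    "is_backbone": int(pid in cl.backbone_ids),
                }
            )
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


def write_family_table(families: Mapping[str, frozenset[ProteinKey]], path: PathLike) -> None:
    rows = []
    for fid in sorted(families):
        for (org, pid) in sorted(families[fid]):
            rows.append({"family_id": fid, "organism_id": org, "protein_id": pid})
    pd.DataFrame(rows, columns=FAMILY_COLUMNS).to_csv(path, sep="\t", index=False)


def write_sequences_fasta(dataset: Dataset, path: PathLike) -> None:
    """Plain input-style FASTA with ``organism_id|protein_id`` ids."""
    records = []
    for key in sorted(dataset.proteins):
        p = dataset.proteins[key]
        if p.sequence is None:
            raise FriggMissingSequence([key])
        records.append(SeqRecord(Seq(p.sequence), id=f"{p.organism_id}|{p.protein_id}", description=""))
    SeqIO.write(records, str(path), "fasta")


class FriggMissingSequence(IntegrityError):
    def __init__(self, members: list[ProteinKey]):
        self.members = members
        super().__init__(f"protein(s) lack sequences: {sorted(members)}")


def write_family_fasta(
    family_id: str,
    dataset: Dataset,
    context_labels: Mapping[ProteinKey, str],
    out_path: PathLike,
) -> None:
    """Export one family to FASTA with structured five-field headers.

    Header: ``organism_name|section|protein_id|copies|label`` where copies is
    the number of family members in that organism and label one of
    ``StrictClust``, ``Clust``, ``0``, ``outsideSC``.  Records are ordered by
    (organism_id, protein_id).
    """
    if dataset.families is None or family_id not in dataset.families:
        raise IntegrityError(f"unknown family_id {family_id!r}")
    members = sorted(dataset.families[family_id])
    missing = [k for k in members if dataset.proteins[k].sequence is None]
    if missing:
        raise FriggMissingSequence(missing)

    per_org: dict[str, int] = {}
    for (org, _pid) in members:
        per_org[org] = per_org.get(org, 0) + 1

    records = []
    for key in members:
        org, pid = key
        label = context_labels.get(key, "0")
        if label not in CONTEXT_LABELS:
            raise FormatError(f"invalid context label {label!r} for {key}")
        organism = dataset.organisms[org]
        header = f"{organism.name}|{organism.section}|{pid}|{per_org[org]}|{label}"
        records.append(SeqRecord(Seq(dataset.proteins[key].sequence), id=header, description=""))
    SeqIO.write(records, str(out_path), "fasta")


def parse_family_fasta_headers(path: PathLike) -> list[dict[str, str]]:
    """Re-parse a family FASTA export; returns one dict per record."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) != 5:
            raise FormatError(f"malformed family-FASTA header: {rec.id!r}")
        name, section, pid, copies, label = fields
        out.append(
            {
                "organism_name": name,
                "section": section,
                "protein_id": pid,
                "copies": copies,
                "label": label,
                "sequence": str(rec.seq),
            }
        )
    return out


# ---------------------------------------------------------------------------
# config


def load_config(path: PathLike, overrides: Optional[Mapping[str, object]] = None) -> PipelineConfig:
    """Read a YAML config file; ``overrides`` (e.g. CLI flags) win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
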