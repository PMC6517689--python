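"""Core domain types: organisms, proteins, clusters, family partitions and run
configuration.

All pipeline stages operate on a validated :class:`Dataset`.  Proteins are
addressed by ``(organism_id, protein_id)`` pairs throughout; sequences are
optional and only required for FASTA export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

#: amino-acid alphabet used by the synthetic generator
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: dataset-wide protein address
ProteinKey = tuple[str, str]

PATTERNS = ("strict", "alternative")

#: lowest recommended value for the large-family multiplier; smaller values
#: risk exempting genuine resistance families and only raise a warning.
MIN_RECOMMENDED_X = 1.5


class FriggError(Exception):
    """Base class for all package errors."""


class FormatError(FriggError):
    """An input table or file does not conform to the documented schema."""


class IntegrityError(FriggError):
    """Cross-references between tables are inconsistent."""


@dataclass(frozen=True)
class OrganismRecord:
    """One genome in the dataset."""

    organism_id: str
    name: str
    section: str
    n_proteins: int = 0

    def __post_init__(self) -> None:
        if not self.organism_id:
            raise FormatError("organism_id must be nonempty")
        if not self.section:
            raise FormatError(f"organism {self.organism_id!r}: section must be nonempty")
        if self.n_proteins < 0:
            raise FormatError(f"organism {self.organism_id!r}: n_proteins must be >= 0")


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein; ``sequence`` is optional (counts-only analyses do
    not need it, FASTA export does)."""

    organism_id: str
    protein_id: str
    length_aa: int
    interpro_ids: frozenset[str] = frozenset()
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise FormatError(f"protein {self.key}: length_aa must be positive")
        if self.sequence is not None and len(self.sequence) != self.length_aa:
            raise FormatError(
                f"protein {self.key}: sequence length {len(self.sequence)} "
                f"!= length_aa {self.length_aa}"
            )

    @property
    def key(self) -> ProteinKey:
        return (self.organism_id, self.protein_id)


@dataclass(frozen=True)
class GeneCluster:
    """A predicted secondary-metabolite gene cluster (ordered member list)."""

    cluster_id: str
    organism_id: str
    members: tuple[str, ...]
    backbone_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"cluster {self.cluster_id!r}: members must be nonempty")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"cluster {self.cluster_id!r}: duplicate member protein ids")
        extra = self.backbone_ids - set(self.members)
        if extra:
            raise FormatError(
                f"cluster {self.cluster_id!r}: backbone ids not among members: {sorted(extra)}"
            )

    @property
    def member_keys(self) -> tuple[ProteinKey, ...]:
        return tuple((self.organism_id, p) for p in self.members)


@dataclass
class PipelineConfig:
    """Run configuration for the five-step pipeline.

    Parameters
    ----------
    pattern
        Cluster selection pattern at step 2: ``"strict"`` or ``"alternative"``.
    x_input
        Large-family multiplier for the alternative pattern; families with
        more than ``x_input * n_organisms`` members dataset-wide are exempt
        from the homolog constraint and ineligible as resistance genes.
    skip_step3
        Skip the recurrence filter (step 3).
    essential_pct
        Step 4 retains candidates whose resistance family has members in at
        least this percentage of all organisms.
    apply_step5
        Whether to apply the single-copy-majority filter (step 5).
    majority_pct
        Step 5 removes candidates whose resistance family is multi-copy in
        strictly more than this percentage of organisms.
    step3_distinct_organisms
        If set, step 3 additionally requires the recurrent candidate clusters
        to come from at least two distinct organisms.
    step5_family_organisms_only
        If set, the step-5 fraction is computed over organisms possessing the
        family rather than over all organisms.
    """

    pattern: str = "strict"
    x_input: float = 2.0
    skip_step3: bool = False
    essential_pct: float = 90.0
    apply_step5: bool = True
    majority_pct: float = 50.0
    random_seed: int = 0
    step3_distinct_organisms: bool = False
    step5_family_organisms_only: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise FormatError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.x_input <= 0:
            raise FormatError("x_input must be positive")
        if not 0 <= self.essential_pct <= 100:
            raise FormatError("essential_pct must be in [0, 100]")
        if not 0 < self.majority_pct <= 100:
            raise FormatError("majority_pct must be in (0, 100]")
        if self.pattern == "alternative" and self.x_input < MIN_RECOMMENDED_X:
            warnings.warn(
                f"x_input={self.x_input} is below the recommended minimum of "
                f"{MIN_RECOMMENDED_X}; true resistance families may be exempted",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}  # type: ignore[attr-defined]

    @property
    def setting_label(self) -> str:
        """Short human-readable label, e.g. ``alt2|step3=on|ess=90``."""
        if self.pattern == "strict":
            pat = "strict"
        else:
            x = self.x_input
            pat = f"alt{int(x) if float(x).is_integer() else x}"
        s3 = "off" if self.skip_step3 else "on"
        return f"{pat}|step3={s3}|ess={int(self.essential_pct)}"


@dataclass
class Dataset:
    """A validated multi-genome dataset.

    ``families`` maps family id to a frozenset of protein keys and, when
    present, must partition the protein catalog.  Index structures are built
    lazily and cached.
    """

    organisms: dict[str, OrganismRecord]
    proteins: dict[ProteinKey, ProteinRecord]
    clusters: dict[str, GeneCluster]
    families: Optional[dict[str, frozenset[ProteinKey]]] = None

    _cluster_by_protein: Optional[dict[ProteinKey, str]] = field(
        default=None, repr=False, compare=False
    )
    _family_by_protein: Optional[dict[ProteinKey, str]] = field(
        default=None, repr=False, compare=False
    )

    # -- indexes ----------------------------------------------------------

    @property
    def cluster_by_protein(self) -> dict[ProteinKey, str]:
        if self._cluster_by_protein is None:
            idx: dict[ProteinKey, str] = {}
            for cl in self.clusters.values():
                for key in cl.member_keys:
                    idx[key] = cl.cluster_id
            self._cluster_by_protein = idx
        return self._cluster_by_protein

    @property
    def family_by_protein(self) -> dict[ProteinKey, str]:
        if self.families is None:
            raise FriggError("dataset has no family partition")
        if self._family_by_protein is None:
            idx: dict[ProteinKey, str] = {}
            for fid, members in self.families.items():
                for key in members:
                    idx[key] = fid
            self._family_by_protein = idx
        return self._family_by_protein

    def invalidate_indexes(self) -> None:
        self._cluster_by_protein = None
        self._family_by_protein = None

    # -- convenience ------------------------------------------------------

    def cluster_of(self, key: ProteinKey) -> Optional[str]:
        """Cluster id containing the protein, or None if free-standing."""
        return self.cluster_by_protein.get(key)

    def family_of(self, key: ProteinKey) -> str:
        try:
            return self.family_by_protein[key]
        except KeyError:
            raise IntegrityError(f"protein {key} is not assigned to any family") from None

    def family_members_in_organism(self, family_id: str, organism_id: str) -> list[ProteinKey]:
        if self.families is None:
            raise FriggError("dataset has no family partition")
        return sorted(k for k in self.families[family_id] if k[0] == organism_id)

    def counts(self) -> tuple[int, int, int, int]:
        """(n_organisms, n_proteins, n_clusters, n_cluster_genes)."""
        n_cluster_genes = sum(len(c.members) for c in self.clusters.values())
        return (len(self.organisms), len(self.proteins), len(self.clusters), n_cluster_genes)

    # -- validation -------------------------------------------------------

    def validate(self) -> "Dataset":
        """Cross-validate all referential-integrity invariants; return self."""
        problems: list[str] = []

        for key, prot in self.proteins.items():
            if prot.organism_id not in self.organisms:
                problems.append(f"protein {key} references unknown organism {prot.organism_id!r}")

        seen_in_cluster: dict[ProteinKey, str] = {}
        for cl in self.clusters.values():
            if cl.organism_id not in self.organisms:
                problems.append(
                    f"cluster {cl.cluster_id!r} references unknown organism {cl.organism_id!r}"
                )
            for key in cl.member_keys:
                if key not in self.proteins:
                    problems.append(
                        f"cluster {cl.cluster_id!r} references unknown protein {key[1]!r} "
                        f"in organism {key[0]!r}"
                    )
                elif key in seen_in_cluster:
                    problems.append(
                        f"protein {key} belongs to both cluster "
                        f"{seen_in_cluster[key]!r} and {cl.cluster_id!r}"
                    )
                else:
                    seen_in_cluster[key] = cl.cluster_id

        if self.families is not None:
            assigned: dict[ProteinKey, str] = {}
            for fid, members in self.families.items():
                if not members:
                    problems.append(f"family {fid!r} is empty")
                for key in members:
                    if key not in self.proteins:
                        problems.append(f"family {fid!r} references unknown protein {key}")
                    elif key in assigned:
                        problems.append(
                            f"protein {key} belongs to families {assigned[key]!r} and {fid!r}"
                        )
                    else:
                        assigned[key] = fid
            missing = set(self.proteins) - set(assigned)
            if missing:
                sample = sorted(missing)[:5]
                problems.append(
                    f"{len(missing)} proteins not covered by the family partition, "
                    f"e.g. {sample}"
                )

        if problems:
            raise IntegrityError("dataset validation failed:\n  " + "\n  ".join(problems))
        return self


def make_dataset(
    organisms: Iterable[OrganismRecord],
    proteins: Iterable[ProteinRecord],
    clusters: Iterable[GeneCluster],
    families: Optional[Mapping[str, Iterable[ProteinKey]]] = None,
    validate: bool = True,
) -> Dataset:
    """Assemble and (by default) validate a :class:`Dataset` from iterables."""
    org_map: dict[str, OrganismRecord] = {}
    for org in organisms:
        if org.organism_id in org_map:
            raise IntegrityError(f"duplicate organism_id {org.organism_id!r}")
        org_map[org.organism_id] = org
    prot_map: dict[ProteinKey, ProteinRecord] = {}
    for prot in proteins:
        if prot.key in prot_map:
            raise IntegrityError(f"duplicate protein {prot.key}")
        prot_map[prot.key] = prot
    cl_map: dict[str, GeneCluster] = {}
    for cl in clusters:
        if cl.cluster_id in cl_map:
            raise IntegrityError(f"duplicate cluster_id {cl.cluster_id!r}")
        cl_map[cl.cluster_id] = cl
    fam_map = None
    if families is not None:
        fam_map = {fid: frozenset(members) for fid, members in families.items()}
    ds = Dataset(organisms=org_map, proteins=prot_map, clusters=cl_map, families=fam_map)
    if validate:
        ds.validate()
    return ds
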