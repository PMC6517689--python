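"""The five-step cluster-prioritization pipeline.

Step 1 tabulates, for every gene of every predicted cluster, how many family
members (copies) exist in the same organism and how many of those sit inside
predicted clusters.  Step 2 selects clusters whose copy-count pattern matches
a planted self-resistance architecture, under either a strict rule or an
alternative rule that exempts large protein families.  Steps 3-5 filter the
selected candidates by recurrence, essentiality of the resistance family, and
a single-copy majority requirement.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import Dataset, FriggError, IntegrityError, PipelineConfig, ProteinKey


@dataclass(frozen=True)
class HomologyCountRow:
    """Step-1 output: one row per (cluster, member protein)."""

    organism_id: str
    cluster_id: str
    protein_id: str
    family_id: str
    copies_in_organism: int
    copies_in_clusters: int

    def __post_init__(self) -> None:
        if not 1 <= self.copies_in_clusters <= self.copies_in_organism:
            raise IntegrityError(
                f"{self.organism_id}/{self.protein_id}: inconsistent copy counts "
                f"({self.copies_in_organism}, {self.copies_in_clusters})"
            )


@dataclass(frozen=True)
class CandidateCluster:
    """A step-2 selection: cluster plus its designated resistance gene."""

    cluster_id: str
    organism_id: str
    resistance_protein_id: str
    resistance_family_id: str
    target_protein_ids: tuple[str, ...]
    exempt_protein_ids: tuple[str, ...] = ()
    pattern: str = "strict"

    @property
    def sort_key(self) -> tuple[str, str]:
        return (self.organism_id, self.cluster_id)


@dataclass
class RunResult:
    """Per-step candidate sets and counts for one configuration."""

    config: PipelineConfig
    after_step2: tuple[CandidateCluster, ...]
    after_step3: Optional[tuple[CandidateCluster, ...]]  # None when skipped
    after_step4: tuple[CandidateCluster, ...]
    after_step5: Optional[tuple[CandidateCluster, ...]]  # None when not applied
    dataset_fingerprint: tuple = ()

    @property
    def final_candidates(self) -> tuple[CandidateCluster, ...]:
        return self.after_step5 if self.after_step5 is not None else self.after_step4

    @property
    def applied_steps(self) -> list[str]:
        steps = ["step2"]
        if self.after_step3 is not None:
            steps.append("step3")
        steps.append("step4")
        if self.after_step5 is not None:
            steps.append("step5")
        return steps

    def candidates_after(self, step: str) -> Optional[tuple[CandidateCluster, ...]]:
        return {
            "step2": self.after_step2,
            "step3": self.after_step3,
            "step4": self.after_step4,
            "step5": self.after_step5,
        }[step]

    def families_after(self, step: str) -> Optional[frozenset[str]]:
        cands = self.candidates_after(step)
        if cands is None:
            return None
        return frozenset(c.resistance_family_id for c in cands)

    @property
    def step_counts(self) -> dict[str, tuple[int, int]]:
        """step -> (n candidate clusters, n distinct resistance families)."""
        out: dict[str, tuple[int, int]] = {}
        for step in ("step2", "step3", "step4", "step5"):
            cands = self.candidates_after(step)
            if cands is None:
                continue
            out[step] = (len(cands), len({c.resistance_family_id for c in cands}))
        return out


# ---------------------------------------------------------------------------
# step 1


def compute_homology_counts(dataset: Dataset) -> list[HomologyCountRow]:
    """Tabulate per-organism family copy counts for every cluster gene.

    ``copies_in_organism`` counts the gene's family members within its own
    organism (including itself); ``copies_in_clusters`` counts how many of
    those sit inside any predicted cluster of that organism.
    """
    if dataset.families is None:
        raise FriggError("dataset has no family partition; build or load families first")
    fam_of = dataset.family_by_protein
    in_cluster = dataset.cluster_by_protein

    org_counts: dict[tuple[str, str], int] = defaultdict(int)
    org_cluster_counts: dict[tuple[str, str], int] = defaultdict(int)
    for key, fid in fam_of.items():
        org = key[0]
        org_counts[(fid, org)] += 1
        if key in in_cluster:
            org_cluster_counts[(fid, org)] += 1

    rows: list[HomologyCountRow] = []
    for cid in sorted(dataset.clusters):
        cl = dataset.clusters[cid]
        for pid in cl.members:
            key = (cl.organism_id, pid)
            fid = fam_of[key]
            rows.append(
                HomologyCountRow(
                    organism_id=cl.organism_id,
                    cluster_id=cid,
                    protein_id=pid,
                    family_id=fid,
                    copies_in_organism=org_counts[(fid, cl.organism_id)],
                    copies_in_clusters=org_cluster_counts[(fid, cl.organism_id)],
                )
            )
    return rows


# ---------------------------------------------------------------------------
# step 2


def family_size_cutoff(n_organisms: int, x_input: float) -> float:
    """Large-family exemption cutoff: ``x_input * n_organisms``.

    A family is exempt iff its dataset-wide member count is strictly greater
    than this value.
    """
    if n_organisms < 1:
        raise FriggError("n_organisms must be >= 1")
    if x_input <= 0:
        raise FriggError("x_input must be positive")
    return x_input * n_organisms


def _exempt_families(dataset: Dataset, x_input: float) -> frozenset[str]:
    assert dataset.families is not None
    cutoff = family_size_cutoff(len(dataset.organisms), x_input)
    return frozenset(fid for fid, members in dataset.families.items() if len(members) > cutoff)


def _free_family_members(dataset: Dataset, family_id: str, organism_id: str) -> tuple[str, ...]:
    """Protein ids of same-organism family members outside all clusters."""
    in_cluster = dataset.cluster_by_protein
    return tuple(
        pid
        for (org, pid) in dataset.family_members_in_organism(family_id, organism_id)
        if (org, pid) not in in_cluster
    )


def _select(
    counts: Sequence[HomologyCountRow],
    dataset: Dataset,
    exempt: frozenset[str],
    pattern: str,
) -> list[CandidateCluster]:
    by_cluster: dict[str, list[HomologyCountRow]] = defaultdict(list)
    for row in counts:
        by_cluster[row.cluster_id].append(row)

    selected: list[CandidateCluster] = []
    for cid, rows in by_cluster.items():
        active = [r for r in rows if r.family_id not in exempt]
        exempt_rows = [r for r in rows if r.family_id in exempt]
        # the resistance gene: exactly 2 copies in the organism, the extra one
        # outside every predicted cluster (so only itself is cluster-resident)
        resistance = [
            r for r in active if r.copies_in_organism == 2 and r.copies_in_clusters == 1
        ]
        if len(resistance) != 1:
            continue
        res = resistance[0]
        if any(r.copies_in_organism != 1 for r in active if r is not res):
            continue
        targets = _free_family_members(dataset, res.family_id, res.organism_id)
        selected.append(
            CandidateCluster(
                cluster_id=cid,
                organism_id=res.organism_id,
                resistance_protein_id=res.protein_id,
                resistance_family_id=res.family_id,
                target_protein_ids=targets,
                exempt_protein_ids=tuple(sorted(r.protein_id for r in exempt_rows)),
                pattern=pattern,
            )
        )
    return sorted(selected, key=lambda c: c.sort_key)


def select_clusters_strict(
    counts: Sequence[HomologyCountRow], dataset: Dataset
) -> list[CandidateCluster]:
    """Strict step-2 rule: exactly one member has exactly one extra copy and
    that copy lies outside all predicted clusters; every other member is
    single-copy in the organism."""
    return _select(counts, dataset, frozenset(), "strict")


def select_clusters_alternative(
    counts: Sequence[HomologyCountRow], dataset: Dataset, x_input: float
) -> list[CandidateCluster]:
    """Alternative step-2 rule: members of families larger than the cutoff are
    exempt — their copy counts are unconstrained and they are ineligible as
    resistance genes; the strict rule applies to the remaining members."""
    return _select(counts, dataset, _exempt_families(dataset, x_input), "alternative")


# ---------------------------------------------------------------------------
# steps 3-5


def filter_recurrent(
    candidates: Iterable[CandidateCluster],
    distinct_organisms: bool = False,
) -> list[CandidateCluster]:
    """Step 3: keep candidates whose resistance family recurs in >= 2
    candidate clusters (optionally from >= 2 distinct organisms)."""
    cands = list(candidates)
    if distinct_organisms:
        orgs: dict[str, set[str]] = defaultdict(set)
        for c in cands:
            orgs[c.resistance_family_id].add(c.organism_id)
        keep = {fid for fid, o in orgs.items() if len(o) >= 2}
    else:
        n = Counter(c.resistance_family_id for c in cands)
        keep = {fid for fid, k in n.items() if k >= 2}
    return sorted((c for c in cands if c.resistance_family_id in keep), key=lambda c: c.sort_key)


def _family_presence(dataset: Dataset, family_id: str) -> tuple[int, int]:
    """(#organisms with >=1 member, #organisms with >=2 members)."""
    assert dataset.families is not None
    per_org: Counter[str] = Counter(org for (org, _pid) in dataset.families[family_id])
    return (
        sum(1 for v in per_org.values() if v >= 1),
        sum(1 for v in per_org.values() if v >= 2),
    )


def filter_essential(
    candidates: Iterable[CandidateCluster],
    dataset: Dataset,
    essential_pct: float,
) -> list[CandidateCluster]:
    """Step 4: keep candidates whose resistance family has members in at least
    ``essential_pct`` percent of all organisms in the dataset."""
    if not 0 <= essential_pct <= 100:
        raise FriggError("essential_pct must be in [0, 100]")
    n_org = len(dataset.organisms)
    kept = []
    for c in candidates:
        present, _multi = _family_presence(dataset, c.resistance_family_id)
        if present / n_org >= essential_pct / 100.0:
            kept.append(c)
    return sorted(kept, key=lambda c: c.sort_key)


def filter_single_copy(
    candidates: Iterable[CandidateCluster],
    dataset: Dataset,
    majority_pct: float = 50.0,
    family_organisms_only: bool = False,
) -> list[CandidateCluster]:
    """Step 5: remove candidates whose resistance family is multi-copy in
    strictly more than ``majority_pct`` percent of the organisms.

    The denominator defaults to all organisms in the dataset; with
    ``family_organisms_only`` it is the organisms possessing the family.
    """
    if not 0 < majority_pct <= 100:
        raise FriggError("majority_pct must be in (0, 100]")
    n_org = len(dataset.organisms)
    kept = []
    for c in candidates:
        present, multi = _family_presence(dataset, c.resistance_family_id)
        denom = present if family_organisms_only else n_org
        if multi / denom > majority_pct / 100.0:
            continue
        kept.append(c)
    return sorted(kept, key=lambda c: c.sort_key)


# ---------------------------------------------------------------------------
# orchestration


def dataset_fingerprint(dataset: Dataset) -> tuple:
    n_org, n_prot, n_clust, n_genes = dataset.counts()
    return (n_org, n_prot, n_clust, n_genes)


def run_pipeline(
    dataset: Dataset,
    config: PipelineConfig,
    counts: Optional[Sequence[HomologyCountRow]] = None,
) -> RunResult:
    """Apply steps 1 -> 2 -> (3) -> 4 -> (5) and record every stage.

    ``counts`` may be supplied to reuse a precomputed step-1 table across the
    settings of a grid.
    """
    if counts is None:
        counts = compute_homology_counts(dataset)
    if config.pattern == "strict":
        step2 = select_clusters_strict(counts, dataset)
    else:
        step2 = select_clusters_alternative(counts, dataset, config.x_input)

    if config.skip_step3:
        step3: Optional[list[CandidateCluster]] = None
        after3 = step2
    else:
        step3 = filter_recurrent(step2, distinct_organisms=config.step3_distinct_organisms)
        after3 = step3

    step4 = filter_essential(after3, dataset, config.essential_pct)

    step5: Optional[list[CandidateCluster]] = None
    if config.apply_step5:
        step5 = filter_single_copy(
            step4,
            dataset,
            majority_pct=config.majority_pct,
            family_organisms_only=config.step5_family_organisms_only,
        )

    return RunResult(
        config=config,
        after_step2=tuple(step2),
        after_step3=tuple(step3) if step3 is not None else None,
        after_step4=tuple(step4),
        after_step5=tuple(step5) if step5 is not None else None,
        dataset_fingerprint=dataset_fingerprint(dataset),
    )


#: the published 12-setting grid: 3 patterns x step 3 on/off x 2 essentiality
#: thresholds, step 5 always applied
GRID_X_VALUES = (2.0, 3.0)
GRID_ESSENTIAL_PCTS = (90.0, 98.0)


def grid_configs(
    x_values: Sequence[float] = GRID_X_VALUES,
    essential_pcts: Sequence[float] = GRID_ESSENTIAL_PCTS,
    base: Optional[PipelineConfig] = None,
) -> list[PipelineConfig]:
    base = base or PipelineConfig()
    configs = []
    patterns: list[tuple[str, float]] = [("strict", base.x_input)]
    patterns += [("alternative", x) for x in x_values]
    for pattern, x in patterns:
        for skip3 in (False, True):
            for ess in essential_pcts:
                configs.append(
                    PipelineConfig(
                        pattern=pattern,
                        x_input=x,
                        skip_step3=skip3,
                        essential_pct=ess,
                        apply_step5=True,
                        majority_pct=base.majority_pct,
                        random_seed=base.random_seed,
                        step3_distinct_organisms=base.step3_distinct_organisms,
                        step5_family_organisms_only=base.step5_family_organisms_only,
                    )
                )
    return configs


def run_grid(dataset: Dataset, configs: Optional[Sequence[PipelineConfig]] = None) -> list[RunResult]:
    """Run all grid settings against one dataset, sharing the step-1 table."""
    if configs is None:
        configs = grid_configs()
    counts = compute_homology_counts(dataset)
    return [run_pipeline(dataset, cfg, counts=counts) for cfg in configs]


def combine_runs(run_results: Sequence[RunResult]) -> tuple[list[str], dict[str, dict[str, int]]]:
    """Union of final resistance families across runs plus a presence matrix.

    Returns ``(sorted family ids, {family_id: {setting_label: 0/1}})``.
    Results must all come from the same dataset.
    """
    if not run_results:
        raise FriggError("combine_runs requires at least one RunResult")
    fps = {r.dataset_fingerprint for r in run_results}
    if len(fps) > 1:
        raise IntegrityError(f"run results come from different datasets: {sorted(fps)}")
    labels = [r.config.setting_label for r in run_results]
    if len(set(labels)) != len(labels):
        raise IntegrityError("duplicate setting labels in run grid")
    union: set[str] = set()
    per_run: dict[str, frozenset[str]] = {}
    for r in run_results:
        fams = frozenset(c.resistance_family_id for c in r.final_candidates)
        per_run[r.config.setting_label] = fams
        union |= fams
    families = sorted(union)
    matrix = {
        fid: {label: int(fid in per_run[label]) for label in labels} for fid in families
    }
    return families, matrix
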