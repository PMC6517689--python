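"""Post-pipeline curation support: context labels, grid summaries, percent
arithmetic, and the TSV exports used for manual follow-up."""

from __future__ import annotations

import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .core import RunResult
from .model import Dataset, FriggError, IntegrityError, ProteinKey

PathLike = Union[str, Path]

#: grid summary layout: step rows (``*`` = step 3 skipped) x pattern columns
STEP_ROWS = ("2", "3", "4", "4*", "5", "5*")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def percent_change(count_before: int, count_after: int) -> int:
    """Signed integer percent change, round-half-away-from-zero."""
    if count_before <= 0:
        raise FriggError("count_before must be positive")
    return _round_half_away(100.0 * (count_after - count_before) / count_before)


def share_of_total(part: int, total: int) -> int:
    """Rounded integer percentage ``part / total``."""
    if total <= 0:
        raise FriggError("total must be positive")
    if not 0 <= part <= total:
        raise FriggError("part must satisfy 0 <= part <= total")
    return _round_half_away(100.0 * part / total)


# ---------------------------------------------------------------------------
# context labels


def label_protein_context(
    protein: ProteinKey, run_result: RunResult, dataset: Dataset
) -> str:
    """Assign the curation context label for one protein under one run.

    ``StrictClust``  designated resistance gene of a final candidate cluster
    ``Clust``        resides in a predicted cluster but is not a designated
                     resistance gene
    ``outsideSC``    outside all clusters and a same-organism family member of
                     a designated resistance gene (the putative target)
    ``0``            anywhere else in a genome
    """
    if protein not in dataset.proteins:
        raise IntegrityError(f"protein {protein} is not in the dataset")
    finals = run_result.final_candidates
    resistance_keys = {(c.organism_id, c.resistance_protein_id) for c in finals}
    if protein in resistance_keys:
        return "StrictClust"
    if dataset.cluster_of(protein) is not None:
        return "Clust"
    fam = dataset.family_of(protein)
    for c in finals:
        if c.resistance_family_id == fam and c.organism_id == protein[0]:
            return "outsideSC"
    return "0"


def label_family_contexts(
    family_id: str, run_result: RunResult, dataset: Dataset
) -> dict[ProteinKey, str]:
    """Labels for every member of a family (the input FASTA export expects)."""
    if dataset.families is None or family_id not in dataset.families:
        raise IntegrityError(f"unknown family_id {family_id!r}")
    return {
        key: label_protein_context(key, run_result, dataset)
        for key in sorted(dataset.families[family_id])
    }


def write_label_table(
    run_result: RunResult, dataset: Dataset, path: PathLike
) -> pd.DataFrame:
    """Label every member of every final candidate's resistance family."""
    rows = []
    fams = sorted({c.resistance_family_id for c in run_result.final_candidates})
    for fid in fams:
        for key, label in label_family_contexts(fid, run_result, dataset).items():
            rows.append(
                {
                    "family_id": fid,
                    "organism_id": key[0],
                    "protein_id": key[1],
                    "label": label,
                }
            )
    df = pd.DataFrame(rows, columns=["family_id", "organism_id", "protein_id", "label"])
    df.to_csv(path, sep="\t", index=False)
    return df


def export_family_curation_table(
    family_id: str, run_result: RunResult, dataset: Dataset, path: PathLike
) -> pd.DataFrame:
    """One-hot per-member table (section, copies, label) for external
    ordination or tree tools; this package does not compute PCA or trees."""
    labels = label_family_contexts(family_id, run_result, dataset)
    per_org: dict[str, int] = defaultdict(int)
    for (org, _pid) in labels:
        per_org[org] += 1
    rows = []
    for (org, pid), label in labels.items():
        row = {
            "organism_id": org,
            "protein_id": pid,
            "section": dataset.organisms[org].section,
            "copies": per_org[org],
        }
        for lab in ("StrictClust", "Clust", "0", "outsideSC"):
            row[f"is_{lab}"] = int(label == lab)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# grid summary (step-count table)


def _pattern_column(run: RunResult) -> str:
    cfg = run.config
    if cfg.pattern == "strict":
        return "strict"
    x = cfg.x_input
    return f"alt{int(x) if float(x).is_integer() else x}"


def summarize_run_grid(run_results: Sequence[RunResult]) -> pd.DataFrame:
    """Build the step-count summary table over a full 12-setting grid.

    Rows are pipeline steps (``4*``/``5*`` mean step 3 skipped); columns are
    the selection patterns; cells are distinct resistance-family counts, with
    ``a/b`` pairs for the two essentiality thresholds at steps 4 and 5.
    """
    by_key: dict[tuple[str, bool, float], RunResult] = {}
    for r in run_results:
        key = (_pattern_column(r), r.config.skip_step3, r.config.essential_pct)
        if key in by_key:
            raise IntegrityError(f"duplicate grid setting {key}")
        by_key[key] = r

    columns = sorted({k[0] for k in by_key}, key=lambda c: (c != "strict", c))
    ess_values = sorted({k[2] for k in by_key})
    if len(ess_values) != 2:
        raise IntegrityError(
            f"grid must cover exactly two essentiality thresholds, got {ess_values}"
        )
    missing = [
        (col, skip3, ess)
        for col in columns
        for skip3 in (False, True)
        for ess in ess_values
        if (col, skip3, ess) not in by_key
    ]
    if missing:
        raise IntegrityError(f"incomplete grid; missing settings: {missing}")

    def nfam(run: RunResult, step: str) -> int:
        fams = run.families_after(step)
        assert fams is not None
        return len(fams)

    table: dict[str, dict[str, str]] = {col: {} for col in columns}
    for col in columns:
        runs = {(skip3, ess): by_key[(col, skip3, ess)] for skip3 in (False, True) for ess in ess_values}
        # steps 2 and 3 do not depend on the essentiality threshold
        s2 = {nfam(r, "step2") for r in runs.values()}
        if len(s2) != 1:
            raise IntegrityError(f"column {col}: step-2 counts disagree across the grid")
        table[col]["2"] = str(s2.pop())
        s3 = {nfam(runs[(False, ess)], "step3") for ess in ess_values}
        if len(s3) != 1:
            raise IntegrityError(f"column {col}: step-3 counts disagree across the grid")
        table[col]["3"] = str(s3.pop())
        lo, hi = ess_values
        table[col]["4"] = f"{nfam(runs[(False, lo)], 'step4')}/{nfam(runs[(False, hi)], 'step4')}"
        table[col]["4*"] = f"{nfam(runs[(True, lo)], 'step4')}/{nfam(runs[(True, hi)], 'step4')}"
        table[col]["5"] = f"{nfam(runs[(False, lo)], 'step5')}/{nfam(runs[(False, hi)], 'step5')}"
        table[col]["5*"] = f"{nfam(runs[(True, lo)], 'step5')}/{nfam(runs[(True, hi)], 'step5')}"

    df = pd.DataFrame({col: [table[col][row] for row in STEP_ROWS] for col in columns})
    df.insert(0, "step", STEP_ROWS)
    return df


def write_step_count_table(run_results: Sequence[RunResult], path: PathLike) -> pd.DataFrame:
    df = summarize_run_grid(run_results)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_presence_matrix(
    families: Sequence[str], matrix: Mapping[str, Mapping[str, int]], path: PathLike
) -> pd.DataFrame:
    """Serialize the per-setting 0/1 presence matrix (rows = families)."""
    if not families:
        df = pd.DataFrame(columns=["family_id"])
        df.to_csv(path, sep="\t", index=False)
        return df
    settings = list(matrix[families[0]].keys())
    rows = [{"family_id": fid, **{s: matrix[fid][s] for s in settings}} for fid in families]
    df = pd.DataFrame(rows, columns=["family_id", *settings])
    df.to_csv(path, sep="\t", index=False)
    return df
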