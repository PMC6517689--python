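"""Protein-family construction from all-vs-all BLASTp hits.

Families are the connected components of an undirected graph whose edges are
*bidirectional* hit pairs in which each direction passes both thresholds:
percent identity >= 50 and query-coverage + subject-coverage >= 130 (percent
of full sequence lengths, computed from the retained best hit's alignment
span).  Within-organism hits are eligible edges — paralogs must share a
family because the pipeline's copy counts depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import networkx as nx

from .model import Dataset, FormatError, IntegrityError, ProteinKey

DEFAULT_MIN_IDENTITY = 50.0
DEFAULT_MIN_COVERAGE_SUM = 130.0

PathLike = Union[str, Path]

#: raw hit-file id -> (protein key, full sequence length)
LengthLookup = Mapping[str, tuple[ProteinKey, int]]


@dataclass(frozen=True)
class DirectedHit:
    """One directed BLASTp hit after parsing (best hit per ordered pair)."""

    query: ProteinKey
    subject: ProteinKey
    percent_identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    query_length_aa: int
    subject_length_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end <= self.query_length_aa):
            raise FormatError(f"hit {self.query}->{self.subject}: bad query coordinates")
        if not (1 <= self.s_start <= self.s_end <= self.subject_length_aa):
            raise FormatError(f"hit {self.query}->{self.subject}: bad subject coordinates")

    @property
    def coverage_sum(self) -> float:
        """Query coverage + subject coverage, each in percent of full length."""
        qcov = 100.0 * (self.q_end - self.q_start + 1) / self.query_length_aa
        scov = 100.0 * (self.s_end - self.s_start + 1) / self.subject_length_aa
        return qcov + scov


def length_lookup_from_dataset(dataset: Dataset) -> dict[str, tuple[ProteinKey, int]]:
    """Build the id-resolution table for :func:`parse_hits`.

    Accepts ids of the form ``organism_id|protein_id``; bare protein ids are
    also resolvable when unique dataset-wide.
    """
    lookup: dict[str, tuple[ProteinKey, int]] = {}
    ambiguous: set[str] = set()
    for key, prot in dataset.proteins.items():
        org, pid = key
        lookup[f"{org}|{pid}"] = (key, prot.length_aa)
        if pid in ambiguous:
            continue
        if pid in lookup and lookup[pid][0] != key:
            del lookup[pid]
            ambiguous.add(pid)
        elif pid not in lookup:
            lookup[pid] = (key, prot.length_aa)
    return lookup


def parse_hits(blast_tab_path: PathLike, length_lookup: LengthLookup) -> list[DirectedHit]:
    """Parse a BLAST tabular (outfmt-6-style) file into directed hits.

    Accepts the standard 12-column dialect
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore) or an extended 14-column dialect with qlen/slen appended;
    file-borne lengths override the lookup.  Self-hits are discarded and
    multiple hits for the same ordered pair are collapsed to the best one
    (highest identity, ties broken by largest coverage sum).
    """
    best: dict[tuple[ProteinKey, ProteinKey], DirectedHit] = {}
    with open(blast_tab_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{blast_tab_path}: line {lineno}: expected >= 12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            for raw in (qid, sid):
                if raw not in length_lookup:
                    raise IntegrityError(
                        f"{blast_tab_path}: line {lineno}: id {raw!r} does not "
                        f"resolve to a catalog protein"
                    )
            qkey, qlen = length_lookup[qid]
            skey, slen = length_lookup[sid]
            try:
                pident = float(fields[2])
                q_start, q_end = int(fields[6]), int(fields[7])
                s_start, s_end = int(fields[8]), int(fields[9])
                if len(fields) >= 14:
                    qlen, slen = int(fields[12]), int(fields[13])
            except ValueError as exc:
                raise FormatError(f"{blast_tab_path}: line {lineno}: malformed row") from exc
            if qkey == skey:
                continue
            hit = DirectedHit(
                query=qkey,
                subject=skey,
                percent_identity=pident,
                q_start=q_start,
                q_end=q_end,
                s_start=s_start,
                s_end=s_end,
                query_length_aa=qlen,
                subject_length_aa=slen,
            )
            prev = best.get((qkey, skey))
            if (
                prev is None
                or hit.percent_identity > prev.percent_identity
                or (
                    hit.percent_identity == prev.percent_identity
                    and hit.coverage_sum > prev.coverage_sum
                )
            ):
                best[(qkey, skey)] = hit
    # deterministic order
    return [best[k] for k in sorted(best)]


def qualifying_edges(
    hits: Iterable[DirectedHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage_sum: float = DEFAULT_MIN_COVERAGE_SUM,
) -> set[tuple[ProteinKey, ProteinKey]]:
    """Undirected edges where both directed hits exist and each passes both
    thresholds independently."""
    passing: set[tuple[ProteinKey, ProteinKey]] = set()
    for h in hits:
        if h.percent_identity >= min_identity and h.coverage_sum >= min_coverage_sum:
            passing.add((h.query, h.subject))
    edges: set[tuple[ProteinKey, ProteinKey]] = set()
    for (a, b) in passing:
        if (b, a) in passing:
            edges.add((a, b) if a <= b else (b, a))
    return edges


def single_linkage_families(
    edges: Iterable[tuple[ProteinKey, ProteinKey]],
    all_proteins: Iterable[ProteinKey],
) -> dict[str, frozenset[ProteinKey]]:
    """Connected components of the edge graph; edge-free proteins become
    singleton families.

    Family ids are ``"F" + zero-padded index``, assigned in order of each
    component's lexicographically smallest member so the labelling is
    deterministic and independent of edge order.
    """
    nodes = set(all_proteins)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for (a, b) in edges:
        if a not in nodes or b not in nodes:
            raise IntegrityError(f"edge endpoint not in protein catalog: {(a, b)}")
        graph.add_edge(a, b)
    components = sorted(nx.connected_components(graph), key=min)
    return {f"F{i:06d}": frozenset(comp) for i, comp in enumerate(components, start=1)}


def build_families(
    dataset: Dataset,
    blast_tab_path: PathLike,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage_sum: float = DEFAULT_MIN_COVERAGE_SUM,
) -> dict[str, frozenset[ProteinKey]]:
    """End-to-end family construction for a dataset lacking a family table."""
    lookup = length_lookup_from_dataset(dataset)
    hits = parse_hits(blast_tab_path, lookup)
    edges = qualifying_edges(hits, min_identity, min_coverage_sum)
    return single_linkage_families(edges, dataset.proteins.keys())
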