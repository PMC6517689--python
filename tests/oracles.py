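"""Independent brute-force re-derivations used as oracles.

Everything here is written directly from the selection-rule prose and avoids
the package's pipeline code paths: no HomologyCountRow, no networkx, no
shared helpers.  Lookups are deliberately naive (linear scans)."""

from __future__ import annotations

import random


# ---------------------------------------------------------------------------
# copy counts and step-by-step selection


def brute_family_of(dataset, key):
    for fid, members in dataset.families.items():
        if key in members:
            return fid
    raise AssertionError(f"{key} not in any family")


def brute_copy_counts(dataset, org, pid):
    """(copies in the organism, copies of those inside predicted clusters)."""
    fid = brute_family_of(dataset, (org, pid))
    same_org = [k for k in dataset.families[fid] if k[0] == org]
    n_in_clusters = 0
    for (o, p) in same_org:
        for cl in dataset.clusters.values():
            if cl.organism_id == o and p in cl.members:
                n_in_clusters += 1
                break
    return len(same_org), n_in_clusters


def brute_select(dataset, exempt_family_ids=frozenset()):
    """{cluster_id: (resistance_pid, resistance_family_id)} under the rule:
    exactly one non-exempt member has exactly 2 same-organism copies with the
    extra one outside every cluster; all other non-exempt members have 1."""
    out = {}
    for cl in dataset.clusters.values():
        resistance = []
        ok = True
        for pid in cl.members:
            fid = brute_family_of(dataset, (cl.organism_id, pid))
            if fid in exempt_family_ids:
                continue
            n_org, n_cl = brute_copy_counts(dataset, cl.organism_id, pid)
            if n_org == 1:
                continue
            if n_org == 2 and n_cl == 1:
                resistance.append((pid, fid))
            else:
                ok = False
        if ok and len(resistance) == 1:
            out[cl.cluster_id] = resistance[0]
    return out


def brute_exempt_families(dataset, x):
    cutoff = x * len(dataset.organisms)
    return frozenset(
        fid for fid, members in dataset.families.items() if len(members) > cutoff
    )


def brute_step3(selected):
    """Keep clusters whose resistance family occurs in >= 2 selected clusters."""
    fams = [fam for (_pid, fam) in selected.values()]
    return {
        cid: v for cid, v in selected.items() if fams.count(v[1]) >= 2
    }


def orgs_with_family(dataset, fid, min_copies):
    hits = set()
    for org in dataset.organisms:
        n = sum(1 for k in dataset.families[fid] if k[0] == org)
        if n >= min_copies:
            hits.add(org)
    return hits


def brute_step4(selected, dataset, essential_pct):
    n = len(dataset.organisms)
    return {
        cid: v
        for cid, v in selected.items()
        if len(orgs_with_family(dataset, v[1], 1)) / n >= essential_pct / 100.0
    }


def brute_step5(selected, dataset, majority_pct=50.0):
    n = len(dataset.organisms)
    return {
        cid: v
        for cid, v in selected.items()
        if not len(orgs_with_family(dataset, v[1], 2)) / n > majority_pct / 100.0
    }


def brute_chain(dataset, pattern, x, skip_step3, essential_pct, majority_pct=50.0):
    """Full step 2->5 re-derivation; returns cluster-id sets per step."""
    exempt = frozenset() if pattern == "strict" else brute_exempt_families(dataset, x)
    s2 = brute_select(dataset, exempt)
    s3 = s2 if skip_step3 else brute_step3(s2)
    s4 = brute_step4(s3, dataset, essential_pct)
    s5 = brute_step5(s4, dataset, majority_pct)
    return {
        "step2": set(s2),
        "step3": None if skip_step3 else set(s3),
        "step4": set(s4),
        "step5": set(s5),
    }


# ---------------------------------------------------------------------------
# connected-components oracles


def components_bfs(edges, nodes):
    """Set of frozensets, via breadth-first traversal over adjacency lists."""
    adj = {n: set() for n in nodes}
    for (a, b) in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    comps = set()
    for start in nodes:
        if start in seen:
            continue
        queue = [start]
        comp = {start}
        seen.add(start)
        while queue:
            cur = queue.pop(0)
            for nxt in adj[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    seen.add(nxt)
                    queue.append(nxt)
        comps.add(frozenset(comp))
    return comps


def components_union_find(edges, nodes):
    """Same result through a second, independent union-find implementation."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b) in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# random small-dataset generator (independent of frigg.synth)


def random_dataset(rng: random.Random, max_organisms=8, max_clusters=30):
    """A structurally random dataset: random family partition, random disjoint
    clusters.  Built straight through the public model constructors."""
    from frigg.model import GeneCluster, OrganismRecord, ProteinRecord, make_dataset

    n_org = rng.randint(2, max_organisms)
    org_ids = [f"o{i:02d}" for i in range(1, n_org + 1)]
    proteins = []
    for org in org_ids:
        for j in range(rng.randint(4, 14)):
            proteins.append((org, f"p{j:03d}"))

    # random partition into families
    shuffled = proteins[:]
    rng.shuffle(shuffled)
    families = {}
    idx = 0
    fnum = 0
    while idx < len(shuffled):
        size = rng.randint(1, 5)
        fnum += 1
        families[f"R{fnum:04d}"] = frozenset(shuffled[idx : idx + size])
        idx += size

    # random disjoint clusters per organism
    clusters = []
    n_clusters = 0
    for org in org_ids:
        pool = [p for (o, p) in proteins if o == org]
        rng.shuffle(pool)
        while pool and n_clusters < max_clusters and rng.random() < 0.8:
            size = min(len(pool), rng.randint(1, 5))
            members = tuple(pool[:size])
            pool = pool[size:]
            n_clusters += 1
            clusters.append(
                GeneCluster(
                    cluster_id=f"{org}.c{n_clusters:03d}",
                    organism_id=org,
                    members=members,
                    backbone_ids=frozenset([members[0]]),
                )
            )

    organisms = [
        OrganismRecord(organism_id=o, name=o, section=f"sec{(i % 3) + 1}")
        for i, o in enumerate(org_ids)
    ]
    records = [
        ProteinRecord(organism_id=o, protein_id=p, length_aa=rng.randint(50, 400))
        for (o, p) in proteins
    ]
    return make_dataset(organisms, records, clusters, families)
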