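"""Minimum-spanning haplotype network and matriline partition.

Identical sequences are collapsed into haplotype nodes with multiplicity;
nodes are joined by a minimum spanning tree over pairwise difference
counts (Kruskal, deterministic lexicographic tie-breaking).  The deepest
population split — e.g. two divergent matrilines — is read off by
deleting the largest tree edge: by the MST cut property that edge is the
minimum-weight connection between the two sides, so any two clusters
separated by more differences than occur within them are split exactly.
Median vectors and reticulations are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class HaplotypeNetwork:
    """Collapsed haplotypes, spanning-tree edges, and the deepest split.

    ``nodes`` maps haplotype id -> (multiplicity, member sample ids);
    ``edges`` are ``(id_a, id_b, differences)`` spanning-tree edges;
    ``partition`` is the two-set node split at the largest edge (None for
    a single-node network) and ``split_length`` that edge's difference
    count.
    """

    nodes: dict[str, tuple[int, list[str]]]
    edges: list[tuple[str, str, int]]
    partition: tuple[frozenset[str], frozenset[str]] | None
    split_length: int | None


def pairwise_differences(rows: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of differing-column counts between alignment rows.

    Rows should already be stripped of missing-data columns
    (:func:`anccap.consensus.strip_missing_columns`).
    """
    if not rows:
        return np.zeros((0, 0), dtype=int)
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError("ragged alignment")
    mat = np.array([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in rows])
    n = len(rows)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = (mat[i + 1 :] != mat[i]).sum(axis=1)
        out[i, i + 1 :] = diff
        out[i + 1 :, i] = diff
    return out


def collapse_haplotypes(ids: Sequence[str], rows: Sequence[str]) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Collapse identical sequences; returns (haplotype ids, haplotype rows, members).

    A haplotype is named after its first member (input order).
    """
    if len(ids) != len(rows):
        raise ValueError("ids and rows differ in length")
    members: dict[str, list[str]] = {}
    hap_of: dict[str, str] = {}
    hap_ids: list[str] = []
    hap_rows: list[str] = []
    for sid, row in zip(ids, rows):
        if row in hap_of:
            members[hap_of[row]].append(sid)
        else:
            hap_of[row] = sid
            members[sid] = [sid]
            hap_ids.append(sid)
            hap_rows.append(row)
    return hap_ids, hap_rows, members


def build_msn(
    diff: np.ndarray,
    ids: Sequence[str],
    multiplicities: Sequence[int] | None = None,
    members: dict[str, list[str]] | None = None,
) -> HaplotypeNetwork:
    """Minimum spanning tree over a difference matrix, plus the deepest split.

    Edges are added in ascending (weight, id_a, id_b) order (Kruskal), so
    the tree is deterministic under weight ties.  The partition deletes
    the largest tree edge (ties broken by the same lexicographic order);
    with fewer than two distinct haplotypes the partition is undefined.
    """
    n = len(ids)
    if diff.shape != (n, n):
        raise ValueError("difference matrix does not match ids")
    if not np.array_equal(diff, diff.T) or np.any(np.diag(diff) != 0):
        raise ValueError("difference matrix must be symmetric with zero diagonal")
    if multiplicities is None:
        multiplicities = [1] * n
    if members is None:
        members = {i: [i] for i in ids}
    nodes = {i: (int(m), list(members[i])) for i, m in zip(ids, multiplicities)}
    if n < 2:
        return HaplotypeNetwork(nodes=nodes, edges=[], partition=None, split_length=None)

    order = sorted(
        ((int(diff[i, j]), *sorted((ids[i], ids[j]))) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str, int]] = []
    for w, a, b in order:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, w))
            if len(edges) == n - 1:
                break

    # deepest split: remove the largest edge (last tie in sorted order wins
    # the "largest" role deterministically via max on (w, a, b))
    cut = max(edges, key=lambda e: (e[2], e[0], e[1]))
    adj: dict[str, list[str]] = {i: [] for i in ids}
    for a, b, _ in edges:
        if (a, b, _) == cut:
            continue
        adj[a].append(b)
        adj[b].append(a)
    side = {cut[0]}
    stack = [cut[0]]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in side:
                side.add(y)
                stack.append(y)
    part = (frozenset(side), frozenset(set(ids) - side))
    return HaplotypeNetwork(nodes=nodes, edges=edges, partition=part, split_length=cut[2])


def build_network(ids: Sequence[str], rows: Sequence[str]) -> HaplotypeNetwork:
    """Collapse -> pairwise differences -> MST network, in one call."""
    hap_ids, hap_rows, members = collapse_haplotypes(ids, rows)
    mult = [len(members[h]) for h in hap_ids]
    return build_msn(pairwise_differences(hap_rows), hap_ids, mult, members)


def write_network(net: HaplotypeNetwork, edge_path: str | Path, partition_path: str | Path) -> None:
    """Edge list and partition tables as TSV."""
    with open(edge_path, "w") as fh:
        fh.write("node_a\tnode_b\tdifferences\n")
        for a, b, w in net.edges:
            fh.write(f"{a}\t{b}\t{w}\n")
    with open(partition_path, "w") as fh:
        fh.write("sample\tmatriline\n")
        if net.partition is None:
            for hap, (_, mem) in net.nodes.items():
                for sid in mem:
                    fh.write(f"{sid}\tA\n")
            return
        for label, group in zip("AB", net.partition):
            for hap in sorted(group):
                for sid in net.nodes[hap][1]:
                    fh.write(f"{sid}\t{label}\n")
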