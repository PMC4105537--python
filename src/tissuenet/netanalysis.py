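"""Comparison of state networks, tissue attribution and TF trio expansion.

Edges present only before the state change "disappear", edges present only
after "emerge"; per-tissue percentages attribute each edge endpoint to its
node's tissue of maximum expression.  The trio search exhaustively scores
every 3-subset of TFs by the size of its combined neighborhood (coverage),
breaking ties by minimal pairwise-overlap redundancy and then
lexicographically.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .pcit import StateNetwork


@dataclass
class NetworkDelta:
    persistent: set[frozenset]
    disappeared: set[frozenset]
    emerged: set[frozenset]
    tissue_table: pd.DataFrame  # pct_pre, pct_post, pct_disappear, pct_emerge
    connection_fold_change: pd.Series  # per node, (post+1)/(pre+1)


def _edge_set(net: StateNetwork) -> set[frozenset]:
    return {frozenset((a, b)) for a, b, _ in net.edges()}


def _tissue_pct(edges: set[frozenset], tissue_of: dict[str, str], tissues: list[str]) -> pd.Series:
    counts = dict.fromkeys(tissues, 0)
    for e in edges:
        for node in e:
            counts[tissue_of[node]] += 1
    total = sum(counts.values())
    if total == 0:
        return pd.Series({t: 0.0 for t in tissues})
    return pd.Series({t: 100.0 * counts[t] / total for t in tissues})


def compare_networks(pre: StateNetwork, post: StateNetwork) -> NetworkDelta:
    """Set algebra on significant edges plus per-tissue endpoint attribution."""
    if set(pre.gene_ids) != set(post.gene_ids):
        diff = sorted(set(pre.gene_ids) ^ set(post.gene_ids))
        raise ValidationError(f"node sets differ: {diff}")
    e_pre = _edge_set(pre)
    e_post = _edge_set(post)
    persistent = e_pre & e_post
    disappeared = e_pre - e_post
    emerged = e_post - e_pre

    tissue_of = pre.node_attrs["tissue_of_max_expression"].to_dict()
    tissues = sorted(set(tissue_of.values()))
    table = pd.DataFrame(
        {
            "pct_pre": _tissue_pct(e_pre, tissue_of, tissues),
            "pct_post": _tissue_pct(e_post, tissue_of, tissues),
            "pct_disappear": _tissue_pct(disappeared, tissue_of, tissues),
            "pct_emerge": _tissue_pct(emerged, tissue_of, tissues),
        }
    )
    table.index.name = "tissue"

    k_pre = pre.connectivity
    k_post = post.connectivity.reindex(k_pre.index)
    fold = (k_post + 1.0) / (k_pre + 1.0)
    return NetworkDelta(persistent, disappeared, emerged, table, fold)


def trio_count(n_tf: int) -> int:
    """Number of unordered TF trios, C(n, 3)."""
    if n_tf < 3:
        raise ParameterError(f"need at least 3 TFs, got {n_tf}")
    return n_tf * (n_tf - 1) * (n_tf - 2) // 6


@dataclass
class TrioExpansion:
    trio: tuple[str, str, str]
    coverage: int
    redundancy: int
    n_trios_examined: int
    covered_nodes: set[str]


def _neighbor_bits(net: StateNetwork, tf_ids: list[str]) -> dict[str, np.ndarray]:
    pos = {g: i for i, g in enumerate(net.gene_ids)}
    return {tf: net.significant[pos[tf]].copy() for tf in tf_ids}


def best_trio(net: StateNetwork, tf_ids: list[str]) -> TrioExpansion:
    """Exhaustive search for the trio covering the most nodes.

    Coverage is the size of the union of the three neighbor sets; ties break
    by minimal summed pairwise intersection, then lexicographic trio id.
    """
    tfs = sorted(set(tf_ids) & set(net.gene_ids))
    if len(tfs) < 3:
        raise ValidationError(f"need >= 3 TFs in the network, got {len(tfs)}")
    bits = _neighbor_bits(net, tfs)
    best: tuple | None = None
    n_examined = 0
    for trio in combinations(tfs, 3):
        n_examined += 1
        a, b, c = (bits[t] for t in trio)
        coverage = int((a | b | c).sum())
        redundancy = int((a & b).sum() + (a & c).sum() + (b & c).sum())
        key = (-coverage, redundancy, trio)
        if best is None or key < best[0]:
            best = (key, trio, coverage, redundancy)
    _, trio, coverage, redundancy = best
    a, b, c = (bits[t] for t in trio)
    covered = {net.gene_ids[i] for i in np.where(a | b | c)[0]}
    return TrioExpansion(trio, coverage, redundancy, n_examined, covered)


def expansion_ability(net: StateNetwork, tf_ids: list[str]) -> pd.Series:
    """Per-TF best coverage over all trios containing that TF.

    Operationalizes "network expansion ability": how much of the topology a
    TF can span when paired with its two best partners.
    """
    tfs = sorted(set(tf_ids) & set(net.gene_ids))
    if len(tfs) < 3:
        raise ValidationError("need >= 3 TFs in the network")
    bits = _neighbor_bits(net, tfs)
    out = {}
    for tf in tfs:
        base = bits[tf]
        others = [t for t in tfs if t != tf]
        best_cov = 0
        for p, q in combinations(others, 2):
            cov = int((base | bits[p] | bits[q]).sum())
            if cov > best_cov:
                best_cov = cov
        out[tf] = best_cov
    return pd.Series(out, name="expansion")


def extract_subnetwork(
    net: StateNetwork,
    de_calls: pd.DataFrame,
    tissues: tuple[str, ...] = ("HYP", "PIT"),
    top_k: int | None = None,
) -> StateNetwork:
    """Induced subgraph on genes DE in the given tissues plus connected TFs.

    ``de_calls`` is a long-format table with columns gene, tissue, is_de and
    posterior_null (as produced by the DE stage).  ``top_k`` optionally keeps
    only the k most significant DE genes per tissue.  Node attributes gain a
    connectivity tercile label (low/medium/high).
    """
    known = set(de_calls["tissue"].unique())
    unknown = set(tissues) - known
    if unknown:
        raise ValidationError(f"unknown tissue name(s): {sorted(unknown)}")
    sel = de_calls[(de_calls["tissue"].isin(tissues)) & (de_calls["is_de"])]
    if top_k is not None:
        sel = (
            sel.sort_values("posterior_null", kind="stable")
            .groupby("tissue", group_keys=False)
            .head(top_k)
        )
    de_genes = set(sel["gene"]) & set(net.gene_ids)

    pos = {g: i for i, g in enumerate(net.gene_ids)}
    tf_nodes = set()
    for g in net.node_attrs.index[net.node_attrs["is_TF"]]:
        row = net.significant[pos[g]]
        if any(row[pos[d]] for d in de_genes):
            tf_nodes.add(g)
    keep = sorted((de_genes | tf_nodes))
    idx = [pos[g] for g in keep]
    sub_sig = net.significant[np.ix_(idx, idx)].copy()
    sub_corr = net.corr[np.ix_(idx, idx)].copy()
    attrs = net.node_attrs.loc[keep].copy()
    sub = StateNetwork(net.state, keep, sub_corr, sub_sig, attrs)

    k = sub.connectivity
    if len(k) and k.max() > 0:
        terciles = np.quantile(k, [1 / 3, 2 / 3])
        tier = np.where(k <= terciles[0], "low", np.where(k <= terciles[1], "medium", "high"))
    else:
        tier = np.array(["low"] * len(k))
    sub.node_attrs = attrs.assign(connectivity=k, connectivity_tier=tier)
    return sub
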