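"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (naive loops,
exhaustive enumeration) and share no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_log_odds(counts, background, pseudocount):
    """counts: list of per-position dicts base->count."""
    out = []
    for col in counts:
        n = sum(col.values())
        row = {}
        for b in "ACGT":
            p = (col[b] + pseudocount * background[b]) / (n + pseudocount)
            row[b] = math.log2(p / background[b])
        out.append(row)
    return out


def naive_scan(seq, counts, background, pseudocount, min_mss):
    """Sliding-window scan on both strands, one window at a time.

    Returns tuples (seq_start, seq_end, strand, raw, mss) in forward
    1-based inclusive coordinates, sorted by (start, strand).
    """
    lo = naive_log_odds(counts, background, pseudocount)
    L = len(lo)
    lo_min = sum(min(row.values()) for row in lo)
    lo_max = sum(max(row.values()) for row in lo)
    span = lo_max - lo_min
    n = len(seq)
    out = []
    for strand in "+-":
        s = seq if strand == "+" else "".join(COMP[c] for c in reversed(seq))
        for i in range(n - L + 1):
            window = s[i : i + L]
            if any(c not in "ACGT" for c in window):
                continue
            raw = sum(lo[j][window[j]] for j in range(L))
            mss = (raw - lo_min) / span if span > 0 else 1.0
            mss = min(max(mss, 0.0), 1.0)
            if mss < min_mss:
                continue
            start = i + 1 if strand == "+" else n - i - L + 1
            out.append((start, start + L - 1, strand, raw, mss))
    out.sort(key=lambda t: (t[0], t[2]))
    return out


# --- trees for the exhaustive Fitch oracle -------------------------------

def all_rooted_binary_trees(leaves):
    """All rooted binary tree shapes over the given leaf labels, as nested
    tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, k):
            right_rest = [x for x in rest if x not in left_rest]
            if not right_rest:
                continue
            for lt in all_rooted_binary_trees([first, *left_rest]):
                for rt in all_rooted_binary_trees(right_rest):
                    yield (lt, rt)


def tree_edges_and_leaves(shape):
    """Flatten a nested-tuple tree into (edges, leaf states index map).

    Nodes are numbered; returns (n_nodes, edges as (parent, child) list,
    dict leaf_label -> node index, list of internal node indices).
    """
    edges = []
    leaf_idx = {}
    internal = []
    counter = itertools.count()

    def build(node):
        idx = next(counter)
        if isinstance(node, tuple):
            internal.append(idx)
            for child in node:
                cidx = build(child)
                edges.append((idx, cidx))
        else:
            leaf_idx[node] = idx
        return idx

    build(shape)
    n = next(counter)
    return n, edges, leaf_idx, internal


def min_changes_exhaustive(shape, present_leaves):
    """Minimum number of state changes over ALL internal 0/1 assignments."""
    n, edges, leaf_idx, internal = tree_edges_and_leaves(shape)
    states = [0] * n
    for leaf, idx in leaf_idx.items():
        states[idx] = 1 if leaf in present_leaves else 0
    best = len(edges) + 1
    for assign in itertools.product((0, 1), repeat=len(internal)):
        for idx, st in zip(internal, assign):
            states[idx] = st
        changes = sum(1 for p, c in edges if states[p] != states[c])
        best = min(best, changes)
    return best


def shape_to_newick(shape, bl="1"):
    if isinstance(shape, tuple):
        inner = ",".join(f"{shape_to_newick(c, bl)}:{bl}" for c in shape)
        return f"({inner})"
    return shape


# --- pattern-miner oracle ------------------------------------------------

def maximal_conserved_subsets(chars, conserved):
    """All maximal subsets of size >= 2 in which every pair is conserved.

    ``conserved`` is a symmetric predicate on character ids.  Exhaustive
    over all subsets; feasible up to ~12 characters.
    """
    chars = sorted(chars, key=str)
    good = []
    for r in range(2, len(chars) + 1):
        for combo in itertools.combinations(chars, r):
            if all(conserved(a, b) for a, b in itertools.combinations(combo, 2)):
                good.append(set(combo))
    maximal = [
        s for s in good if not any(s < t for t in good)
    ]
    return {frozenset(s) for s in maximal}
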