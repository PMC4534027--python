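"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid every code path in ``replistool``: trees are plain
nested tuples, UniFrac is an explicit per-branch enumeration, the ANOVA is
the textbook two-pass computation with Python loops, and the distance-R²
decomposition enumerates pairs directly.
"""

from __future__ import annotations

import numpy as np

# A nested tree is either ("leaf", name, length) or ("node", children, length).


def random_nested_tree(rng: np.random.Generator, n_leaves: int,
                       mean_length: float = 0.5):
    """Random rooted binary tree as nested tuples with a Newick rendering."""
    nodes = [("leaf", f"L{i}", float(rng.exponential(mean_length)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(int(j))
        left = nodes.pop(int(i))
        nodes.append(("node", [left, right], float(rng.exponential(mean_length))))
    kind, payload, _ = nodes[0]
    root = ("node", payload, 0.0) if kind == "node" else ("node", [nodes[0]], 0.0)
    return root


def to_newick(tree) -> str:
    def render(node):
        kind, payload, length = node
        if kind == "leaf":
            return f"{payload}:{length!r}"
        inner = ",".join(render(c) for c in payload)
        return f"({inner}):{length!r}"
    kind, payload, _ = tree
    inner = ",".join(render(c) for c in payload)
    return f"({inner});"


def leaf_names(tree):
    kind, payload, _ = tree
    if kind == "leaf":
        return [payload]
    out = []
    for child in payload:
        out.extend(leaf_names(child))
    return out


def iter_branches(tree, is_root=True):
    """Yield (branch_length, frozenset of descendant leaves) per non-root edge."""
    kind, payload, length = tree
    if kind == "leaf":
        yield length, frozenset([payload])
        return
    below = frozenset()
    collected = []
    for child in payload:
        child_branches = list(iter_branches(child, is_root=False))
        collected.extend(child_branches)
        ckind, cpayload, clength = child
        if ckind == "leaf":
            below |= frozenset([cpayload])
        else:
            below |= frozenset(leaf_names(child))
    yield from collected
    if not is_root:
        yield length, below


def unweighted_unifrac_oracle(set_a, set_b, tree) -> float:
    set_a, set_b = set(set_a), set(set_b)
    shared = unique = 0.0
    for length, below in iter_branches(tree):
        to_a = bool(below & set_a)
        to_b = bool(below & set_b)
        if to_a and to_b:
            shared += length
        elif to_a or to_b:
            unique += length
    total = shared + unique
    return unique / total if total > 0 else 0.0


def weighted_unifrac_oracle(abund_a, abund_b, tree) -> float:
    total = 0.0
    for length, below in iter_branches(tree):
        pa = sum(abund_a.get(leaf, 0.0) for leaf in below)
        pb = sum(abund_b.get(leaf, 0.0) for leaf in below)
        total += length * abs(pa - pb)
    return total


def faith_pd_oracle(present, tree) -> float:
    present = set(present)
    total = 0.0
    for length, below in iter_branches(tree):
        if below & present:
            total += length
    return total


def icc_oracle(groups):
    """Textbook one-way ANOVA ICC with explicit loops (unbalanced-safe)."""
    all_vals = [v for _, vals in groups for v in vals]
    n = len(all_vals)
    g = len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(vals) * (sum(vals) / len(vals) - grand) ** 2
              for _, vals in groups)
    ssw = sum(sum((v - sum(vals) / len(vals)) ** 2 for v in vals)
              for _, vals in groups)
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    k = (n - sum(len(vals) ** 2 for _, vals in groups) / n) / (g - 1)
    denom = msb + (k - 1) * msw
    icc = (msb - msw) / denom if denom > 0 else 1.0
    return icc, msb, msw, k


def r2_oracle(d: np.ndarray, labels) -> tuple[float, float, float]:
    n = len(labels)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, lbl in enumerate(labels) if lbl == g]
        if len(idx) < 2:
            continue
        ss = sum(d[a, b] ** 2 for ii, a in enumerate(idx)
                 for b in idx[ii + 1:])
        ss_within += ss / len(idx)
    return ss_total, ss_within, 1.0 - ss_within / ss_total
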