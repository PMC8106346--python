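"""Horizontal gene transfer calls from phylogenetic tree placement.

A query domain (here, a gut-fungal PKS ketosynthase or NRPS condensation
domain) is scored against a tree of its homologs: the call is *sister* when
the query's sibling clade is purely prokaryote or purely non-fungal
eukaryote, and *nested* when the next ancestral flank is pure as well, so
the query sits inside the foreign clade. Calls are downgraded to *none*
when bootstrap support falls below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

GROUPS = ("query", "prokaryote", "nonfungal_eukaryote", "fungi_other")
FOREIGN_GROUPS = ("prokaryote", "nonfungal_eukaryote")


@dataclass(frozen=True)
class PlacementCall:
    tree_id: str
    verdict: str  # nested | sister | none
    group: str | None
    support_ok: bool

    def __post_init__(self) -> None:
        if self.verdict == "none" and self.group is not None:
            raise ValueError("verdict 'none' must not carry a group")


def read_tree(path_or_string: str, is_path: bool = True) -> dendropy.Tree:
    """Read a newick tree with FastTree/RAxML-style internal support labels."""
    kwargs = {"path": path_or_string} if is_path else {"data": path_or_string}
    return dendropy.Tree.get(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
        **kwargs,
    )


def select_homologs(
    hits_by_group: dict[str, list],
    per_group: int = 10,
    max_tree_size: int = 31,
) -> list[str]:
    """Pick homologs for tree building: up to ``per_group`` best per group.

    Groups are the three homolog pools (prokaryotes, non-fungal eukaryotes,
    other fungi), each pre-ranked by descending bitscore. The total selected
    plus the query itself never exceeds ``max_tree_size``; when the per-group
    caps would overshoot, the globally lowest-bitscore selections are dropped.
    """
    selected: list = []
    for group in sorted(hits_by_group):
        selected.extend(hits_by_group[group][:per_group])
    budget = max_tree_size - 1  # room for the query leaf
    if len(selected) > budget:
        selected = sorted(selected, key=lambda h: -h.bitscore)[:budget]
    return [h.subject_id for h in selected]


def _support(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def _leaf_groups(node: dendropy.Node, group_of: dict[str, str]) -> set[str]:
    return {
        group_of.get(leaf.taxon.label, "unknown") for leaf in node.leaf_iter()
    }


def classify_placement(
    tree: dendropy.Tree,
    group_of: dict[str, str],
    tree_id: str = "",
    min_support: float = 70.0,
    support_scope: str = "whole_tree",
) -> PlacementCall:
    """Classify the query leaf's placement relative to foreign clades.

    Let P be the query's parent node. The verdict is ``sister(G)`` when the
    union of P's non-query subtrees is non-empty and homogeneous for a single
    foreign group G, and ``nested(G)`` when additionally the extra leaves
    under P's parent all belong to G — the query is then enclosed by G on
    both flanks. ``support_scope`` is either ``whole_tree`` (every labeled
    internal branch must reach ``min_support``) or ``path_only`` (only the
    branches at P and its parent); branches without a support label are
    skipped. A verdict is downgraded to ``none`` when support fails.
    """
    queries = [
        leaf
        for leaf in tree.leaf_node_iter()
        if group_of.get(leaf.taxon.label) == "query"
    ]
    if len(queries) != 1:
        raise ValueError(f"tree {tree_id!r}: expected exactly one query leaf, got {len(queries)}")
    query = queries[0]
    parent = query.parent_node
    if parent is None:
        return PlacementCall(tree_id, "none", None, True)

    sibling_groups: set[str] = set()
    for child in parent.child_nodes():
        if child is not query:
            sibling_groups |= _leaf_groups(child, group_of)

    verdict, group = "none", None
    if len(sibling_groups) == 1 and (g := next(iter(sibling_groups))) in FOREIGN_GROUPS:
        verdict, group = "sister", g
        grand = parent.parent_node
        if grand is not None:
            flank_groups: set[str] = set()
            for child in grand.child_nodes():
                if child is not parent:
                    flank_groups |= _leaf_groups(child, group_of)
            if flank_groups == {g}:
                verdict = "nested"

    if support_scope == "whole_tree":
        in_scope = [n for n in tree.preorder_internal_node_iter() if n.parent_node is not None]
    elif support_scope == "path_only":
        in_scope = [n for n in (parent, parent.parent_node) if n is not None and n.parent_node is not None]
    else:
        raise ValueError(f"unknown support_scope {support_scope!r}")
    supports = [s for n in in_scope if (s := _support(n)) is not None]
    support_ok = all(s >= min_support for s in supports)

    if not support_ok:
        verdict, group = "none", None
    return PlacementCall(tree_id, verdict, group, support_ok)


def summarize_placements(calls: list[PlacementCall]) -> pd.DataFrame:
    """Fractions of trees per (verdict, group), plus combined sister-or-nested.

    The combined row per foreign group mirrors the headline statistic
    "fraction of domains sister to or nested within" that group. An empty
    call list yields an empty summary.
    """
    rows = []
    n = len(calls)
    if n == 0:
        return pd.DataFrame(columns=["verdict", "group", "count", "fraction"])
    combos = [(v, g) for v in ("sister", "nested") for g in FOREIGN_GROUPS]
    for verdict, group in combos + [("none", None)]:
        count = sum(1 for c in calls if c.verdict == verdict and c.group == group)
        rows.append(
            {"verdict": verdict, "group": group or "", "count": count, "fraction": count / n}
        )
    for group in FOREIGN_GROUPS:
        count = sum(
            1 for c in calls if c.group == group and c.verdict in ("sister", "nested")
        )
        rows.append(
            {
                "verdict": "sister_or_nested",
                "group": group,
                "count": count,
                "fraction": count / n,
            }
        )
    return pd.DataFrame(rows)
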