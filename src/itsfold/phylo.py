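"""Ancestral hairpin-count reconstruction on a supplied phylogeny.

Tip taxa carry unordered integer character states (hairpin counts of their
MFE structures; a taxon observed with several counts carries a state set,
and taxa without data are kept in the topology but excluded from the
character). A generalized Fitch pass (Hartigan's rule, valid for
polytomies) returns the set of equally parsimonious root states and the
minimum number of state changes. The tree is always an input — topology
inference is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy

#: tip state: frozenset of equally supported counts, or None for no data
TipState = frozenset[int] | None
TipStateMap = Mapping[str, TipState]


@dataclass
class Phylogeny:
    """A rooted tree with uniquely labeled tips (polytomies preserved)."""

    tree: dendropy.Tree

    @property
    def taxon_labels(self) -> list[str]:
        return [t.label for t in self.tree.taxon_namespace]


def read_newick(source: str | Path) -> Phylogeny:
    """Parse a newick tree from a path (or a literal newick string).

    Rejects unparsable newick and duplicate tip labels.
    """
    raw = str(source)
    if raw.rstrip().endswith(";"):
        text = raw
    else:
        path = Path(raw)
        if not path.exists():
            raise FileNotFoundError(source)
        text = path.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return Phylogeny(tree=tree)


def write_newick(phy: Phylogeny) -> str:
    return phy.tree.as_string(schema="newick").strip() + "\n"


def parse_state(token: str) -> TipState:
    """Parse a tip-state token: an integer, 'a/b' alternatives, or NA."""
    token = token.strip()
    if not token or token.upper() in {"NA", "N/A", "?", "-"}:
        return None
    return frozenset(int(t) for t in token.split("/"))


def read_tip_states(path: str | Path) -> dict[str, TipState]:
    """Two-column tab-separated file: taxon <TAB> count | 'a/b' | NA."""
    states: dict[str, TipState] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        taxon, _, token = line.partition("\t")
        states[taxon.strip()] = parse_state(token)
    return states


def _hartigan_up(node, tips: TipStateMap, counts: dict) -> tuple[frozenset | None, int]:
    """Bottom-up pass; returns (state set or None if the subtree has no
    data, changes within the subtree)."""
    if node.is_leaf():
        label = node.taxon.label if node.taxon else None
        state = tips.get(label)
        return (frozenset(state) if state else None), 0
    child_sets = []
    score = 0
    for child in node.child_nodes():
        cset, csc = _hartigan_up(child, tips, counts)
        score += csc
        if cset is not None:
            child_sets.append(cset)
    if not child_sets:
        return None, score
    if len(child_sets) == 1:
        return child_sets[0], score
    freq: dict[int, int] = {}
    for cset in child_sets:
        for s in cset:
            freq[s] = freq.get(s, 0) + 1
    top = max(freq.values())
    node_set = frozenset(s for s, c in freq.items() if c == top)
    # every child set not containing a maximal state forces one change
    score += len(child_sets) - top
    return node_set, score


def fitch_root_states(
    phy: Phylogeny, tips: TipStateMap
) -> tuple[frozenset[int], int]:
    """Most-parsimonious root state set and the minimal change count.

    Unordered (Fitch) characters; polytomies handled by Hartigan's
    generalization: a node's set is the states of maximal coverage among its
    children's sets, and each child set missing all of them costs one
    change. Tips with missing states stay in the topology but contribute no
    state. Raises if no tip has a state.
    """
    known = {t: s for t, s in tips.items() if s}
    if not known:
        raise ValueError("no tip carries a state")
    labels = set(phy.taxon_labels)
    missing = sorted(set(known) - labels)
    if missing:
        raise ValueError(f"taxa not present in the tree: {missing}")
    root_set, score = _hartigan_up(phy.tree.seed_node, tips, {})
    assert root_set is not None
    return root_set, score


def annotate_newick(phy: Phylogeny, tips: TipStateMap) -> str:
    """Newick with internal node comments carrying Hartigan state sets."""

    def annotate(node) -> frozenset | None:
        if node.is_leaf():
            state = tips.get(node.taxon.label if node.taxon else None)
            return frozenset(state) if state else None
        child_sets = [s for s in (annotate(c) for c in node.child_nodes()) if s]
        if not child_sets:
            return None
        if len(child_sets) == 1:
            node_set = child_sets[0]
        else:
            freq: dict[int, int] = {}
            for cset in child_sets:
                for s in cset:
                    freq[s] = freq.get(s, 0) + 1
            top = max(freq.values())
            node_set = frozenset(s for s, c in freq.items() if c == top)
        node.label = "|".join(str(s) for s in sorted(node_set))
        return node_set

    annotate(phy.tree.seed_node)
    return phy.tree.as_string(schema="newick", suppress_internal_node_labels=False)
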