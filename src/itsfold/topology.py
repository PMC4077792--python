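"""Hairpin/stem census of secondary structures.

A structure is decomposed into an element tree: the exterior loop at the
root, helices (maximal runs of stacked pairs; bulges and interior loops
break a helix), and the loops they close (hairpin loop, bulge, interior
loop, multibranch loop). The census rules operate on the substructures
anchored at the exterior loop ("candidates", one per exterior child helix):

* a candidate counts as ONE hairpin — branched or not — when it closes at
  least one loop and carries at least ``min_bonds`` base pairs in total
  (four pairs, i.e. eight nucleotides, by default);
* a candidate whose anchor helix does not close an immediate loop — the
  nearest hairpin loop lies at least ``stem_gap`` loop elements below the
  anchor — is censused as a stem instead.

Both thresholds are explicit parameters because manual censuses leave
edge-case conventions (e.g. a 4-bp helix interrupted by a 1-nt bulge)
underdetermined; ``bonds_scope`` switches the pair-count threshold between
the whole candidate substructure (default) and the anchor helix alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Literal

from .seqio import SecondaryStructure


class ElementKind(str, enum.Enum):
    EXTERIOR = "exterior"
    HELIX = "helix"
    HAIRPIN_LOOP = "hairpin_loop"
    BULGE = "bulge"
    INTERNAL = "internal"
    MULTIBRANCH = "multibranch"


LOOP_KINDS = frozenset(
    {ElementKind.HAIRPIN_LOOP, ElementKind.BULGE, ElementKind.INTERNAL,
     ElementKind.MULTIBRANCH}
)


@dataclass
class Element:
    """One node of the element tree.

    For a helix, ``pairs`` holds its stacked pairs outermost-first; loops
    keep ``pairs`` empty and are identified by their closing context.
    """

    kind: ElementKind
    pairs: list[tuple[int, int]] = field(default_factory=list)
    children: list["Element"] = field(default_factory=list)
    parent: "Element | None" = None

    def add(self, child: "Element") -> "Element":
        child.parent = self
        self.children.append(child)
        return child

    def walk(self) -> Iterator["Element"]:
        yield self
        for c in self.children:
            yield from c.walk()

    @property
    def n_pairs_subtree(self) -> int:
        return sum(len(e.pairs) for e in self.walk())


@dataclass
class ElementTree:
    root: Element  # the exterior loop
    seq_length: int

    @property
    def candidates(self) -> list[Element]:
        """Exterior-anchored helices, 5' to 3'."""
        return list(self.root.children)


def _direct_children(pairs: list[tuple[int, int]]) -> dict:
    """Map each pair (and None for the exterior) to its directly nested pairs."""
    children: dict = {None: []}
    stack: list[tuple[int, int]] = []
    for p in sorted(pairs):
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        children[stack[-1] if stack else None].append(p)
        children[p] = []
        stack.append(p)
    return children


def build_element_tree(structure: SecondaryStructure, seq_length: int) -> ElementTree:
    """Decompose a structure into its unique element tree.

    Every pair is assigned to exactly one helix; a helix extends only
    through perfectly stacked pairs, so any bulge or interior loop starts a
    new helix below the corresponding loop node.
    """
    structure.pair_table(seq_length)  # validates bounds/involution
    children = _direct_children(list(structure.pairs))
    root = Element(ElementKind.EXTERIOR)

    def grow(parent_el: Element, pair: tuple[int, int]) -> None:
        helix = parent_el.add(Element(ElementKind.HELIX, pairs=[pair]))
        cur = pair
        while True:
            kids = children[cur]
            if len(kids) == 1 and kids[0] == (cur[0] + 1, cur[1] - 1):
                cur = kids[0]
                helix.pairs.append(cur)
                continue
            break
        kids = children[cur]
        if not kids:
            helix.add(Element(ElementKind.HAIRPIN_LOOP))
        elif len(kids) == 1:
            (k, l) = kids[0]
            kind = (
                ElementKind.BULGE
                if k == cur[0] + 1 or l == cur[1] - 1
                else ElementKind.INTERNAL
            )
            loop = helix.add(Element(kind))
            grow(loop, kids[0])
        else:
            loop = helix.add(Element(ElementKind.MULTIBRANCH))
            for kid in kids:
                grow(loop, kid)

    for top in children[None]:
        grow(root, top)
    return ElementTree(root=root, seq_length=seq_length)


# ---------------------------------------------------------------------------
# Census


def _loops_to_nearest_hairpin(anchor: Element) -> int | None:
    """Loop elements strictly between the anchor helix and its nearest
    hairpin loop (0 = the anchor closes the hairpin loop itself)."""
    best: int | None = None
    stack = [(anchor, 0)]
    while stack:
        el, loops_below = stack.pop()
        for child in el.children:
            if child.kind is ElementKind.HAIRPIN_LOOP:
                if best is None or loops_below < best:
                    best = loops_below
            elif child.kind in LOOP_KINDS:
                stack.append((child, loops_below + 1))
            else:  # helix
                stack.append((child, loops_below))
    return best


BondsScope = Literal["substructure", "anchor_helix"]


def classify_candidates(
    tree: ElementTree,
    min_bonds: int = 4,
    stem_gap: int = 2,
    bonds_scope: BondsScope = "substructure",
) -> list[str]:
    """Label each exterior-anchored candidate 'hairpin', 'stem' or 'none'.

    ``min_bonds`` is the minimum number of base pairs ("nucleotide bonds")
    the candidate must carry; ``bonds_scope`` selects whether they are
    counted over the whole substructure or only the anchor helix. A
    qualifying candidate is a stem when its anchor helix is separated from
    the nearest hairpin loop by at least ``stem_gap`` intervening loop
    elements, a (possibly branched) hairpin otherwise.
    """
    labels = []
    for cand in tree.candidates:
        bonds = (
            cand.n_pairs_subtree
            if bonds_scope == "substructure"
            else len(cand.pairs)
        )
        if bonds < min_bonds:
            labels.append("none")
            continue
        gap = _loops_to_nearest_hairpin(cand)
        if gap is None:  # cannot happen for a finite nested structure
            labels.append("none")
        elif gap >= stem_gap:
            labels.append("stem")
        else:
            labels.append("hairpin")
    return labels


def count_hairpins(
    tree: ElementTree,
    min_bonds: int = 4,
    stem_gap: int = 2,
    bonds_scope: BondsScope = "substructure",
) -> int:
    """Number of exterior-anchored hairpins under the census rules.

    A single stem-loop and a branched substructure both count once; a
    candidate below the ``min_bonds`` pair threshold counts zero.
    """
    return classify_candidates(tree, min_bonds, stem_gap, bonds_scope).count("hairpin")


def count_stems(
    tree: ElementTree,
    min_bonds: int = 4,
    stem_gap: int = 2,
    bonds_scope: BondsScope = "substructure",
) -> int:
    """Number of exterior-anchored candidates censused as stems (structures
    that do not close an immediate loop)."""
    return classify_candidates(tree, min_bonds, stem_gap, bonds_scope).count("stem")


def paired_stats(structure: SecondaryStructure, seq_length: int) -> tuple[int, float]:
    """(number of paired bases, percentage of positions paired)."""
    structure.pair_table(seq_length)
    n_paired = 2 * structure.n_pairs
    return n_paired, 100.0 * n_paired / seq_length


@dataclass(frozen=True)
class TopologySummary:
    """Per-structure census row."""

    seq_id: str
    n_paired: int
    pct_paired: float
    n_hairpins: int
    n_stems: int


def summarize_structure(
    structure: SecondaryStructure,
    seq_length: int,
    min_bonds: int = 4,
    stem_gap: int = 2,
    bonds_scope: BondsScope = "substructure",
) -> TopologySummary:
    tree = build_element_tree(structure, seq_length)
    labels = classify_candidates(tree, min_bonds, stem_gap, bonds_scope)
    n_paired, pct = paired_stats(structure, seq_length)
    return TopologySummary(
        seq_id=structure.seq_id,
        n_paired=n_paired,
        pct_paired=pct,
        n_hairpins=labels.count("hairpin"),
        n_stems=labels.count("stem"),
    )
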