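#!/usr/bin/env python
"""Map hairpin counts onto a phylogeny and reconstruct the ancestral count.

The structured sequences stand in for taxa: they are grouped into 25
two-member 'tribes' (multiple counts per tribe become ambiguous state
sets, as in real tribe-level summaries), placed on a random coalescent-
shaped tree, and the root state set is obtained by generalized Fitch
parsimony. Outputs: results/tip_states.tsv, results/annotated.nwk,
results/root_states.tsv.
"""

import random
from pathlib import Path

import pandas as pd

from itsfold.phylo import annotate_newick, fitch_root_states, read_newick

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def random_tree(taxa: list[str], rnd: random.Random) -> str:
    nodes = list(taxa)
    while len(nodes) > 1:
        k = min(len(nodes), rnd.choice([2, 2, 2, 3]))
        group = [nodes.pop(rnd.randrange(len(nodes))) for _ in range(k)]
        nodes.append("(" + ",".join(group) + ")")
    return nodes[0] + ";"


def main() -> None:
    rnd = random.Random(SEED)
    table = pd.read_csv(OUT / "metrics.tsv", sep="\t")
    structured = table[table.seq_class == "STRUCTURED"].reset_index(drop=True)

    tips = {}
    rows = []
    for g in range(len(structured) // 2):
        members = structured.iloc[2 * g : 2 * g + 2]
        counts = sorted(set(int(c) for c in members.n_hairpins))
        taxon = f"tribe_{g + 1:02d}"
        tips[taxon] = frozenset(counts)
        rows.append({"taxon": taxon, "states": "/".join(map(str, counts))})
    pd.DataFrame(rows).to_csv(OUT / "tip_states.tsv", sep="\t", index=False)

    phy = read_newick(random_tree(sorted(tips), rnd))
    root, score = fitch_root_states(phy, tips)
    (OUT / "annotated.nwk").write_text(annotate_newick(phy, tips))
    report = (
        f"root_states\t{'/'.join(str(s) for s in sorted(root))}\n"
        f"parsimony_score\t{score}\n"
    )
    (OUT / "root_states.tsv").write_text(report)
    print(report.strip())


if __name__ == "__main__":
    main()
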