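# itsfold

Are the internal transcribed spacers (ITS1/ITS2) of the nuclear rRNA
cistron neutrally evolving phylogenetic markers, or are they under
selective constraint to preserve a self-splicing secondary structure?
`itsfold` is a pipeline for answering that question the way a molecular
evolutionist would: fold the spacer RNAs to their minimum-free-energy
(MFE) structures, enumerate their suboptimal ensembles, census hairpins
and paired bases, compare everything against random sequences matched in
length distribution and pooled GC content, and map hairpin counts onto a
phylogeny to reconstruct the ancestral state.

It is intended for people working with ITS (or other structured
spacer/intron) sequence sets who want the *entire* chain — folding engine,
null model, census rules, statistics, ancestral reconstruction — in one
auditable, seedable package rather than scattered across a folding GUI, a
shuffling script and a stats session.

## What is inside

| module | what it does |
| --- | --- |
| `itsfold.seqio` | FASTA (gapped or not), Vienna dot-bracket and CT structure files |
| `itsfold.fold` | Zuker-style MFE dynamic program over a nearest-neighbor model (Turner 2004 free energies at 37 °C shipped as plain-text tables), loop-decomposition energy evaluation, an exhaustive enumerator as oracle, and Wuchty-style best-first suboptimal enumeration with an energy band and a structure-distinctness window |
| `itsfold.topology` | element-tree decomposition (helices/loops) and the hairpin/stem census: an exterior-anchored substructure is one hairpin iff it closes a loop and carries ≥ 4 base pairs ("four bonds, i.e. eight nucleotides"); branched substructures count once; candidates whose anchor helix closes no immediate loop are stems |
| `itsfold.nullgen` | matched random null: lengths copied one-to-one, pooled GC hit exactly by count |
| `itsfold.stats` | group summaries and the two-way ANOVA (class × dataset half, type-II SS), including the energy/ensemble-size ratio test |
| `itsfold.phylo` | Fitch/Hartigan parsimony for ancestral hairpin counts on a user-supplied newick tree (polytomies, ambiguous and missing tips supported) |
| `itsfold.synthetic_data` | benchmark generator: stem-loop scaffolds with known intended structure vs matched random sequences |
| `itsfold.cli` | `itsfold` executable with `simulate / fold / census / nullgen / compare / phylo` subcommands, each writing a manifest for reproducibility |

The MFE model: pseudoknot-free structures, AU/UA/GC/CG/GU/UG pairs,
minimum hairpin loop 3, helix stacking + terminal mismatches + loop
initiations (log-extrapolated beyond 30) + Ninio asymmetry + affine
multiloops + terminal-AU penalty. For a structure *S* decomposed into
loops *L*:

    ΔG(S) = Σ_{loops ℓ ∈ L(S)} ΔG_37(ℓ),   MFE = min_S ΔG(S)

computed by the standard V/M/M1/W recursions in integer tenths of
kcal/mol. Energies agree with an independent folding engine (RNAfold,
dangles off) at r = 0.995 with a ~4% mean offset from deliberately
omitted second-order terms (dangles, coaxial stacks, tabulated special
loops); the dynamic program is tested for *exact* equality against
exhaustive enumeration on hundreds of short sequences.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale
on synthetic data with known ground truth (50 structure-constrained
scaffolds — 25 six-hairpin "ITS1-like", 25 four-hairpin "ITS2-like" —
vs 50 matched random sequences):

```bash
python analysis/01_simulate.py
python analysis/02_fold_census.py
python analysis/03_compare.py
python analysis/04_phylo.py
```

which prints (abridged):

```
structured: pooled GC 54.88%, lengths 119-217
random:     pooled GC 54.88%, lengths 119-217

            mfe_energy  n_structures  pct_paired  n_hairpins
RANDOM          -44.65         16.96       57.33        0.44
STRUCTURED      -80.60         24.46       54.86        4.94

          mfe_energy: class F=   689.04  p=1.35e-45
        n_structures: class F=    19.08  p=3.17e-05
  energy/count ratio: class F=     0.44  p=0.509

root_states	4
parsimony_score	8
```

Reading: sequences constrained to fold (STRUCTURED) reach far lower free
energies than composition-matched random sequences of identical lengths —
the class effect on MFE is overwhelming — while the per-sequence
energy/ensemble-size *ratio* shows no class effect, exactly what is
expected when both quantities scale together. The census recovers the
designed hairpin counts (mean 4.94 against the designed 6/4 mix), and the
parsimony pass reconstructs an ancestral 4-hairpin state for this
particular synthetic tree. Tables land in `results/`.

The same stages run on real data through the CLI, e.g.

```bash
itsfold fold my_its1.fasta --region ITS1 -o fold_out
itsfold nullgen my_its1.fasta --seed 1 -o null_out
itsfold phylo tribes.nwk hairpin_counts.tsv -o phylo_out
```

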