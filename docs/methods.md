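# Methods

## The question and the design

ITS1 and ITS2 are excised from the rRNA primary transcript by
structure-guided processing, so if their secondary structure is functional
they cannot be evolving neutrally. The operational test: compare folding
properties of real (or, at desk scale, synthetic structure-constrained)
sequences against random sequences with the *same* length distribution and
the *same* pooled GC content. Composition and length are the two dominant
non-structural determinants of folding energy; matching them exactly makes
the contrast attributable to sequence order, i.e. to structure.

Four quantities per sequence: MFE free energy; number of distinct
suboptimal structures within an energy band (a proxy for how uniquely the
sequence commits to one fold); paired-base fraction; hairpin count of the
MFE structure. Class differences are tested by two-way ANOVA; hairpin
counts are mapped onto a phylogeny and the root state reconstructed by
parsimony.

## Thermodynamic model

Nearest-neighbor free energies at 37 °C (Turner 2004 set), shipped as
TSVs under `src/itsfold/data/` and fully swappable via `EnergyModel`:

* helix stacking, 6 × 6 pair types (AU/UA/GC/CG/GU/UG);
* hairpin-loop initiation by loop size plus a terminal-mismatch term
  (size-3 loops get the terminal-AU/GU penalty instead, the convention of
  the published tables);
* bulge initiation (size 1 keeps the flanking stack; larger bulges add
  terminal-AU terms on both closing pairs);
* interior-loop initiation by total size, Ninio asymmetry
  0.6·|n1−n2| kcal/mol capped at 3.0, terminal mismatches on both closing
  pairs (the generic table; the tabulated 1×1/2×1/2×2 special cases are
  not used);
* multiloops affine: a + b·(branches+1) + c·unpaired with
  a = 9.3, b = −0.9, c = 0.0 kcal/mol; terminal-AU on every helix end in
  multiloops and the exterior;
* loop initiations beyond size 30 extrapolated as
  ΔG(30) + 1.07856·ln(n/30).

Omitted on purpose: dangling ends, coaxial stacking, tetra/hexaloop
bonuses. These are second-order terms whose omission keeps the loop
decomposition exactly additive (every structure's energy is a plain sum
over loops, which the exhaustive oracle can verify term-for-term). The
cost is a small systematic offset in *absolute* energies — about 4% vs an
independent engine with the full table set on random sequences — which
cancels in the class contrasts the analysis is about. Ambiguity codes
(N, R, Y, …) are retained in sequences but can never pair.

All internal arithmetic uses integer tenths of kcal/mol (the published
free energies are multiples of 0.1, so this is exact); energies are
reported to one decimal.

## Folding algorithms

*MFE.* Standard Zuker recursions with matrices V (interval closed by a
pair), M (multiloop segment with ≥ 1 branch), M1 (segment with exactly one
branch starting at its 5′ end), W (exterior prefix); interior loops
restricted to ≤ 30 unpaired bases (the usual search restriction); minimum
hairpin loop 3. Each recursion is keyed on the status of the rightmost
base, so every structure has exactly one derivation — which makes the same
recursions drive complete suboptimal enumeration. Traceback ties are
broken by a fixed rule (hairpin first, then two-loops scanned 5′-innermost
first, then multiloops by smallest last-branch start; the exterior prefers
the smallest pairing partner), so folding is fully deterministic.

*Suboptimal ensemble.* Best-first (Wuchty-style) expansion of partial
structures whose unresolved intervals carry exact completion bounds from
the DP matrices; structures therefore emerge in non-decreasing energy
order, each exactly once. The ensemble keeps structures within
`max_pct_diff` (default 10%) of the MFE, capped at `max_count` (default
50). A structure is accepted only if it contains at least one base pair
differing by ≥ `window` positions from every pair of every previously
accepted structure (window default: 3 below 200 nt, else 5 — the
classical distinctness heuristic; 0 disables the filter, yielding the
complete band, which is what the oracle tests check). With a window
active, exploration stops after `pop_limit` (default 100 000) candidate
states; because candidates arrive in energy order the result is still the
energetically first window-distinct set, and truncation is flagged on the
returned ensemble. Absolute ensemble counts depend on these settings
(as they do for any suboptimal folder), so they are treated as a
qualitative, settings-stable signal rather than a reproducible constant.

*Oracle.* `brute_force_structures` enumerates every pseudoknot-free
pairing (≤ 25 nt guard) and scores each with the loop-decomposition
evaluator. The test suite requires bit-exact agreement of DP vs oracle
minima on hundreds of random sequences, and of windowless enumeration vs
the band-filtered oracle list.

## Census rules

The element tree assigns every pair to exactly one helix (maximal stacked
runs; bulges/interior loops break helices). Census candidates are the
helices anchored on the exterior loop:

* **hairpin** — candidate whose subtree closes ≥ 1 hairpin loop and
  carries ≥ `min_bonds` = 4 base pairs in total; branched candidates count
  once. The four-bond threshold is read over the whole candidate
  substructure ("four bonds, i.e. eight nucleotides"); reading it over the
  anchor helix alone is available as `bonds_scope="anchor_helix"`.
* **stem** — qualifying candidate whose anchor helix does not close an
  immediate loop: the nearest hairpin loop lies ≥ `stem_gap` = 2 loop
  elements below the anchor. Manual censuses leave such conventions
  underdetermined, so both thresholds are explicit, documented parameters
  rather than constants.

`paired_stats` reports 2 × (number of pairs) and its percentage of
sequence length. Lengths are always ungapped sequence lengths; alignment
columns are never counted.

## Null model

`nullgen` copies the reference lengths one-to-one and places
round(L × gc_target) G/C bases per sequence uniformly at random (G vs C
and A vs U each split uniformly) — GC is matched by count, not in
expectation, so the pooled deviation is bounded by 0.5·n_seqs/total_length
(about 0.1 percentage points for 100 ITS-length sequences). Matching is
pooled ("overall") by default; per-sequence matching is an option.
Mononucleotide randomization only — a dinucleotide-preserving shuffle
would be a stricter null and is noted as an extension.

`its_like_spec` packages the observed study conditions: 50 lengths uniform
on 238–286 (ITS1 range), 50 on 177–220 (ITS2 range), pooled GC 54.9%.

## Statistics

Two-way ANOVA with factors *sequence class* (real/structured vs random)
and *dataset half* (ITS1-matched vs ITS2-matched), type-II sums of
squares, fitted by OLS (statsmodels); responses tested separately
(energy, ensemble size, and the per-sequence energy/count ratio). The
ratio is the per-sequence quantity whose class-invariance is expected
when energy and ensemble size scale together; its null behavior is
checked by simulation (counts differing between classes, energy tracking
count with class-independent multiplicative noise). Zero-variance
responses are flagged and reported as NA rather than fabricating an F.
Calibration: under the null the class factor rejects at 5% ± 1.5% over
1000 replicates and its p-values pass a KS uniformity test. No
multiple-testing correction is applied (none is applied in the analysis
this mirrors). Medians use the midpoint convention.

## Ancestral hairpin counts

Unordered (Fitch) characters on a user-supplied rooted tree, generalized
to polytomies by Hartigan's rule: a node's state set is the set of states
of maximal coverage among its children's sets, and each child set
containing none of them costs one change. Taxa observed with several
counts ("6/7") enter as ambiguous state sets; taxa without data stay in
the topology but contribute no state. The pass returns the root state set
and the parsimony score; tests require exact agreement with brute-force
minimization over all internal assignments on random trees (≤ 8 tips,
≤ 4 states, polytomies/ambiguity/missing data included). Tree inference,
bootstrap and likelihood reconstruction are out of scope.

## Synthetic data

`make_structured` concatenates k stem–loop units (stem s bp, loop ≥ 3 nt,
reverse-complement stem) separated by spacers. Spacers and loops are
A/U-biased and G-free, and spacers are re-drawn (up to 50 times) if any
4-mer could pair with a stem; the GC budget implied by `gc_target` goes
into stems first (as G-C pairs) with the exact remainder placed as C
residues in the unpaired runs, so the target is hit exactly and the
constrained and random classes are composition-identical. Defaults
(stem 8 bp, loop 5 nt, spacer 10 nt, GC 54.9%) give scaffolds whose MFE
structures recover the designed hairpin count in ≥ 90% of seeds at k = 3.

The benchmark dataset mirrors the two-region design: half the structured
class uses a 6-hairpin scaffold (ITS1-like: longer, more hairpins), half
a 4-hairpin scaffold (ITS2-like), with per-sequence spacer jitter; the
random class inherits lengths, pooled GC, and half labels one-to-one.

What the synthetic data do *not* emulate: phylogenetic correlation
between sequences, indels/length evolution, compensatory (covarying)
substitutions, or real ITS motif content. Passing tests on these data
demonstrate that the machinery detects structural constraint when present
and not when absent — they do not certify the biological conclusion for
any particular real dataset, which additionally depends on alignment,
annotation consistency and the energy model's fit.

## Problem sizes and numerical choices

Test-suite experiments are sized for a single CPU: exhaustive oracles run
on ≤ 18-nt sequences (200 for the MFE identity, 40 for enumeration
completeness), ANOVA calibration uses 1000 null replicates, the ratio
null 500, the benchmark contrast 50-vs-50 sequences of ~120–220 nt folded
MFE-only, and the acceptance script folds the 100-sequence matched null
(~15 s after JIT warm-up). The headline class contrast (p < 1e-6) is
insensitive to these sizes; quantities that do depend on settings
(ensemble counts) are asserted only directionally.

Known limitations: no pseudoknots, no partition-function/base-pair
probabilities, no dangling-end/coaxial terms (absolute energies offset a
few percent low in magnitude), suboptimal counts are settings-dependent,
and the stem/hairpin boundary implements one explicit reading of a
qualitative manual rule.
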