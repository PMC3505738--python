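# Methods

## Descriptor model

A conformer is reduced to four distance distributions, one per reference
point: the all-atom centroid (ctd), the atom closest to it (cst), the atom
farthest from it (fct), and the atom farthest from fct (ftf). ctd is the
arithmetic mean of the considered coordinates; the other three coincide with
actual atom positions, with ties broken by the lowest atom index so a fixed
input ordering gives a deterministic result. Each distribution is summarised
by three moments:

* **μ** — the mean distance (Å);
* **σ** — the *population* standard deviation (1/N normalisation): the atoms
  of a conformer are a complete population, and a single-atom distribution
  must give σ = 0 rather than an undefined sample variance;
* **κ** — the signed cube root of the third central moment (Å). The cube
  root form (rather than the standardised skewness `m₃/σ³`) keeps the value
  finite when σ = 0 and in the same units as the other moments.

Twelve moments (4 points × 3) form the classic shape vector. The extended
vector appends four blocks for the hydrophobic, aromatic, acceptor and donor
atom subsets — in that order, matching the weight indices of the similarity
metric — computed from only the subset atoms but against the **all-atom**
reference points. Re-using the global reference points is deliberate: rare
features (a typical drug-like molecule has only ~2 donors) often cannot
anchor four meaningful reference points of their own, and measuring subsets
in the global frame encodes *where* the features sit relative to the overall
shape. An empty subset yields twelve exact zeros. Within each block the
order is (ctd μ,σ,κ), (cst …), (fct …), (ftf …); this within-block convention
affects only file interoperability, never similarity values, because the
metric is a per-block L1 sum.

Hydrogens are excluded from the considered atom set by default (the
pharmacophore SMARTS address heavy atoms); `hydrogens="include"` retains
them. Pharmacophore subsets never contain hydrogens regardless of the
pattern set.

Because the descriptor sees only distance distributions it is invariant
under rotation and translation, and also under reflection — it cannot
distinguish enantiomers. That degeneracy is inherited from the moment
approach and is verified, not worked around.

## Atom typing

Subset membership is SMARTS configuration, not code. The shipped default
file (`data/pharmacophore_patterns.yaml`) defines: hydrophobic = carbons
without polar multiple bonds, halogens, thioether sulfur; aromatic = `[a]`;
donor = N/O/S bearing at least one hydrogen; acceptor = oxygens except
ester-type ether oxygen, basic trivalent nitrogens, pyridine-type aromatic
nitrogen. These are functional, documented defaults — different projects
legitimately disagree on feature definitions, so every test that depends on
typing pins this file, and users can replace it wholesale. Classes are
independent (a hydroxyl oxygen is both donor and acceptor); formal charges
and tautomers are taken as given, with no standardisation pass.

## Similarity and screening

Similarity is `S = 1/(1 + Σ_b w_b·d_b)` with `d_b` one twelfth of the L1
distance between the b-th 12-moment blocks and weights `(ow, hw, rw, aw,
dw)` applied at query time (defaults all 1.0). S is symmetric, lies in
(0, 1], equals 1 iff all weighted block distances vanish, and is
non-increasing in every weight. Keeping the weights in the metric rather
than baked into the moments lets one descriptor table serve any weighting.
All-zero weights are legal but degenerate (every pair scores 1.0); screening
warns and falls back to the deterministic tie order.

The probe-radius prefilter is defined set-theoretically: a candidate passes
iff every one of its first 12 moments lies within the radius of the query's
(a Chebyshev box on the all-atom block only, mirroring a 12-D cube-index
bounding box). Any acceleration structure must return exactly this set; the
implementation uses a vectorised interval test, so soundness is by
construction and screening with a radius covering the table is byte-identical
to a linear scan.

Ranking collapses each molecule to its best-scoring conformer, sorts by
descending score with ties broken by ascending (mol_id, conf_id), and
truncates to `top_k` molecules or `ceil(top_fraction · M)` where M counts
the molecules of the *full* table — a prefilter can shrink the retrieved
set but never re-normalises the cut. A multi-conformer query is handled by
an all-by-all cross join collapsed by the maximum pair score.

## Benchmark protocol

For each target, every active's conformer 0 (the lowest-energy conformer of
an energy-sorted ensemble) is used as the query against all conformers of
all actives and decoys, with **every** conformer of the query molecule
excluded. At each percent level x the top `ceil(x/100 · M)` molecules are
retrieved (M = molecules screened; the ceiling must be fixed for small
synthetic sets) and the enrichment factor computed as printed above:
`EF = (a/d)/(A/D)` with A, D the target's totals. When d = 0 with a > 0, d
is replaced by 1 and the record flagged — this keeps EF finite and monotone
in a. The more common convention `(a/n)/(A/N)` is available via
`ef_convention="standard"`; under it a random ranking has mean EF exactly 1,
while the printed form is mildly upward-biased at small retrieved sets (the
seeded 500-shuffle check stays within 3 standard errors of 1 for both).
Per-query EFs are averaged per target and the target means averaged again —
an unweighted two-stage mean, so targets with many actives do not dominate.

Scaffold-hopping counts compare, per query and level, the actives retrieved
by the shape method against those retrieved by a topological-fingerprint
ranking (2048-bit circular/path/tree or MACCS via the chemistry backend,
Tanimoto similarity); a query enters the summary only if both methods
retrieved at least one active, and the per-target summary reports
min/max/mean of the exclusive counts. Fingerprint values are
backend-dependent, so tests pin regression values rather than claiming
cross-toolkit equality.

The probe-radius sweep reruns the benchmark at each radius plus a
no-prefilter reference. Because the cut is taken relative to the full
molecule count, small radii can only lose candidates, so mean EF converges
(non-decreasing up to sampling noise) to the linear-scan value and equals it
exactly once the radius covers the observed moment range.

## Synthetic fixtures

The generators emulate exactly what the moment machinery consumes: labeled
point clouds. Coordinate models are a Gaussian blob (σ = 2 Å, globular), an
extended chain (1.5 Å spacing, elongated) and a ring-plus-chain hybrid;
cloud sizes default to 10–25 atoms (drug-like heavy-atom counts) and labels
are drawn independently per class with probabilities 0.40 / 0.30 / 0.15 /
0.20 (hydrophobic / aromatic / donor-scarce / acceptor), reflecting that
donors are the rarest feature in drug-like libraries. Every output is a
pure function of the spec (seed included); per-cloud streams are derived
from the seed and the molecule id via a CRC so records can be regenerated
independently.

A *shape twin* permutes the per-atom label tuples of a cloud (rejecting
permutations that change nothing, erroring when all atoms are labeled
identically): coordinates are untouched, so the first 12 moments are
bit-identical, while at least one subset block differs.

`build_benchmark_set` forms a target set from one template cloud: actives
are jittered copies (conformer k gets noise σ·(1+k), so conformer 0 is the
least perturbed, standing in for an energy-sorted ensemble) that keep the
template labels; decoys are `twin_fraction` label-permuted twins at matched
jitter plus independent clouds for the remainder. The default conditions —
10 actives, 200 decoys, twin fraction 1.0, jitter 0.15 Å, 3 conformers —
make shape uninformative by construction, so any enrichment above the
random-ranking expectation must come from the pharmacophore blocks. This is
the package's core validation scenario: it shows the subset moments rescue
discrimination where shape-only screening fails. What it does *not* show:
performance on real conformer ensembles, property-matched decoys, or
molecules of widely varying size — global moment descriptors are known to
struggle when query and library sizes differ substantially, and synthetic
clouds do not probe that.

## Numerical choices

* Third central moments smaller than the rounding error of their own
  summation (bounded by `32·N·ε·max|c|²·max(μ, max|c|)` for centred values
  c) are flushed to exact zero before the cube root. The cube root has
  unbounded derivative at zero, so without the flush a mathematically zero
  skewness — e.g. any two-atom subset — leaves ~10⁻¹⁷ cancellation residue
  that the cube root amplifies into ~10⁻⁶ jitter, destroying reproducibility
  across algebraically equivalent evaluation orders. Genuine skewness values
  sit many orders of magnitude above the bound.
* Reference-point ties (closest/farthest atoms) break by lowest atom index.
* Descriptor tables print moments at 17 significant digits (`repr`), making
  the CSV round trip bit-faithful.
* Degenerate screens (all-zero weights; an empty prefilter candidate set)
  return well-defined results — tie-ordered hits and an empty list
  respectively — rather than raising.

## Problem sizes

The validation suite uses 200 seeded clouds of 3–40 atoms for oracle and
invariance checks, a 10,000-row table for prefilter equivalence, 500
shuffles for the random-ranking EF check, and the 10-active/200-decoy twin
benchmark (3 conformers per molecule, 630 descriptor rows) for the
directional enrichment and sweep results; the full suite and the acceptance
script each run in well under a minute on one CPU.
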