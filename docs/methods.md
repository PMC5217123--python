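# Methods

## State space

The population is infinite, diploid, with two diallelic loci. The state is
the vector of ten unordered two-locus genotype frequencies; the coupling
(A0B0/A1B1) and repulsion (A0B1/A1B0) double heterozygotes are distinct
entries because they produce different gamete mixtures under linkage.
Maternal/paternal origin is never tracked. Phenotype = number of
subscript-1 alleles (0–4), an additive two-locus trait with five classes of
sizes 1, 2, 4, 2, 1.

A generation is mating followed by reproduction. Internally a mating
distribution is a symmetric 10×10 matrix of ordered pair frequencies; the
unordered frequency of a pair (i, j), i ≠ j, is the sum over both
orderings. Reproduction always enumerates the full mating table (an
einsum against a precomputed 10×10×10 offspring tensor); the gamete-pool
closed form D' = (1 − c)·D under random mating is retained only as a test
oracle, because the non-random models are defined at the mating-type level.

## Mating models and the design choices inside them

**Wright assortative.** A fraction *A* of the population assorts into the
five phenotype groups and mates at random within its group; group weight is
the phenotype-class frequency, so the within-class component of mating
(i, j) is (2 − δij)·gi·gj/f_P. The remaining 1 − *A* mates at random.
Every genotype contributes equally to the next generation, so allele
frequencies are conserved exactly (asserted to 1e-12 in the property
tests). Empty classes carry zero weight and are skipped.

**Wright disassortative.** Three isolated groups: phenotype 0 × 4 crosses,
1 × 3 crosses, and random mating within phenotype 2. How to weight crosses
when the two sides have unequal frequencies is genuinely open; the choice
here is group weight = sum of the two class frequencies, with each mate
drawn independently from its side's within-class distribution. Rare-side
genotypes thereby over-contribute per capita, which is exactly what makes
the model selective (allele frequencies move toward 1/2); this construction
reproduces the known equilibrium D = −1/28 ≈ −0.0357 and the mating shares
2.9% (0 × 4), 45.7% (1 × 3), 51.4% (2 × 2) at the symmetric equilibrium.
If one side of a cross group is empty the group is dropped and its weight
redistributed proportionally over the viable groups.

**Selective model I.** Random-mating frequencies restricted to the 18
same-phenotype mating types (1 + 3 + 10 + 3 + 1 by class), renormalised,
then mixed with random mating in proportion *A* : 1 − *A*. Equivalent to
the limit of model II in which d = 0 matings get weight 1 and all others 0
(asserted as a property test).

**Selective model II.** Each of the 55 matings weighted by its random
frequency times m = 1 − s·d/4 (assortative) or m_D = 1 − s(4 − d)/4
(disassortative), d = |phenotype difference|, renormalised. s alone
interpolates from random mating (s = 0) to maximal selectivity (s = 1);
there is no separate partial-mixing parameter.

## Measures

D is computed as x00·x11 − x01·x10 (identical to x00 − p0·q0; both are
asserted). r² = D²/(p0·p1·q0·q1). F is computed per locus as
(H_E − H_O)/H_E and the two loci averaged; d_H = H_O(AB) − H_O(A)·H_O(B).
Undefined measures (a fixed locus, zero phenotypic variance among mates)
are returned as NaN and serialised as JSON nulls — never silently 0,
because fixation is a common absorbing outcome of the selective models.

The mate correlation is the Pearson correlation of the phenotype pair over
the symmetrised ordered mating distribution. No explicit estimator is
standard for this quantity; this one was adopted because it reproduces the
expected identities — correlation = *A* at the Wright-model equilibrium,
−1 under complete disassortment, and 0.268 (c = 0.5) / 0.014 (c = 0.01)
for model II at s = 1. Note that for selective model I the often-quoted
identity "correlation = *A*" does **not** hold under this (or any weighted
Pearson) estimator except trivially at *A* = 1: e.g. at *A* = 0.25 the
correlation is 0.16 at a Hardy–Weinberg start and 0.157 at the unlinked
equilibrium. The package reports what the estimator measures.

## Numerics

* Fixed-point iteration stops when the L∞ change in genotype frequencies
  falls below 1e-12 (default; configurable), or after 2,000,000 generations.
  The deep tolerance is needed because the published equilibria carry 3–4
  significant digits and low-recombination runs approach equilibrium
  slowly (the Wright model's equilibrium is c-independent but its approach
  is not: ~4,200 generations at c = 0.01 vs ~160 at c = 0.5 for A = 1).
* The genotype vector is renormalised to sum 1 every generation. This is
  not cosmetic: the renormalising models amplify a deficit ε in the total
  by roughly (2 − A)·ε per generation, so float drift would otherwise grow
  exponentially.
* A state is classified *fixed* when a single genotype exceeds 1 − 1e-9;
  converged-but-not-fixed states are *polymorphic_equilibrium*; anything
  else is *not_converged* rather than guessed.
* Basin boundaries on the equal-initial-frequency diagonal are located by
  bisection to 1e-3 (default), with a 200,000-generation cap per probe.
  Near-boundary runs of model I decide within a few hundred generations, so
  the cap is generous. For model I at c = 0.1, A = 0.25 the polymorphic
  basin is [0.361, 0.639] (bracketed: p = 0.360 fixes, p = 0.362 reaches
  the polymorphic equilibrium), slightly wider than the coarser historical
  statement "between 0.37 and 0.63".
* Degenerate inputs: infeasible initial D raises with the violated gamete
  named; a sweep records per-point failures in an `error` column instead of
  aborting; the CLI exits 2 on configuration errors and 3 on numerical
  failure.

## Starting conditions

All equilibria are computed from Hardy–Weinberg, linkage-equilibrium starts
(`hardy_weinberg_state(p0, q0, D0)` with D0 = 0 unless stated), the
conditions under which the reference values are defined: equal allele
frequencies 1/2, or p0 = 0.2, q0 = 0.5 for the unequal-frequency Wright
case. The fixture generator supports D0 ≠ 0 within its feasibility bounds
(each derived gamete frequency in [0, 1]).

## What the package does and does not show

The recursions are exact for an infinite population, so "passing tests"
here means the implementation agrees with the model's algebra and its
published equilibria — not that any model describes a real mating system.
Finite population size (drift), mutation, viability selection after birth,
multi-allelic or n-locus traits, and eigenvalue stability analysis of the
fixed points are all out of scope; outcomes are classified purely
numerically. Known discrepancy: the reference value D = 0.0140 for the
Wright model at A = 0.25, p0 = 0.2, q0 = 0.5 is internally inconsistent
with its companion r² = 0.0047; the converged recursion gives D = 0.01364,
which matches the r² value (r² = 0.00465 → 0.0047).
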