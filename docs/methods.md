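# Methods

## Scope and model

The package links three kinds of evidence about a secreted protein family:
precursor cDNA sequences, intact-protein proteomics (deconvoluted average
masses and Edman N-terminal reads), and RNA-seq read counts. It does not
perform alignment, read mapping, spectrum deconvolution or phylogenetic
inference — those upstream results enter as inputs (FASTA and TSV tables),
and the mapping stringency used to produce counts is treated as run
metadata only.

## Sequence handling

CDS detection without an explicit `cds=` header token takes the longest
ATG-initiated open reading frame on the forward strand, leftmost on ties.
RACE products are already oriented, so the reverse strand is never
scanned. An `N` inside a codon is an error rather than an `X` residue:
every downstream consumer (masses, motifs, Edman comparison) requires
unambiguous residues. Signal peptides are removed by fixed length
(default 20 residues, the family's known signal length) rather than by a
neural predictor.

p-distance excludes gap columns pairwise, not listwise; the convention is
not fixed by any upstream source, and pairwise deletion uses the most
data per pair.

## Cysteine-motif classification

The alpha (8+6) and beta (10+8) scaffolds are counted on either side of a
domain boundary. No published rule defines where "anterior" ends, so the
boundary is the midpoint of the single largest gap between consecutive
cysteines (leftmost largest gap on ties): the two three-finger domains are
joined by a cysteine-free linker, which in any well-formed precursor is
the dominant gap. The rule is deterministic, and reversal of a sequence
swaps the anterior/posterior counts whenever the largest gap is unique.
Counts other than exactly (8, 6) or (10, 8) — including extra cysteines
outside the canonical motifs — yield `unknown` rather than a forced call.

Sequon scanning uses the canonical N-{P}-[S/T] rule; a flag restores the
unrestricted Asn-Xaa-Ser/Thr variant. Every sequon counts as a potential
glycosylation site; no occupancy score is modelled, because the site count
is only used to bound the number of glycan trees.

## Mass arithmetic

All masses are **average** masses (deconvoluted intact-protein spectra are
not isotopically resolved). The residue table is frozen in
`constants.py` so results are bit-reproducible; it agrees with Biopython's
average-mass table to ~1 ppm, which a cross-check test enforces.

Disulfide correction subtracts 2 × 1.00794 Da per bridge with
bridges = floor(n_cys/2) — the fully oxidised scaffold is assumed. An odd
cysteine count triggers a warning.

Glycoforms: each tree adds 2 HexNAc (203.19 Da each) and 3–9 hexoses
(162.14 Da each), the high-mannose range from paucimannose to Man-9.
Whether multi-tree forms are enumerated per tree or as totals is
immaterial for mass, so totals are collapsed to distinct values in
[3t, 9t]; with *s* sequons and up to three trees this gives
1 + Σ_{t=1..min(s,3)} (6t+1) distinct forms.

The default matching tolerance is ±2.0 Da (`--tol`): ion-trap
deconvolution of ~20 kDa proteins is accurate to a few Da, and at 2 Da
the synthetic recovery experiments show ≥99% top-hit recovery at 0.3 Da
mass noise. All pairs within tolerance are reported (sorted by absolute
error per observation) — matching is evidence collection, not assignment.

## Edman attribution

Reads are anchored at the mature N-terminus; Edman chemistry cannot start
mid-chain, so no offset scanning is done (a `signal_aware` option adds the
uncleaved precursor N-termini as QC targets). Blanks (`x`) are wildcards;
low-confidence calls are wildcards by default with a flag to harden them —
they are near-background signals, and hardening them can only remove
matches (a monotonicity property the tests assert). Strict mode requires
zero mismatches; all consistent candidates are returned, because two
precursors can encode an identical mature protein and the ambiguity is
real. The `wildcards_on_cys / wildcards_total` consistency ratio
quantifies the expectation that blanks sit on unmodified cysteines.

A random length-15 read matches a fixed N-terminus with probability
20⁻¹⁵ ≈ 3 × 10⁻²⁰, so strict matches are essentially never spurious; the
suite confirms zero false matches in 10⁵ vectorised trials.

## Expression quantification

RPKM uses the number of reads mapped to the SPF coding set as its
denominator (1,153,834 in the packaged reference table) — the only
denominator that reproduces the reference RPKMs, a consistency the
acceptance tests verify. Relative expression is computed on unrounded
RPKMs and is independent of the denominator (it cancels). Rounding is
half-up and applied only at report time: RPKM to 1 decimal, relative
expression to 2, clade aggregates to 1 decimal at ≥0.1% and 2 below.
`unique_reads` is carried through for reporting but not used in RPKM,
which is consistent with total gene reads. A few reference rows (e.g.
SPF1, printed 19.15 vs recomputed 19.16) are not exactly reproduced by
any single rounding convention, suggesting a marginally larger unstated
denominator upstream; the robust rows and the cumulative claims are
unaffected.

## Synthetic data

The generator emulates the study conditions: 14 precursors (~2 alpha),
20-residue signal peptides, 180–220-residue matures with a planted
scaffold whose inter-block spacer (≥20 residues) is by construction the
largest cysteine gap, 1–3 planted sequons, 0.3 Da Gaussian mass noise,
15-cycle Edman reads with full cysteine dropout, and ~1.15 M multinomial
reads. Background residues follow Swiss-Prot-like frequencies with
cysteine and asparagine excluded (scaffold and sequons are planted
exactly), which puts generated matures at a realistic ~111 Da mean
residue mass and their glycoforms in the 20–25 kDa class; the heaviest
220-residue Man-9 forms run slightly past the nominal gel window, as a
real gel band would. Back-translation uses uniform synonymous codons —
translation is the only downstream consumer, so codon usage is not
modelled. Signal peptides are hydrophobic-biased but not
predictor-realistic; only their fixed length matters. Read-count truth
proportions default to a symmetric Dirichlet(0.5) draw, giving strongly
uneven profiles like real cloacal expression. Every generator is a pure
function of (config, seed).

What passing synthetic tests does **not** show: robustness to mis-called
signal-peptide boundaries, to sequence errors in RACE contigs, to
non-high-mannose glycans (complex/hybrid types change the composition
grammar), or to Edman preview/lag artefacts. Real-data claims rest on the
reference expression table only.

## Validation experiments

`spfid.validation` packages the seeded Monte-Carlo experiments the test
suite and `scripts/acceptance.py` both run: glycoform top-hit recovery
(1000 trials, σ = 0.3 Da, tol = 2 Da, ≥99%), planted-class recovery
(1000 scaffolds, 100%), Edman source recovery (~1000 reads, 100%; zero
false matches in 10⁵ random reads), and multinomial proportion recovery
at n = 10⁶. For proportion recovery, note that over 100 replicates × 14
transcripts a perfectly calibrated sampler is *expected* to exceed 3
binomial SD a few times (normal tail 0.27%); the check is therefore that
a single seeded dataset stays within 3 SD and that the exceedance rate
across replicates stays at the tail rate, rather than demanding all 1400
z-scores stay below 3 — a bound that would fail ~98% of the time for a
correct implementation.

## Problem sizes and determinism

Default experiment sizes (1000 mass trials, 1000 scaffolds, 72 synthetic
Edman datasets, 100 proportion replicates at 10⁶ reads) give tight
empirical bounds while the whole suite runs in a few seconds. All
randomness flows through `numpy.random.default_rng` seeded from explicit
integers; fixed seeds give byte-identical generator output.
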