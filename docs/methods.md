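# Methods

## The problem

The residue immediately following the initiator methionine (iMet; we call
it *position 2*, with iMet at position 1) determines much of a nascent
chain's early fate: methionine aminopeptidases (MetAPs) cleave iMet when
position 2 carries a small-radius-of-gyration residue (A, C, G, P, S, T,
V), and the co-translational N-terminal acetyltransferases choose their
substrates by the same position (NatA acts after cleavage; NatB acetylates
retained iMet before D/E/N/Q; NatC before the bulky hydrophobics L/F/I/W).
`nterm-atlas` asks where, in an annotated proteome, position-2 residue
usage departs from the proteome-wide background — globally, inside Gene
Ontology (GO) protein groups, inside the cohort of mitochondrial precursors
carrying a cleavable targeting sequence (MTS), and among genes enriched in
selective translating-ribosome affinity purification (sel-TRAP)
experiments.

## Signed HGT scores

All significance statements use one statistic. For a subset of `n`
proteins of which `k` carry a feature, against a reference pool of `N`
items of which `K` carry it, we compute a one-tailed hypergeometric
p-value and report

    HGT = -log10 p        (upper tail)  when k/n >= K/N,
    HGT = +log10 p        (lower tail)  when k/n <  K/N,

so over-representation scores positive and under-representation negative;
HGT = 4 means p = 1e-4. Ties (F_obs = F_ref exactly) take the upper tail
and a non-negative sign.

Position-2 excesses in a real proteome reach p-values around 1e-270, far
below the smallest positive double, so tails are summed in log space: the
exact log-PMF (log-factorial differences, cached table) combined by
log-sum-exp. The test suite pins this implementation to two independent
oracles: exact integer-rational enumeration for every parameter
combination with N ≤ 60 (agreement ≤ 1e-9 on the log10 scale; observed
~5e-14) and exact big-integer arithmetic at proteome scales including a
configuration with |log10 p| > 500 (≤ 1e-6 relative; observed ~1e-15).
Relative agreement is asserted only for |log10 p| ≥ 1e-3; nearer p = 1
both the implementation and the oracle lose relative (not absolute)
precision to cancellation, which no analysis here depends on.

No multiple-testing correction is applied anywhere: raw HGT scores with
explicit thresholds (3, 4) are the reported quantities, and the null
calibration tests document the realised false-positive rates instead.

## Position-2 bias tables and the background

`F2` is a residue's frequency at position 2 (over proteins with a
canonical residue there); `Fmean` is its pooled frequency over every
position of every analyzable protein. The hypergeometric reference is
materialised from the pooled counts themselves: N = total pooled residues,
K = the residue's pooled count, n = proteins contributing at position 2,
k = the observed count. This treats the background as a finite urn rather
than an idealised frequency; the two coincide up to rounding and the urn
form keeps a single test family throughout the package. `Fmean` is the
pooled frequency, not the mean of per-position frequencies — the two
differ slightly because position coverage decays with protein length; the
pooled reading matches "average usage at any position".

Ambiguity codes (X, B, Z, J, O, U) are excluded from numerators and
denominators alike. Proteins on an exclusion list (e.g. transposon-encoded
ORFs, supplied explicitly by the user rather than re-derived from a
database) are kept in the container but invisible to every count.

## Aspecificity score

A significant position-2 bias is only interesting if it is *specific* to
position 2. For each residue we derive a reference `F2ref = 0.9*F2` when
`F2 > Fmean` (else `1.1*F2`), then slide a 100-position window over
positions 3..500 of the positional frequency profile. Each window's local
score is the percentage of its valid positions whose frequency crosses
`F2ref` (above it for over-represented residues, at or below it for
under-represented ones — the ≤ convention is deliberate, matching the more
precise of two possible phrasings); the retained aspecificity score is the
maximum local score. 0% means the position-2 signal is echoed nowhere
else. Positions 1 and 2 are excluded from the windows by default
(position 1 is the invariant iMet, position 2 is the position under test;
`start_position` exposes this choice), and positions where no protein is
long enough drop out of the local denominator. The implementation is
pinned to an exhaustive window enumeration on random vectors.

## GO scan and BestN/BestF reduction

Counting unit: proteins sharing their first 10 residues collapse to one
dedup identifier (representative = lexicographically smallest accession,
for determinism), so N-terminally identical paralog families cannot
manufacture a bias. Contingency tables per GO domain count, per term, the
dedup proteins with each residue at position 2; the proteome margins use
the same dedup universe.

The screen keeps (term, residue) pairs with HGT > 4 (strict). A fold-change
filter then removes entries with position-2 fold change < 1.8 (the
boundary value 1.8 is kept) — these are typically very large generic terms
whose enrichment is significant but weak.

Redundancy reduction is a two-stage greedy selection over protein sets
(the paper-scale GO hierarchy is deliberately not used):

* **BestN** — repeatedly select the term covering the most
  not-yet-covered bias proteins (the union, over its qualifying residues,
  of dedup members carrying the residue at position 2), subject to
  overlap < 40% with every already-selected BestN. Overlap between two
  sets is `|A∩B| / |smaller set|`, which reads "partially or fully
  included" naturally. Ties break by higher HGT, then smaller term, then
  term id; selection stops when no admissible term adds a new bias
  protein. Coverage is monotone by construction.
* **BestF** — a non-BestN term qualifies when its containment
  `|F∩parent|/|F|` in its max-containment BestN is ≥ 40% and its best
  fold change is ≥ 1.3× the parent's best fold change. Candidates are
  accepted in decreasing fold order; a candidate overlapping an accepted
  BestF by ≥ 30% replaces it only if preferable (more distinct biased
  residues, then higher fold, then term id), else it is marked redundant.
  The ≥ 30% overlap rule is applied among accepted BestF terms.

Several of these conventions (the overlap denominator, the tie-break
chain, the stopping rule, which fold "frequency bias" refers to) are not
forced by the underlying idea of the algorithm; they are fixed here for
determinism and exposed in `AnalysisConfig`. The selection is asserted
order-invariant and reproduces a hand-traceable three-term example
exactly.

A final specificity check recomputes the positional HGT profile of a
term's proteins over positions 1..100 and flags the term when any other
position matches or exceeds the position-2 score for the biased residue.

## MTS profiling

MTS membership always comes from a curated annotation table (accession,
is_mito, has_mts, compartment) — never from de-novo prediction. The MTS
and MTS-less mitochondrial cohorts are profiled position by position
(default 1..20) against the whole proteome as the urn; the expected
picture for a presequence cohort is strong positive arginine cells and
negative D/E cells over positions 3..20, with the bulky-hydrophobic
signature confined to position 2.

Cross-species conservation transfers the source species' MTS set through
an ortholog-group table: per species, the cohort is the set of orthologs
of MTS-bearing genes (MTS status inherited from the source member — the
table's orthogroups are anchored on it; missing orthologs are skipped and
counted; when a cell lists several orthologs the first is taken and the
multiplicity logged), scored against that species' own full proteome at
position 2 and as the per-residue maximum over positions 3..30. An
identity pseudo-species reproduces the within-species matrices
bit-identically (tested).

## sel-TRAP analysis

Inputs are gene-level log2(IP/input) tables for a bait IP and a reference
IP of a canonical ribosomal protein. Corrected enrichment = bait −
reference per replicate; genes missing from either table are dropped with
a count. Replicates are averaged; a gene must be present in every
replicate. The threshold sweep evaluates, at every cutoff t on the grid
−3.0..+4.0 in 0.1 steps (generated by integer arithmetic to avoid
accumulation; endpoints inclusive), the proportion and HGT of every
N-terminus class among genes with mean enrichment ≥ t, against the full
table as the urn. At the grid minimum the retained set is everything, so
proportions equal the background and HGT is exactly 0 — a structural
identity the tests assert. Targets are called at mean ≥ 0.8 by default
(the threshold where the class HGT curves peak in the motivating data);
a strict per-replicate mode is available because the two formulations
("mean ≥ 0.8" vs "≥ 0.8 in both experiments") are both defensible — the
mean is the default. The composition report uses the enrichment table
(not the whole proteome) as the background universe: the array defines
which genes could have been observed.

The mass-spec partner filter applies, per replicate and intersected
across replicates: Mascot score > 250 in the tagged IP, control ≤ 250,
tagged/control ratio ≥ 2 (a protein absent from the control counts as 0,
i.e. the ratio test passes). A kept protein scoring ≥ 5× every other bait
is assigned bait-specific, else shared.

## Synthetic data

The generators produce exactly the statistical structure the analyses
assume, with a machine-readable `FixtureTruth` for recovery tests:

* `simulate_proteome` — iMet + i.i.d. residues from a bundled yeast-like
  background table (documented constants, overridable); planted GO groups
  override position 2 with the planted residue at the planted
  probability; decoy terms are unbiased random samples. Default 1,000
  proteins; length = 30 + geometric (mean 450).
* `simulate_mts_cohort` — defaults mirror the curated yeast mitochondrial
  annotation scale: 361 MTS-bearing of 726 curated mitochondrial proteins.
  MTS members draw position 2 from a mix dominated by bulky hydrophobics
  (L 0.36, F 0.12, I 0.05, W 0.04; small-gyration residues total 0.20)
  and are Arg-enriched (p = 0.20) at positions 3–20. Pseudo-species
  orthologs mutate positions i.i.d. (default 10%) but retain the source's
  position-2 residue with probability 0.9 — a caricature of purifying
  selection at that site.
* `simulate_seltrap` — per replicate, bait = shift·1[planted class] +
  N(0, noise_sd), reference = N(0, reference_sd); defaults 1,000 genes,
  5% planted, shift 1.5, noise 0.5, two replicates.

Each generator uses one private `numpy` Generator seeded explicitly;
identical seeds give byte-identical files. What the fixtures do *not*
model: realistic length/composition coupling, GO term nesting and
hierarchy, substitution matrices or phylogeny, microarray normalisation
artefacts, and correlated replicate noise. Passing recovery tests
therefore show that the statistics detect the planted structure under
clean assumptions, not that real data meet those assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
exhaustive oracle grids to N = 60 plus 200 random cases to N = 5,000;
20-seed recovery batches for the GO scan (700 proteins, 3 planted terms,
30 decoys) and the sel-TRAP sweep (1,000 genes); a 5,959-protein planted
proteome for the deep-tail demonstration. All randomness flows from
explicit seeds; analyses themselves are deterministic given their inputs
(sorted iteration orders, lexicographic tie-breaks).

## Known limitations

* GO annotations are used flat; ancestor propagation through the ontology
  graph is intentionally out of scope (annotations are taken as
  published).
* The greedy BestN/BestF selection is one deterministic instantiation of
  an under-specified family; it is not a globally optimal set cover.
* HGT scores are raw one-tailed log p-values, not corrected for the
  number of (term, residue) pairs tested; the screening threshold of 4
  absorbs some of that burden but the scan is exploratory by design.
* The sel-TRAP module starts from normalised log-ratios; array
  normalisation, probe mapping and moderated statistics live upstream.
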