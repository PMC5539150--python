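# Methods

This note describes the models, rules and numerical choices behind
`luxcassette`, in the order the pipeline applies them, together with what
the synthetic-data generators do and do not emulate.

## Candidate mining

LuxI candidates are proteins with at least one hit to the autoinducer-
synthase domain (IPR001690) and a length inside [150, 350] aa — a permissive
envelope around the 191–292 aa range observed for Gram-positive synthases.
LuxR candidates must satisfy a two-domain rule: at least one DNA-binding
helix-turn-helix hit (IPR000792 or IPR011991) *and* at least one
autoinducer/ligand-binding-class (ABD) hit, with length in [200, 300] aa.
The ABD list is not standardised anywhere; the default —
IPR005143 (autoinducer-binding), IPR029016 (GAF-like), IPR011006
(CheY-like superfamily), IPR001789 (receiver domain) — is an explicit,
configurable reconstruction, and the LuxR filter refuses to run with an
empty ABD set rather than silently degrading to a one-domain filter.

## Redundancy reduction

Representative selection uses the classic greedy scheme: sequences sorted
longest-first each join the first cluster whose representative they match at
≥ the identity threshold (default 0.30), else found a new cluster. Identity
is matches / alignment length from a full Needleman–Wunsch global alignment
(match +1, mismatch 0, linear gap −1); a shorter-sequence denominator is
available as a flag. At desk scale the exact dynamic program is affordable,
so no k-mer pre-filter is used; traceback ties are resolved
diagonal → gap-in-second → gap-in-first, and inputs are ordered canonically
by (length, lexicographic) first, which makes the identity symmetric and
deterministic across co-optimal alignments. Because a sequence founds a new
cluster only when it is below threshold to *every* existing representative,
representatives are mutually non-redundant by construction.

## Cassette pairing and topology

Coordinates are 1-based inclusive throughout (the GFF3 convention). The gap
between two ORFs is the count of bases strictly between them
(`right.start − left.end − 1`); overlapping pairs get gap 0 and a flag. Each
luxI is paired with the nearest available luxR on its replicon with gap ≤
3400 bp (each luxR used at most once; ties prefer the smaller gap, then the
leftmost luxR). The 3400 bp default, rather than the stricter 3000 bp also
used in the cassette literature, is chosen because the published
Gram-positive cassette set itself contains a pair at gap 3258 bp; both
thresholds are exposed. Intervening genes are unclassified features of
either strand lying wholly inside the gap; counts above seven are reported
as the ">7" bucket. ORF lengths assume the annotated span includes the stop
codon: residues = (end − start + 1)/3 − 1, and spans not divisible by three
are an error naming the locus.

## Amino-acid composition

Comp(x) = A_x / N per sequence, with ambiguous "X" residues excluded from
both numerator and denominator. Group comparison is per-sequence by
default: fold change is the ratio of group means, the p-value a two-sided
Welch t-test on per-sequence fractions (Mann–Whitney U selectable for small
or non-normal groups), and a residue is significant when FC ≤ 0.80 or
FC ≥ 1.20 *and* p < 0.05. No multiple-testing correction is applied by
default (significance is defined on raw p-values); Benjamini–Hochberg is
available via a flag. A pooled (length-weighted) composition is provided
separately. Degenerate cases are made total rather than silent: a
zero-mean denominator yields an infinite fold change with a flag, and
zero-variance comparisons report p = 1.0 (identical constants) or 0.0
(different constants) instead of NaN.

## Reference-anchored conservation

Each ungapped position of the chosen reference row is scored by the
percentage of *other* rows carrying the reference residue in that column;
gaps in non-reference rows count as mismatches. The conservation threshold
defaults to ≥ 50%, the smallest value consistent with published
invariant-residue tables for LuxI; exact percentages are retained internally
and only rounded for reporting, since rounding conventions differ between
publications. The module consumes alignments; it does not compute them.

## Trees, bootstrap and HGT

Distances are p-distances over pairwise non-gap columns, optionally
Poisson-corrected (d = −ln(1 − p)); saturated pairs (p → 1) are flagged
rather than fabricated. Tree building is standard neighbor joining
(Saitou–Nei Q-criterion) with deterministic lexicographic tie-breaking and
negative branch estimates clamped to zero (counted on the tree object).
Bootstrap supports come from column resampling with replacement: the
support of an internal edge is the percentage of replicate trees containing
the same bipartition, fully reproducible for a given seed. The in-repo
builder is deliberately distance-based; externally built
maximum-likelihood trees can be imported as Newick and fed to the same
downstream logic, which is tree-agnostic.

An HGT call starts from any internal gene-tree edge with support ≥ 70
(configurable; "high support" is not standardised) whose smaller side —
restricted to tips shared with the reference tree — contains both
Gram-positive and Gram-negative tips. The call is *reference-incongruent*
when (a) the reference (16S) tree separates the Gram labels cleanly on the
shared tips and (b) the clade's bipartition is incompatible with that
Gram-label bipartition, i.e. all four pairwise intersections of clade /
complement with positives / negatives are non-empty. Incompatibility, not
mere mixedness, is the operative test: in a perfectly label-monophyletic
gene tree the complement of a pure cherry can be a supported,
gram-mixed smaller side, yet it can be drawn on the reference tree and so
is no evidence of transfer. The verdict is `hgt_supported` exactly for
mixed, supported, incongruent clades; supported mixed clades compatible
with the reference are reported as `candidate`. Shared ecological niche
between cross-group tips in the clade is annotated as corroboration but
never required — this mirrors how niche evidence is used qualitatively in
the comparative-genomics literature. The bipartition formalisation of
"deviation from the 16S tree" is one reconstruction of a qualitative
criterion; full gene-tree/species-tree reconciliation is out of scope.

Co-transfer classification compares, for each cassette, the nearest
Gram-negative partner of its tip in the LuxI, LuxR and concatenated trees.
"Nearest" is by patristic distance, but distances within 5% of the minimum
are treated as tied: patristic distances on inferred trees carry estimation
noise of exactly that order, and the strict minimum was observed to flip
between a true donor and its sister over branch-length differences of
~0.3%. Ties resolve toward the candidate sharing the smallest clade with
the tip, then the higher placement support, then lexicographically.
Placement support is the bootstrap support of the smallest bipartition side
containing both tip and partner. A cassette is `simultaneous` when all
three partners agree, `individual` when the LuxI and LuxR partners differ
with both placements supported at ≥ 70, else `unclear`. Note that for an
untransferred gene the partner is decided by which Gram-negative lineage
branches closest to the inter-clade split — when that order is weakly
resolved, single-gene events legitimately come out `unclear`; this is a
property of the data, not a defect of the rule.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a scenario seed and serialise planted
truth sufficient to score each stage.

* **Replicons** plant one cassette per replicon from an orientation class,
  gap and intervening count (defaults: the four published topology classes
  at their printed gaps), plus decoy solo luxI/luxR loci separated by
  4400 bp, beyond the 3400 bp pairing threshold. Intervening placeholder
  genes are evenly spaced inside the gap; specs whose intervening genes
  cannot fit (< 32 bp per gene) are rejected.
* **Composition groups** draw sequences i.i.d. from a bacterial background
  amino-acid frequency vector (group 1) and a multiplicatively shifted,
  renormalised copy (group 2), lengths uniform on 200–300 aa to match the
  LuxR candidate window, 50 sequences per group by default. Renormalisation
  means a nominal ×1.4 shift of alanine realises as ≈ ×1.35 with a ≈ 3%
  depression of the other residues; the truth object records the realised
  expectation. Real proteins are not i.i.d. in composition, so these groups
  test the statistic, not biological effect sizes.
* **Tree scenarios** build a random bifurcating species tree with the Gram
  labels monophyletic: two random clades (default 6 + 6 tips; terminal
  branches uniform 0.05–0.15, internal 0.03–0.10 expected
  substitutions/site) joined by a 0.6-substitutions/site separating branch —
  a strong-signal regime in which a 200-column alignment recovers the Gram
  split essentially always. Sequences evolve under an equal-rates
  (Poisson-style) substitution process: per branch of length t each site
  mutates with probability 1 − e^(−t), to a uniformly random different
  residue. A transfer event detaches the recipient tip and re-attaches it
  at the midpoint of the donor's terminal branch in a copy of the tree,
  then re-evolves the affected gene alignment there, guaranteeing the
  incongruence signal the detector tests for. The Gram-negative leaf
  closest to the inter-clade split is never auto-chosen as donor — for an
  untransferred gene that leaf is the expected nearest partner, so allowing
  it would make single-gene transfers unidentifiable from both-gene
  transfers by construction. Recipient and donor are assigned a shared
  niche so the ecological corroboration flag is exercised. The simulator
  does not model rate heterogeneity, indels, an empirical substitution
  matrix (an LG hook is left as an extension point), or genome composition;
  passing tests therefore demonstrate correctness of the detection logic
  under its stated assumptions, not performance on real divergent proteins.

## Problem sizes and reproducibility

The bundled analyses run at desk scale: statistical properties are measured
over 20 seeded replicates (composition detection, transfer recovery with
100 bootstrap replicates on 12-tip, 200-column alignments), topology
recovery over 50 random 6–10-taxon trees, and co-transfer classification
over 10 seeded scenarios per event type. All randomness flows from a single
seed through `numpy.random.default_rng` seed sequences, so every artifact —
generator output, bootstrap supports, pipeline report — is bit-for-bit
reproducible.

## Network-dependent checks

Two descriptive anchors require fetching sequences and are therefore
documented rather than tested offline: the eleven Gram-positive LuxI
UniProt entries have mean length 219 aa (minimum 191, maximum 292), and
aligning them against *V. fischeri* LuxI (P12747) shows 100% identity at
reference position R25. The 191 aa minimum is independently reproduced
offline from the bundled gene coordinates. Database-scale counts (tens of
thousands of LuxR hits, hundreds of representatives) depend on a specific
domain-database release and are out of scope.

## Known limitations

* Greedy clustering will not reproduce CD-HIT's exact membership (different
  heuristics and word sizes); only the scheme and threshold semantics match.
* The NJ builder is not a substitute statistically for maximum-likelihood
  inference on real data; it is the in-repo, fully deterministic builder,
  and external ML trees are importable.
* HGT detection is bipartition-based and cannot localise donors or count
  events; it flags incongruent clades.
* The intervening-gene bucket ">7" follows the published reporting
  convention even where a short gap makes more than seven genes physically
  implausible; the package reports what the annotation says.
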