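# Methods

This note documents the models implemented in genefam, their default
parameters, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Protein physicochemical profile

For a protein of length L over the 20 canonical residues:

* **Charged residues** — ncr = #Asp + #Glu, pcr = #Arg + #Lys;
  percentages are 100·count/L, rounded to one decimal only in report
  output (raw values retained internally).
* **GRAVY** — mean Kyte–Doolittle hydropathy; bounded by the table
  extremes [−4.5, 4.5] and invariant under sequence shuffling.
* **Aliphatic index** — Ikai's convention
  AI = X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)) on mole percents.
* **Instability index** — Guruprasad's dipeptide weights:
  II = (10/L)·Σ DIWV(aa_i, aa_i+1) over the L−1 ordered dipeptides;
  the call is *stable* iff II < 40 (II = 40 is *unstable*). II is
  direction-sensitive because DIWV is asymmetric.
* **Molecular weight** — sum of average residue masses plus one water,
  in kDa.
* **Isoelectric point** — the pH where the Henderson–Hasselbalch net
  charge is zero, found by bisection on [0, 14] to 10⁻³ pH. The pKa set
  is the EMBOSS one (Nterm 8.6, Cterm 3.6, D 3.9, E 4.1, C 8.5, Y 10.1,
  H 6.5, K 10.8, R 12.5). Published pI values for the same sequences
  vary by pKa set; this package's choice is documented and swappable,
  and no claim is made of bit-exact agreement with any web service.

All constant tables ship as versioned JSON resources
(`genefam/data/*.json`) so they can be inspected or replaced.

## Hsf motif rules and classification

DBD and HR-A/B coordinates are inputs (they come from profile-HMM and
coiled-coil tools upstream of this package). The short-motif scanners
are deliberately simple, configurable window rules validated on
exemplar motifs and planted synthetic proteins — they are *plumbing*,
not trained predictors:

* **NLS** — length-8 windows with ≥4 Lys/Arg, overlapping windows
  merged into maximal spans.
* **AHA** — length-10 windows whose central residue is Trp/Phe with ≥2
  Asp/Glu in the window, merged likewise.
* **RD** — exact LFGV/IFGV tetrapeptide occurrences, leftmost,
  non-overlapping.
* **NES** — no default rule; an explicit user pattern list is scanned
  exactly (published NES annotations are too heterogeneous for a
  defensible default).

**Classification.** Class A iff the HR-A/B extent is ≥ 40 residues
(class A Hsfs carry a ~21-aa insertion inside HR-A/B that stretches the
region); otherwise class B iff the DBD→HR-A/B linker exceeds 44
residues; otherwise class C. Coordinates are 1-based inclusive; linker
= hr.start − dbd.end − 1. The thresholds are configuration
(`ClassThresholds`), and each call records its geometry and rationale.
Published family tables do not separate all members under any single
span threshold, so family-wide class recovery from printed coordinates
is *not* asserted anywhere; the rule is validated on planted,
non-boundary synthetic geometries instead.

## Ka/Ks (NG86) and dating

The estimator is Nei–Gojobori (1986) counting with equal-weight pathway
averaging and Jukes–Cantor correction:

* per-codon synonymous sites: s = Σ_positions (#synonymous one-step
  changes)/3; changes to stop codons count as nonsynonymous; s + n = 3
  exactly, so S + N = 3 × codons for every pair (a test invariant);
* S, N are averaged over the two sequences; Sd, Nd average the
  synonymous/nonsynonymous step counts over all minimal substitution
  pathways between each codon pair, excluding pathways through stop
  codons (if every pathway is blocked — only possible at 2–3
  differences — all pathways are used; a documented tie-break);
* Ks = −¾ ln(1 − 4/3·pS) with pS = Sd/S (Ka analogously); pS or
  pN ≥ ¾ raises a saturation error; Ks = 0 makes the ratio undefined,
  serialized as `NA`, never 0 or ∞.
* gapped codon columns are dropped pairwise before counting.

Transition/transversion weighting and ML codon models are out of scope;
the NG86 engine is verified against an independent full-path-enumeration
oracle to 10⁻⁹ and recovers simulated ω ∈ {0.1, 0.3, 1.0} with
|bias| < 0.05 at 900 codons × 200 replicates.

**Sliding windows** re-run the estimator per codon-aligned window
(defaults 90 bp, step 9 bp = 3 codons; the step is configurable and
recorded in output headers). Windows that saturate or lose all sites
carry a flag instead of a value. With step = window, the per-window
difference counts partition the whole-alignment counts exactly.

**Dating** uses T = Ks/(2λ), λ = 9.1×10⁻⁹ synonymous substitutions per
site per year (the *Populus* clock), reported in MYA to two decimals.

## Duplicated blocks and duplication typing

A duplicated block is a region where ≥3 conserved homologs lie within a
15-gene window between two scaffolds. Gene rank is the 0-based ordinal
by start coordinate on its scaffold (strand-agnostic, ties by id).
"Within 15 genes" is read as an anchor-to-anchor rank gap bound on
*both* scaffolds (the alternative reading — a bound on total block
extent — is rejected as it makes long collinear blocks impossible).
Two anchors of one scaffold pair are *chainable* when their rank
distance is ≤ window on both scaffolds; blocks are the connected
components of this relation with ≥ `min_anchors` members. A connected
component of ≥3 anchors always contains a 3-anchor chain and any chain
stays inside one component, so the component reading and the literal
chain reading report identical blocks; the equivalence is exercised
against an exhaustive oracle on random layouts up to 200 genes per
scaffold. Intra-scaffold homolog pairs never anchor blocks.

**Typing**: tandem iff same scaffold with ≤5 intervening genes (the
threshold is configuration; observed tandem pairs in family surveys are
adjacent, which any threshold ≥0 satisfies); else WGD iff the pair
anchors — or lies within the window of — an inter-scaffold block; else
dispersed. Every pair receives exactly one type.

## Promoter scanning and enrichment

Promoters are the 2 kb immediately 5′ of the translation start
(position 1 = most distal; minus-strand genes take the reverse
complement of the downstream 2 kb; scaffold edges truncate with a
flag). Scanning matches IUPAC consensus patterns at every position on
both strands; an N in the sequence matches only the pattern code N;
overlapping matches are all reported; hits are per-(position, strand),
with palindromic consensi (e.g. HSE `AGAAnnTTCT`) reported once per
position. The packaged catalog holds compact published consensus
strings for the common stress/hormone/development elements and is
explicitly a replaceable stand-in for database matrices — absolute hit
counts on real genomes depend on the catalog used, so only the
enrichment *statistic* (total hits / carrying genes, ≥1 by
construction) is asserted against printed worked examples (73/27 → 2.7,
37/12 → 3.1).

## qRT-PCR analysis

Relative expression is 2^−ΔΔCt with amplification efficiency fixed at
2.0 and the 0-h control (or tissue median) as calibrator. Induction
calling runs a two-sample Student's t-test (pooled variance; Welch via
config) on log₂ expression of treated vs 0-h control replicates;
*induced* ⇔ P < 0.05 (strict) ∧ log₂FC ≥ 1 (inclusive). Zero variance
in both groups short-circuits to p = 1 (equal means) or p = 0. No
multiple-testing correction is applied by default, matching the
single-gene qPCR convention; Benjamini–Hochberg is available as an
option. Per-condition induced counts use set semantics: a gene induced
at several timepoints counts once. Tissue profiles are
log₂(value/median) with the even-count median as the mean of the two
central values, making profiles scale-invariant.

## Synthetic-data generators

All generators draw from a single `numpy.random.default_rng(seed)` and
emit ground truth; identical spec + seed reproduce identical outputs.

* **Codon pairs** are substitution-count-targeted: the number of
  synonymous (nonsynonymous) events is Poisson with mean Ks·S
  (ω·Ks·N) and each event picks uniformly among the one-step changes of
  its class available in the current sequence, so repeated hits arise
  at the rate the Jukes–Cantor correction assumes. This is a deliberate
  simplification of continuous-time codon models: it has no
  transition/transversion bias, no codon-frequency bias, and one
  mutated lineage, but it makes realized event counts exact and the
  estimator's target recoverable.
* **Layouts** place blocks and two-anchor decoys on disjoint scaffold
  pairs with planted rank gaps ≤ window, plus adjacent tandem pairs, so
  the 3-in-15 rule recovers the planted truth exactly at zero noise.
* **Promoters** start from an i.i.d. background (default GC 0.40) that
  is locally resampled until it contains *zero* catalog matches, then
  receive planted element realizations at non-overlapping recorded
  positions; the final sequence is re-scanned and regenerated until
  recovered counts equal planted counts exactly. Real promoters are not
  match-free, are not i.i.d., and have positional biases — planted-count
  recovery demonstrates scanner correctness, not realistic abundances.
* **Ct tables** use Ct = baseline − log₂(fold) + N(0, σ_Ct) per
  replicate with a constant reference Ct (default baseline 24,
  reference 18, σ_Ct 0.2, 3 replicates, timepoints 0/1/6/12 h —
  matching a typical qPCR design). Pipetting covariance, efficiency
  drift, and reference-gene instability are not modelled, so power
  estimates are upper bounds for real assays.
* **Proteins** plant DBD/HR-A/B geometries ≥5 residues away from the
  class thresholds (non-boundary cases by construction).

## Problem sizes in the default test and acceptance runs

The bundled runs use: 500 random 50-codon pairs for the oracle
comparison; 200 replicates × 900 codons per ω for recovery; layouts of
2 × 200 genes for the block oracle; 32 × 2-kb promoters for the planted
73/27 scenario; 10,000 null genes (n = 3+3) and 1,000 powered genes
(n = 4+4) for calibration. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Known limitations

* Profile-HMM domain detection, alignment construction, phylogeny
  building, and motif discovery are upstream of this package — domain
  coordinates and codon alignments are inputs.
* Printed Ka/Ks values from other estimators (ML, weighted-pathway)
  will differ from NG86; only the fully specified dating formula is
  asserted against printed values.
* pI and MW depend on the pKa/mass sets; values are reproducible within
  this package, not across services.
* The cis-element catalog is a compact consensus stand-in; absolute hit
  counts on real genomes are catalog-dependent.
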