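# Methods

This note records the models, algorithms, parameter choices and known
limitations behind each stage of the pipeline.

## Element anatomy and detection

An intact LTR retrotransposon is modelled as
`TSD + LTR + internal + LTR' + TSD`: two direct repeats (the LTRs)
flanking an internal region, with a 4–6 bp target site duplication (TSD)
in the host sequence on both sides. A solo LTR is `TSD + LTR + TSD` —
the product of intra-element unequal recombination. A complex locus is
`LTR–internal–LTR–internal–LTR` (three or more LTR copies alternating
with internal copies at one insertion site).

**Direct-repeat search.** All exact k-mers (default `seed_word = 12`)
are 2-bit encoded and sorted; k-mers occurring more than once seed
candidate repeat pairs whenever the two occurrences lie within the
maximum element length (15 kb). Seeds sharing one diagonal are merged
into runs when their gap is at most `seed_merge_gap = 300` bp — small on
purpose: mismatch clusters inside one LTR are bridged later by the
extension, while a larger gap on the same diagonal means two distinct
same-family loci that must not be chained into a chimera. Each run is
extended in both directions with an X-drop comparison of the two copies
(match +1, mismatch −2, drop-off 10), accepting a new boundary only at a
run of ≥ 3 consecutive matches so that one or two chance flank matches
cannot drag the edge outward. A k of 12 rather than something longer is
needed because TRIM LTRs of 130–250 bp at a few percent divergence do not
reliably share a longer exact word.

When the maximal extension of a repeat pair overlaps itself
(`end₁ ≥ start₂`), the locus is a tandem array: the overlap length is one
LTR, the extension period is LTR + internal, and the array spans
`n_ltrs = (span − LTR)/period + 1` LTR copies — this is how complex
elements are recognized directly, without any fragile merging of
overlapping pairwise calls. Two neighbouring independent insertions never
form such an array because the host sequence between them breaks the
period. Arrays that are also self-periodic at a period ≤ 30 bp are
simple-sequence repeats and are rejected, as is any candidate span that
is.

**Candidate filtering and overlap resolution.** Candidates must satisfy
LTR length 100–3000 bp, element length 300 bp–15 kb, repeat identity
≥ 0.80 and ≤ 10 % N. Competing overlapping candidates are resolved
greedily: TSD-corroborated candidates first, then higher identity, then
longer, then leftmost. The TSD-first rule matters when two same-family
elements sit close together: the cross-pair of their LTRs forms a longer,
similar-identity chimeric candidate, but only the true elements carry
TSDs.

**TSD calling.** The flanking L-mers are compared at L = 6, 5, 4 (first
success wins). At the exact boundary one mismatch is allowed for
L ∈ {5, 6}; a 4-bp duplication must match exactly, because with one
mismatch allowed about one random flank pair in twenty would carry a
spurious 4-bp "TSD" and intact elements without TSDs would be
systematically misclassified. Because extension boundaries carry ±1–8 bp
of noise (chance matches extend them; terminal LTR substitutions trim
them), the search also tries shifted boundaries, demanding stronger
corroboration the farther the boundary moves: small shifts (≤ 2 bp) need
only an exact TSD; inward shifts up to 8 bp (overrun corrections) need an
exact 5/6-mer; outward shifts up to 9 bp are allowed only when the
uncovered columns still agree between the two LTR copies — for a genuine
under-extension those columns are LTR sequence and must match. Element
spans exclude the TSDs.

**Homology pass.** LTRs of TSD-confirmed intact elements form the
library; the genome (both strands) is scanned by k-mer seeding plus edlib
verification at ≥ 80 % identity over ≥ 80 % of the library LTR, hits
overlapping existing calls are dropped, and surviving hits become solo
LTRs (ST/SnT after TSD calling). The library deliberately excludes
InT-only boundaries, whose jitter would propagate into every hit.
Truncated fragments below the 80/80 thresholds are not called at all.

## Families, superfamilies, lineages

Families are single-linkage clusters of elements whose LTRs align at
≥ 80 % identity over ≥ 80 % of the shorter LTR with ≥ 80 aligned bp.
LTRs (not internal regions) carry the linkage so solo LTRs can join the
family of the intact elements they derive from. Family consensus
sequences are majority-rule columns of a star alignment to the longest
member (ties alphabetical, gap-majority columns dropped).

Superfamily assignment scans the six-frame translation of the consensus
internal region against bundled INT and RT core peptides with an ungapped
+1/−1 local score; a domain is present at ≥ 40 % of the motif self-score.
INT upstream of RT ⇒ Copia; RT upstream of INT ⇒ Gypsy; no domains and
internal > 4 kb ⇒ LARD; no domains, internal < 1 kb and element < 2.5 kb
⇒ TRIM; otherwise unknown. The motif file and the per-lineage reference
RT sequences are synthetic stand-ins written for this package (see
`src/ltrscape/data/*_synthetic*`); both are plain inputs replaceable by
curated sequences.

Lineage assignment extracts the best RT window from the family consensus
and takes the lineage of the nearest same-superfamily reference by JC
distance (cap 1.5; ties broken by reference id and flagged). Trees are
Saitou–Nei neighbor joining on pairwise-alignment JC distances; negative
branch lengths are clamped to zero with the deficit moved to the sister
branch. Distances from pairwise rather than multiple alignment affect
tree cosmetics only.

## Dating

For each intact element the two LTRs are globally aligned (match +1,
mismatch −1, gap open −5, extend −1 — conventional values, configurable);
columns containing a gap or N are excluded; `p` is the mismatch
proportion of the remaining columns and `K = −(3/4)·ln(1 − 4p/3)` the
Jukes–Cantor distance (a Kimura two-parameter option exists behind
`model="K2P"`). Insertion age is `T = K/(2r)` with
r = 1.3 × 10⁻⁸ site⁻¹ yr⁻¹ for LTRs; gene-level divergence times use
r = 6.03 × 10⁻⁹ (an *Adh*-calibrated rate). "Age 0" means `p = 0`
exactly. The age histogram (0.5 My bins) is summarized by the Pearson
correlation of count vs bin midpoint (linear diagnostic) and of
ln(count) vs midpoint (exponential-decay diagnostic).

## Chromosomal distribution

Chromosomes are tiled with fixed windows; the trailing partial window is
dropped; a feature belongs to the window holding its midpoint; windows
with more than half their length in N are ineligible (the stated rule for
1-Mb windows, generalized proportionally to the smaller tiers). The
randomization test re-places the observed count of midpoints uniformly
over eligible windows `n_sim` times (default 10 000; multinomial) and
scores each window two-sidedly by |count − expected|, with the add-one
empirical p-value `(1 + #extreme)/(n_sim + 1)`. No multiple-testing
correction is applied to per-window p-values (a Benjamini–Hochberg flag
exists, off by default); the headline statistic is the fraction of
windows with p ≥ α. The discrete null makes the test slightly
conservative, which the calibration suite checks only against the upper
bound.

Marey-map recombination rates reduce the marker table to the longest
non-decreasing cM subsequence along bp and take the least-squares slope
over the 7 markers nearest each window midpoint, clamped at ≥ 0, in
cM/Mb; chromosomes with fewer than 5 usable markers get no rate.
Density–density associations are Pearson correlations with a percentile
bootstrap (default 10 000 resamples) over windows.

## Orthologous insertions and divergence

For each element with ≥ 50 bp of N-free flank and junctions that occur
exactly once in its own genome, two 100-bp junctions (50 bp flank + 50 bp
element terminus) are searched against the sister genome on both strands
at ≥ 90 % identity. An insertion is *orthologous* when each junction has
exactly one qualifying locus, both on the same strand, in the right
order, within twice the element length — the spacing/orientation rule
operationalizes the junction-consistency requirement; *absent* when the
rejoined 50-bp flanks match adjacently (up to one TSD copy between them)
but the element-side halves do not; *ambiguous* otherwise and never
counted. All four structural categories are eligible: junctions need
well-defined boundaries, which structural detection provides whether or
not the TSD survived later substitutions.

For orthologous intact elements the four LTR comparisons give K_intra
(within each genome) and K_inter (mean of the 5′ and 3′ cross-genome
divergences); insertion predating the split implies
K_intra > K_inter, tested with paired two-sided t-tests (paired because
the same elements are measured under both conditions).

Ka/Ks uses the Nei–Gojobori (1986) counting method: per-codon synonymous
site fractions (changes creating stop codons count as nonsynonymous),
site counts averaged over the two sequences, multi-hit codons averaged
over all minimal mutational paths excluding those through stop codons
(if every path is blocked, all are used so the counts stay defined), and
JC correction of pS and pN. ω is undefined at Ks = 0 and the correction
is flagged undefined at p ≥ 0.75. Divergence-time estimation bins K or
Ks in fixed 0.01 bins, takes the modal bin (ties to the lower, which is
conservative in time), and converts its edges through T = K/(2r).

## The synthetic-genome generator

The generator is the package's study system. Backgrounds are i.i.d.
bases at a chosen GC (default 0.40, typical of a plant genome), with
optional N-gap runs. Substitutions follow the Jukes–Cantor transition
kernel, which makes planted divergences additive across mutation rounds;
the manifest always records the *realized* post-mutation divergence, not
the request. Default geometry: LTRs 200–600 bp (TRIM 130–250 bp),
internal regions 2–6 kb (TRIM 0.2–0.9 kb, LARD 4.2–6.5 kb), TSDs 4–6 bp,
LTR–LTR divergence target K = 0.02 (≈ 0.77 My at the default rate),
within-family LTR divergence 0.03, ~10 elements per family, insertion
points uniform over non-N space with ≥ 300 bp of clear background around
each (an optional hotspot profile exists solely to exercise the
randomization test's power). Copia/Gypsy internals embed
reverse-translated INT/RT motifs in the superfamily's domain order.

A sister genome keeps each insertion with probability
`ortholog_fraction`; deletions remove the element plus one TSD copy,
restoring the pre-insertion site; both genomes then accumulate
independent substitutions at `point_divergence` each (so orthologous
sequence diverges by twice that, and intra-element LTR divergence grows
by the same amount in both genomes). Ortholog CDS pairs plant synonymous
and nonsynonymous changes at Poisson counts matched to the NG86
site counts, so the estimator recovers the requested Ks and ω in
expectation.

What the generator does **not** emulate: indels (configurable mutation
model is substitution-only by default — real LTR alignments gap), nested
insertions, truncated fragments, transposition bursts, recombination-
mediated solo-LTR formation, assembly errors beyond N-gaps, and base
composition beyond a single GC parameter. Passing tests therefore
demonstrate correctness of the algorithms under clean element anatomy,
not performance on a real, repeat-nested assembly.

## Reference problem sizes

The test and acceptance runs use 2–5 Mb genomes with 30–65 planted
elements, 50 elements per divergence level for dating recovery
(K* ∈ {0.005, 0.01, 0.026, 0.05}), 400 windows × 2000 simulations for
calibration, 60 elements at 1 % per-genome divergence and 50 % ortholog
fraction for orthology, 1000 random codon pairs for the NG86 oracle,
100 random 6–10-taxon additive matrices for the NJ oracle, and 100
replicates of 33 elements (insertion 3 My before a 1-My-old split) for
the intra/inter contrast. These sizes give the recovery estimates
comfortable Monte-Carlo margins while keeping a full run in minutes on
one CPU.

## Known limitations

* Boundary localization is ±1 bp typically but can err by several bp
  when terminal LTR bases are substituted; the TSD-guided refinement
  recovers most but not all such cases (4-bp TSDs with large boundary
  noise are occasionally lost to the InT class).
* Family linkage uses LTRs only; families whose LTRs diverged beyond
  80 % identity while internals remained similar would split.
* The randomization null places midpoints over eligible windows only;
  ineligible windows carry no mass.
* NG86 underestimates divergence relative to codon-model estimators at
  high divergence or strong transition bias; recovery tolerances absorb
  this at the low divergences studied here.
* The junction-uniqueness screen uses exact occurrence counts in the
  source genome; near-duplicate (but not identical) junctions pass the
  screen and are instead caught by the unique-match requirement in the
  sister genome.
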