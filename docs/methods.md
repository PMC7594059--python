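# Methods

This note documents the models, conventions and numerical choices behind
virus-prospector, and what the synthetic benchmark does and does not
demonstrate about real data.

## ORF model and genetic codes

An ORF is a *maximal stop-free translated region*: no start codon is
required, regions touching a contig end are flagged partial (5′ and/or 3′),
and trailing incomplete codons are dropped. This matches the permissive
convention used for viral dark-matter work, where assembly fragments
routinely truncate genes. Coordinates are 0-based half-open on the forward
strand; `frame` is the reading-frame offset on the record's own strand, so
reverse-complementing a contig mirrors coordinates and swaps strands but
leaves the ORF set otherwise identical (a tested invariant).

Two genetic codes are supported: NCBI translation tables 1 (standard) and
4 (protozoan/mold mitochondrial, TGA = Trp). Mito-like viruses make the
code genuinely ambiguous; the pipeline therefore predicts ORFs under every
configured code and keeps, per contig, the deduplicated union. Codons
containing N translate to X and never terminate a region — a deliberate
conservative choice: an ambiguous base should not split a long ORF.

The orphan-tier length gate is 200 aa (600 nt): shorter than most RdRps,
long enough to support evolutionary inference, and the conventional floor
for this kind of screen. The gate applies only to the orphan route; the
similarity route has no length requirement beyond the 60-aa minimum used
to enumerate search ORFs.

## Frameshift fusion

The −1 ribosomal frameshift is modeled by one slippery heptamer, GGAUUUU
(DNA `GGATTTT`), searched on both strands. Candidate fusions are generated
*systematically*: every heptamer occurrence lying inside the overlap of a
forward-strand ORF pair whose frames differ by −1 (and where the second
ORF extends further 3′) is fused. The ribosome model translates ORF1
through the last codon covering the heptamer, slips back one nucleotide,
and resumes in the −1 frame; the fused protein is the ORF1 prefix plus the
−1 continuation. Minus-strand fusions can be obtained by
reverse-complementing the contig first; the scan itself stays on the
forward strand for coordinate clarity.

## Similarity search and its statistics

The reference-set search stands in for a BLASTX stage. Alignment is
Smith–Waterman with affine gaps (BLOSUM62, gap open 11 / extend 1, the
BLASTP defaults), computed by Biopython's `PairwiseAligner`; a gap of
length *k* costs 11 + *k*. Bit scores and e-values use the Karlin–Altschul
form with the standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041, and
a search space of query length × total reference residues. These analytic
e-values are what the tier thresholds (10⁻⁵, 10⁻³) are applied to.

Because the reference search runs on translated ORFs rather than raw
contigs, the two nucleotide/protein cutoffs of a conventional two-database
screen collapse into a single protein-space pair of bounds: 10⁻⁵ separates
strong from weak hits and 10⁻³ closes the weak band. This is a deliberate
simplification — one coherent protein-space triage.

## Profile HMM scoring

Profiles are stored and exchanged in the HMMER3 flat-text dialect
(negative natural-log probabilities, `*` = probability zero, optional
`STATS` calibration lines); only the amino alphabet is supported. The
scoring model is fully local: uniform entry into any match state (cost
ln L), free exit from any match state, flanking residues scored by the
background (hence contributing zero to the log-odds). Within the model,
match/insert emissions are scored as log-odds against the background and
transitions come from the profile. Scores are reported in bits.

Viterbi and forward are exact dynamic programs over this model; the
in-row delete chain is computed by a prefix-scan (cumulative max for
Viterbi with argmax tracking for the matched interval, `logaddexp`
accumulation for forward), which keeps a 350-state × 350-residue score in
the tens of milliseconds without compiled code. Both are verified against
exhaustive path enumeration on small instances, and forward ≥ Viterbi is
asserted as a property.

E-values for profile hits come from `STATS LOCAL FORWARD` calibration when
a profile provides it (exponential tail, *E* = *N*·exp(−λ(S−τ))). Profiles
built in-package carry no calibration; a seeded 200-shuffle permutation
null is available (`profile_evalue_permutation`), but the pipeline's
arbitration deliberately runs on bit scores, not e-values, with a fixed
reporting floor (below).

Profiles are built from ungapped alignments with background pseudocounts
totalling one pseudo-observation per real sequence (a 50/50 blend). This
is the single most consequential numerical choice in the module: with
light smoothing, residues unseen in the training family cost ≈ −2 nats
each and a 40%-identity homolog scores *negative* per position on
average, so only short local islands survive; with the 50/50 blend the
same homolog scores ≈ +0.3 nats per position and aligns full length
(observed: ≳ 200 bits at 40% identity, 6–10 bits for unrelated 300-aa
sequences). Entropy-weighting schemes could sharpen this further but are
out of scope.

## Triage and arbitration

Tiers partition contigs exactly (a tested invariant). Candidate
arbitration is winner-takes-all by bit score over the union of profile
hits and reference hits, with a lexicographic name tie-break for
determinism. The winner's class decides: `rdrp_viral`/`viral` → candidate;
`decoy` → rejected `phage-like`; `nonviral` → rejected as a nonviral best
hit. Profile hits below `min_profile_bits` (default 15 bits) never enter
arbitration: a winner-takes-all rule has no intrinsic significance notion,
and without the floor a long random orphan ORF whose chance best local
segment happens to land on an RdRp profile (typical chance scores are
6–12 bits) could be promoted with no positive evidence. Fifteen bits sits
several bits above the observed chance ceiling for 200–700-aa ORFs
against 300-state profiles and four orders of magnitude below the
weakest true planted signal.

Failing the motif gate never discards a candidate — the motif chain
upgrades confidence to `confirmed`, its absence (or a noncanonical C such
as GFD) leaves the row `unresolved`. This mirrors how such candidates are
treated in practice: tabulated, but not called viral.

The motif patterns themselves (`D-x(2,4)-D`; G-rich then N/T, implemented
as `G.{0,2}G.{0,3}[NT]`; C anchored on `[GS]-x-[DN]` with canonical set
{GDD, SDD, GDN}) are a conservative operationalization of what is usually
checked by eye in curated alignments; they are declared approximations,
not validated PSSMs.

## Abundance

Counts are inputs (or synthetic truth); the module only normalizes to
percent of non-rRNA reads and bands the result. Band edges are anchored at
0.01% (average) and 1.2% (very high); boundary inclusion (≤ 0.01 average,
≥ 1.2 very high) is a declared convention, since only the two anchor
values are standard.

## Species demarcation

Identity is measured on a Needleman–Wunsch global alignment (same matrix
and gap costs as the local stage). Terminal-gap columns are excluded from
the denominator; internal gaps count as mismatches — a common convention
where none is canonical. Because co-optimal global alignments can differ
with argument order, the pair is canonically ordered (by length, then
lexicographically) before aligning, making identity exactly symmetric.

Clustering is single linkage: a demarcation threshold defines a relation
("≥ t% identical"), not a centroid, and single linkage is its transitive
closure — order-invariant and deterministic, with clusters reported by
first-seen label. Raising the threshold can only split clusters (tested).

Rank placement compares a query's identities against reference intra- and
inter-genus samples: below every intra-genus sample → new genus candidate;
at or above the 5% lower quantile of the intra-genus distribution →
existing taxon; in between → new species. The 5% quantile guards the
existing-taxon call against a single permissive intra-genus outlier.

The neighbor-joining tree (scikit-bio, on 100 − identity distances) is
lightweight plumbing for inspection. It reproduces additive matrices
exactly (tested to 1e-6) but is not a substitute for maximum-likelihood
phylogenetics, which is out of scope.

## The synthetic benchmark

The generator emulates an rRNA-depleted, assembled, nonaxenic culture
library: host-like coding contigs (diverged slices of reference host
proteins → strong nonviral hits), random-codon contigs with a
stop-frequency knob (populating the orphan and dark-matter tiers),
rRNA-like tandem repeats, bacteriophage decoy ORFs at 75–90% identity to
a decoy seed, and planted viruses. Planted RdRps are produced by
substitution-only mutation: exactly `round(L·(1−t/100))` positions change,
drawn from a BLOSUM62-derived exchangeability table, so realized identity
equals the target up to one position — which is what makes identity
recovery a sharp test. Back-translation picks synonymous codons uniformly
under the plan's genetic code (codon bias is out of scope). Read counts
are drawn log-normally (μ = 5.5, σ = 1.5 on the log scale, giving the
few-hundred-read background typical of moderately sequenced culture
libraries against a 10⁶ non-rRNA total); no read-level simulation is
performed because assembly and quantification are upstream of this
package.

The default study conditions plant three viruses spanning the detection
range — 80% identity with a −1 frameshift under code 4, 60% single-ORF
standard code, and 40% single-ORF code 4 whose seed is deliberately
absent from the reference set so it can only be found via the profile
route — on a background of 24 host, 4 rRNA-like and 4 decoy contigs.
Benchmark problem sizes (10–20 libraries of ~35 contigs, 330–350-aa
profiles) were chosen for desk-scale runtime; the seed proteins are
synthetic stand-ins carrying proper motif blocks, not real RdRps.

Consequences for interpretation: passing tests demonstrates the *logic* —
tier rules, arbitration, motif gating, frameshift reconstruction,
demarcation — under controlled divergence, not database-scale
sensitivity. Real screens face profile families with indels and entropy
weighting, chimeric and fragmented assemblies, and compositional biases
none of which the generator models (no indels in mutation, no chimeras,
no strain mixtures, no realistic rRNA structure). Absolute identity
values from the demarcation engine also depend on alignment parameters,
so demarcation *logic*, not absolute identity reproduction, is the claim.

## Degenerate inputs and tie-breaks

Empty hit lists arbitrate to "no hits"; empty tier summaries avoid
division by zero; identity of zero-overlap alignments is 0; NJ requires
three taxa; all orderings that could depend on dict/iteration order are
explicitly sorted (bit score descending, then lexicographic), making every
report byte-reproducible under a fixed configuration and seed.
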