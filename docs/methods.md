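# Methods

## Sequence model and conventions

All coordinates are 0-based, half-open, on the stored top strand; positions
on circular sequences are taken modulo length, and every positional query on
a circle is rotation-invariant. The stored top strand of a vector is the EC
(expression-cassette) sense strand; minus-strand elements occupy `[start,
end)` with their 5′ end at `end`. Translation uses the standard genetic code
(NCBI table 1); the bacterial table differs only in start-codon
permissiveness, which never affects stop logic, and starts are taken as
annotated, never inferred. Codons containing `N` translate to `X` and are
never classified as stops or target codons (conservative); lowercase input
is uppercased, `U` is rejected.

An `Orf` is frame-anchored at offset 0 and must be a multiple of 3 long. By
default it may not contain in-frame stops (other than a declared terminal
one), matching the cloning requirement that inserts be amplified without a
stop codon; `strict=False` admits stop-containing ORFs so the screening
functions can analyse them and warn.

## Restriction–ligation model

The default enzyme is SmaI (CCCGGG, blunt, cut after position 3 — geometry
from standard enzyme references). Digestion requires a unique site and
returns the linearised vector starting at the cut, so its two blunt ends are
the two halves of the destroyed site. Blunt ligation is orientation-
agnostic: with an insert we return both circular products, *forward* (insert
strand as given, i.e. in EC sense) and *reverse* (reverse-complemented);
`forward(I)` and `reverse(revcomp(I))` are identical base for base.
Self-ligation restores the site. Junction bookkeeping scans the 6-mer
windows spanning each new joint and counts re-created recognition sites
(e.g. an insert beginning GGG or ending CCC); regenerated sites are
surfaced as warnings since such products are not immune to re-digestion.
Concatemers are not modelled: unphosphorylated-insert chemistry admits at
most one insert per circle. Inserts containing an internal recognition site
are refused by the one-step simulator with an explicit "ineligible" error —
they require the two-step workflow, which is not a separate simulation path.

The single-tube (one-step) reaction is abstracted to one parameter,
`p_recut`: the probability that a restored site on a self-ligation is cut
again before transformation (default 1.0, reflecting enzyme excess over the
2-h reaction; insert-containing products are never recut). Each colony is an
independent draw with relative weights `{self: w_self·(1−p_recut), forward:
bias·w_ins, reverse: (1−bias)·w_ins}`. No measured self- vs insert-ligation
propensity is available, so `w_self = w_ins = 1` by default and both are
exposed as configuration. One seeded generator per simulation call; the seed
is recorded in outputs.

## Cassette model and phenotype prediction

`VectorModel` records the SC start, GFP ORF, EC start, cut position, His6
run, EC stop and promoter/terminator landmarks. `validate_cassette`
recomputes everything from the bases: (a) the SC reading frame from its
start codon to the last pre-GFP codon is stop-free (the antisense
read-through corridor, which includes the entire EC antisense); (b) the
enzyme cuts exactly once, at the annotated position; (c) frame congruence —
the cut lies at a codon boundary of both the EC frame and the SC frame, so
any 3n insert stays in frame with EC start/His6/stop in one orientation and
with SC start/GFP in the other; (d) the EC ORF is open and ends in exactly
six histidine codons followed by a stop.

`predict_gfp_outcome` never trusts labels: it locates the SC start and the
GFP ORF inside the actual ligation-product sequence by unique 24–30-mer
anchors taken from regions the reaction cannot disturb, then walks the SC
reading frame codon by codon. A product is fluorescent iff translation
reaches the GFP terminal stop; forward-orientation readthrough (target-
codon-free insert) is downgraded to *low_fluorescent* under the default
policy, modelling degradation of a GFP fusion carrying a random unstructured
N-terminal peptide. This destabilisation call is a rule-based heuristic —
no brightness or proteolysis rate is predicted, and the low/none boundary is
not quantified. Premature stops are mapped back to the insert's own codon
numbering and the *first* (lowest-index) flagged codon is reported, matching
the screenability scan. A reverse-orientation insert with an internal stop
in its own frame also truncates translation; it is reported as a premature
stop with an explicit warning that reverse-orientation screening is
compromised. Internal ATGs in the fused message are ignored (no
re-initiation model), and promoter strength / transcriptional interference
are not modelled.

The target-codon set is derived at run time by enumerating all 64
trinucleotides and keeping those whose reverse complement is a stop; the
result, {TCA, TTA, CTA}, is asserted rather than assumed.

### Reference vector

`build_reference_model` assembles a deterministic ~3.6 kb circular plasmid
satisfying every constraint above: SC (promoter label, 120-codon toy GFP,
terminator) opposing an EC (promoter, operator and RBS labels, start, four
codons, CCC^GGG at a codon boundary, four codons, His6, TAA, terminator),
plus neutral filler. Promoters, operator, RBS and terminators are synthetic
placeholder sequences — feature labels carry the biological identity — built
from triplets that are neither stops nor antisense stops, with CCC/GGG
excluded from random pools and a global uniqueness check (with reseeded
retries) guaranteeing a single cloning site. The model is written/read as
annotated GenBank (labels `SC_start`, `EC_start`, `EC_stop`, `GFP`, `SmaI`,
`6xHis`, `lacO`, plus promoter/terminator features). Equivalence to any real
deposited vector sequence is not claimed; the model is a structural
stand-in whose constraints are re-verified by the validator.

## Codon survey

`survey_cds` counts a gene iff at least one of its in-frame codons
(positions 0, 3, 6, …) is in the target set; out-of-frame substring matches
never count. The terminal stop codon is scanned like any other codon — it
can never match the default target set, so this is observationally neutral
there, but it matters for custom sets and is therefore documented. Records
whose length is not a multiple of 3, or that contain `N` at a scanned
position, are skipped and tallied in `n_skipped`; pseudogene and
internal-stop handling is otherwise not special-cased. The reported
`fraction` is `n_with_target / n_genes` over analysed genes, with a
per-codon breakdown (a gene may contribute to several codons, so per-codon
fractions need not sum to the total).

## qPCR copy-number estimation

Curves are fitted to the four-parameter logistic
`F(c) = F0 + Fmax/(1 + exp(−(c − c_half)/k))` by bounded least squares
(SciPy `curve_fit`), initialised at `F0 = min`, `Fmax = range`, `c_half` at
the largest first difference, `k = 1/ln 2`. Fits are rejected when residual
sum of squares exceeds 25% of the total signal variance, or when the curve
is flat or shorter than 10 cycles. In the low-signal limit the logistic
grows by `exp(1/k)` per cycle, so the amplification efficiency is
`E = exp(1/k)`; efficiencies are fitted per curve and pooled per amplicon by
the median across samples and replicates. Ct is called where
baseline-subtracted signal crosses `threshold_frac × Fmax` (default 0.1),
in closed form `Ct = c_half + k·ln(thr/(1−thr))` — at `thr = 0.5` this is
the inflection cycle, and thresholds below 0.5 cross earlier. The sigmoid
parameterisation, Ct rule and efficiency extraction are this package's own
reimplementation choices; equivalence with other qPCR toolchains holds at
the level of the RQ formula, whose sign convention (reference − test) is
followed exactly. `RQ = Ep^ΔCt_pls / Ec^ΔCt_chr`; replicate-wise RQ spread
is propagated when a complete replicate pairing exists.

The simulator generates logistic curves (40 cycles, baseline 0.05, plateau
1.0, plasmid inflection at cycle 20, chromosome at 22) in which the test
sample's plasmid template excess advances its inflection by
`log_E(ratio)` cycles, with multiplicative Gaussian noise per reading. It
emulates clean real-time traces; it does not model baseline drift, plateau
suppression, pipetting error between replicates, or inhibition, so
parameter-recovery results bound performance on well-behaved data only.

## Synthetic fixtures

Random ORFs satisfy require/forbid codon sets, forbidden motifs (checked
across codon boundaries) and an optional GC target (±0.05) by rejection
sampling capped at 10,000 attempts, followed by targeted repair (required
codons written into random in-frame positions, 1,000 attempts), so feasible
specs always succeed and pathological ones fail fast. CDS datasets plant an
exact number of target-carrying genes (`round(n·fraction)`) and shuffle the
order; gene lengths are uniform on 20–60 codons. All generators are
bit-reproducible under a fixed seed. No codon-usage bias or realistic genome
composition is modelled — survey results on these fixtures validate the
frame-aware counting, not organism-level codon statistics.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale problems chosen to
exercise every code path with comfortable statistical margins: 100–500
random sequences for property checks, 1,000-colony ligation simulations
(binomial SE ≈ 1.6 percentage points), and 50 independent simulated qPCR
experiments of 12 curves each for the copy-number median. Every stochastic
path takes an explicit seed, and CLI outputs embed the seed; JSON reports
are byte-stable for fixed inputs apart from a timestamp confined to the
metadata block.

## Known limitations

* Phenotype calls are rule-based; fluorescence intensity, proteolysis
  kinetics and promoter interference are out of scope.
* The reference vector is a synthetic structural model, not a reconstruction
  of any deposited plasmid sequence.
* The one-step model collapses digestion/ligation kinetics into `p_recut`
  and assumes independent colonies; transformation efficiency and multi-
  insert events are not modelled.
* The qPCR module estimates *relative* copy number only; absolute
  quantification, multi-gene normalisation and melt-curve analysis are out
  of scope.
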