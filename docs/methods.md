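# Methods

## The screen and its statistical model

A pooled base-editing screen couples each designed gRNA to a small,
predictable set of point mutations and uses the guide itself as the
abundance barcode for the cell subpopulation carrying those mutations.
Between the mutagenesis time point (t0) and the end of bulk competition
(t1), a guide whose edits cost fitness is depleted. The per-guide,
per-replicate statistic is the change in log2 relative abundance

    Δlog2_g = log2(n_g,t1 / N_t1) − log2(n_g,t0 / N_t0)

where n is the guide's read count and N the sample total. Δlog2 values are
standardised within each replicate (sample mean and sd over all eligible
guides, synthesis-error controls included) and z-scores are averaged across
the two replicates.

The null distribution comes from **synthesis-error (SE) guides**:
one-mismatch by-products of oligo synthesis that cannot direct editing
(their sequence no longer matches a genomic site) and therefore carry no
fitness signal. A guide read one mismatch away from a designed guide is
reclassified from "sequencing error" to SE guide when its reads exceed
7.5 % of the parent's perfectly matching reads, aggregated over all
samples; SE guides with more than 1000 total reads are retained as
negative controls, the rest are discarded. A maximum-likelihood normal fit
to the averaged z of these abundant controls converts any z threshold t
into a false-positive rate Φ((t − μ_SE)/σ_SE), hence an expected
false-positive count among the n tested (non-SE, eligible) guides, hence an
FDR estimate given the observed number of hits at t. The reported threshold
is the largest observed z value whose estimated FDR is at or below the
target (default 10 %); guides at or below it are GNEs, everything else
NSGs, and SE controls are never called.

### Calibration under count-depth heterogeneity

Guide abundances in a cloned library span an order of magnitude, so Δlog2
sampling noise varies per guide (∝ 1/√count) and the pooled null z
distribution is a scale mixture — symmetric but heavier-tailed than normal
(excess kurtosis ≈ 0.8 under the default simulator settings). The Gaussian
SE fit therefore underestimates the far-tail false-positive rate, and the
realized false-discovery proportion of the 10 % procedure runs at roughly
1.2–1.5× nominal in the simulations (pooled over seeds), with full
sensitivity for lethal outcomes at editing rates ≥ 0.5. This is a property
of the normal-null procedure itself, not of its implementation; the test
suite asserts the pooled realized FDR stays within 1.5× of nominal, and
per-seed false-discovery proportions scatter around that expectation.

## Guide design

Protospacers are enumerated by direct NGG scanning of both strands,
attributed to a gene when any extended-window position (−20…−14,
PAM-relative; −1 abuts the PAM) falls inside the gene's intervals. Filters
(each failure recorded as a reason code):

* `no_high_window_c` — no C at −19/−18/−17, nothing to edit efficiently;
* `all_three_high`, `pair_18_17`, `three_in_high_window` — co-editing
  configurations that scramble the genotype–guide link;
* `bsai` — protospacer contains GGTCTC or its reverse complement
  (incompatible with Golden-Gate library cloning);
* `not_unique` — protospacer+NGG occurs ≠ 1 time in the genome (both
  strands, exact match);
* `nag_site` — the protospacer also matches a genomic site followed by NAG
  (a weak alternative PAM that would create off-target edits);
* `cds_fraction` — the top-ranked target C falls outside the 0.5–75 % span
  of the CDS (nucleotide coordinates; truncation position is what matters,
  so the fraction is anchored to the edit site, not the PAM).

The nucleotide (rather than codon) reading of the CDS-span rule, and the
strict-majority reading of the dropout filter ("absent from more than half
of the samples" = zero count in strictly more than half), are the two
coordinate conventions this package fixes where the procedure leaves room.

**Co-editing risk.** Each guide's window 7-mer maps to a risk category.
A configurable pattern table is consulted first (shipped with the one
unambiguous anchor, NCDDDNN → very_low); everything else uses an
activity-weight rule: the highest-weight C is the intended edit and the
category grows with the secondary Cs — none → very_low; only at weight
≤ 0.1 positions → low; a mid-weight (−16) secondary → moderate; any
secondary in the high window or a CC dinucleotide (processive co-editing)
→ high.

## Outcome model

Editing activity per window position is represented by relative weights
(default −18: 1.0, −17: 0.9, −19: 0.8, −16: 0.3, −15: 0.1, −20: 0.1,
−14: 0.05). Only the *ordering* of these weights is contractual — it
encodes the editor's known activity ranking; the numbers are an editable
parameterisation, and ties break toward the PAM. The model set per guide is
{C→G, C→T} at the top-ranked editable C plus the same pair at the
second-ranked C when present (≤ 4 genotypes); C→A products are
representable in coverage denominators but never part of the model set
(they are empirically negligible). Consequences are computed by translating
the mutated CDS: a template-strand (non-coding-strand) edit appears
complemented on the mRNA (C→T ⇔ G→A, C→G ⇔ G→C). A guide is an SGG when
any model-set genotype gains a stop; by exhaustive enumeration under this
outcome spectrum the stop-capable codons are TCA, TAC (via C→G), CAA, CAG,
CGA (via C→T) and TGG (via template-strand C→T/C→G) — TGG being the only
codon reached through the non-coding strand.

Model evaluation utilities: `model_coverage` (share of edited reads
explained by the model set), `random_combination_percentile` (the q-th
percentile coverage of random k-subsets of single-edit genotypes —
exhaustive below a subset-count cap, seeded sampling above it) and
`rank_agreement_test` (within-guide permutation test of predicted vs
observed per-position editing ranks; p = (1 + #{perm ≥ obs})/(n_perm + 1)).

**Duplex melting temperature** uses nearest-neighbor thermodynamics with
the published RNA/DNA hybrid parameter set (Sugimoto et al., as shipped in
Biopython's `MeltingTemp`); the parameter table, salt and strand
concentrations are arguments.

## Synthetic screens

`generate_reference` builds random start/stop-flanked CDSs (GC content,
length range, strand and essentiality class configurable).
`simulate_screen` models each guide's subpopulation as a mixture of
unedited cells (relative fitness 1) and edited cells (relative fitness
1 − s) at the guide's editing rate; subpopulations grow deterministically
and exponentially for G generations (default 10 — exposed as a parameter
because the competition design does not pin it down), so a guide's relative
abundance changes by (1 − r) + r·2^(−sG); reads are drawn multinomially at
the configured depth per sample (default 300× per guide, two replicates,
two time points). No drift or bottleneck noise is simulated by default:
sequencing sampling is the only stochastic term. SE guides are injected as
extra rows with zero editing; they model the *abundant* SE subset retained
as controls and therefore draw their abundance from the same lognormal
(CV 0.5) as designed guides. `simulate_amplicon_genotypes` draws edited
reads over single- and double-edit genotypes with a configurable outcome
spectrum (default C→G 0.45, C→T 0.45, C→A 0.05, multi 0.05), for testing
the coverage/rank machinery.

What the simulator does **not** emulate: PCR jackpotting and chimeras,
index hopping, biological replicate noise beyond sampling, guide-specific
editing kinetics, position effects within genes, and fitness effects that
depend on the environment. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
noise model, not performance on real sequencing data.

## Numerical choices and degenerate inputs

* A zero count at t1 (only) is replaced by 0.5 before the ratio; nonzero
  counts are never perturbed, so Δlog2 is exact arithmetic otherwise.
  A zero count at t0 cannot occur for eligible guides (n ≥ 54 filter).
* z standardisation uses the sample sd (ddof 1) over all eligible guides;
  the SE-null fit is the MLE (ddof 0). Degenerate inputs (sd = 0, all-equal
  controls, fewer controls than the configurable floor of 10) are hard
  errors.
* The FDR threshold search walks observed z values only; no continuous
  root-finding. With no admissible threshold the call set is empty and the
  threshold reported as −inf.
* The SE ratio rule is evaluated on totals aggregated over all samples; a
  variant with mismatch reads but zero perfect parent reads is SE by
  convention (ratio = ∞). Boundary: ratio must strictly exceed 0.075, and
  "abundant" strictly exceeds 1000 reads; the eligibility threshold n = 54
  is inclusive.
* Read matching is exact plus unique Hamming-1 (a masked-pattern index);
  reads matching several guides at distance 1, or of the wrong length, are
  unassigned. Reads are conserved: perfect + mismatch + unassigned = input,
  and SE correction only moves reads between categories (non-abundant SE
  reads are dropped from the table but accounted in the SE set).
* Multiple-testing: the pattern-enrichment family uses Holm step-down at
  α = 0.05 (family-wise error control — that is the named procedure), with
  a Benjamini–Hochberg option for users who want FDR control instead.
* All randomness flows from explicit integer seeds (numpy `default_rng`);
  identical configs reproduce byte-identical outputs.

## Known limitations

* Off-target assessment is exact-match uniqueness plus the NAG-shadow rule
  only; no alignment-based off-target scoring and no alternative PAMs.
* The outcome model predicts ranks, not quantitative editing
  probabilities; multi-edit genotypes are handled through the risk
  category, not predicted explicitly.
* The normal SE null is mildly anti-conservative under strong count-depth
  heterogeneity (see calibration note above).
* Gene models support multiple intervals, but the designer treats intron
  targets as their own class rather than modelling splice consequences.
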