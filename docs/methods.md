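# Methods

## Recording model

A recorder channel couples an agonist concentration `c` to a tape write
rate through a Hill response,

    rate(c) = basal + (max − basal) · cⁿ / (cⁿ + EC50ⁿ)   [writes/day],

with `basal ≥ 0` the signal-independent background and `max > basal` the
saturating rate. Channels are independent; on a shared tape they compete
only for write opportunities.

**Sequential tape.** A tape copy has `n_units` (default 5) truncated target
units. Each write inserts `barcode_len` (default 3) variable bases plus a
3-bp key that completes the next unit, so writes occupy a contiguous
prefix, and the left-to-right symbol order is the temporal write order.
Time is discretised into steps of `dt = 0.05` day. Per step, a tape that is
not full writes at most once, with probability `Σ_c rate_c(t)·bias_c·dt`;
the writing channel is drawn in proportion to its term. The bound
`Σ rate·dt < 0.2` is enforced (a `ConfigError` otherwise); at the default
rates the per-step probability is ≤ 0.03 and the discretisation error of
this Bernoulli-competition scheme relative to an exact event-driven
simulation is under ~2%. Exact simulation was deliberately not used: the
discrete scheme vectorises over tens of thousands of tape copies and its
single-write-per-step rule is itself a reasonable model of editing kinetics
at these rates.

**Single-site tape.** With total write intensity
`Λ = Σ_r activity_r · plasmid_prop_r · bias_r`, a copy is edited within
time `t` with probability `1 − exp(−Λt)` and carries symbol `r` with
probability proportional to its term — the exact endpoint law of the
competing-exponentials model, so no time stepping is needed.

**Efficiency bias.** Barcode identity biases write efficiency
multiplicatively on the channel rate. `sample_efficiency_bias` draws
log-uniform multipliers spanning a fourfold range by default, matching the
observed spread in which ~91% of barcodes fall within fourfold of each
other; any mapping symbol → multiplier can be supplied instead (e.g. one
derived from the efficiency model, as the loop-closure test does).

**Read model.** Reads are sampled uniformly over tape copies (no PCR bias)
with i.i.d. substitution errors (default 0.001/base). Indels, chimeras and
quality-score structure are not modelled.

## Default parameters and calibration

Absolute write rates per day are not published; defaults are calibrated to
reported endpoint fractions and fixed:

| parameter | default | basis |
|---|---|---|
| sequential-tape `basal_rate` | 2.5e-4 /day | 6-day unstimulated background ≈ 0.15% of copies (reported 0.1–0.2%) |
| sequential-tape `max_rate` | 0.5 /day | 6-day recording concentrated at units 1–2; >60% unit-1 editing under sustained dual stimulation |
| single-site `basal_rate` | 7.5e-4 /day | 48-h background ≈ 0.15% |
| single-site `max_rate` | 11.5× / 19× / 22.6× basal | reported fold-activation of the Tet-On, NF-κB and WNT recorders |
| EC50 (TET, NFKB, WNT) | 0.17 µg/ml, 2.5 ng/ml, 2.2 µM | reported half-maximal agonist concentrations, each in its native units |
| Hill n | 1.2–2.0 | WNT set steepest (near switch-like over a fourfold dose range) |
| tapes per cell | 20 | typical synthetic-tape integration count |
| `dt` | 0.05 day | keeps Σrate·dt ≤ 0.03 at defaults |

Programme concentrations in the default enumerator (0.1 µg/ml doxycycline
equivalent for TET, 3 µM CHIR equivalent for WNT; 5× pulse dose) sit in the
responsive-to-saturating range of the corresponding EC50s so the two
channels run at comparable rates.

## Temporal programmes

`enumerate_programmes` generates three families over a 6-day experiment:
serial (first agonist on `[0,d)`, second on `[d,2d)`), layered (first
throughout, second joining at day `d`), for `d ∈ {1,2,3}` and both orders
(12 programmes), plus three pulse programmes (24-h pulse of one channel at
day 0/2/4 against continuous co-stimulation): 15 in total. The pulse
programmes share identical per-channel exposure integrals by construction;
their per-symbol write totals agree so long as the tape stays well below
capacity — at saturating co-stimulation ~6% of copies fill and a late
pulse loses a few percent of its writes, a real capacity effect to keep in
mind when comparing totals.

## Decoding

Parsing is a deterministic flank walk, not alignment: every feature of the
amplicon sits at a computable offset once the number of insertions is
known, so the parser anchors on the constant left flank, then per unit
either matches the unedited unit sequence (recording stopped) or reads
barcode + key. Matching is exact by default; `max_flank_mismatch=1` gives a
permissive mode. Reads failing the walk (an error in a constant region, an
uncorrectable barcode) are discarded and counted; at 0.1%/base error ~10%
of reads are discarded, approximately uniformly across tape states.
Reverse-complement reads are normalised to reference orientation first.

Barcode correction assigns exact matches, then unique Hamming-1 neighbours;
vocabularies with minimum pairwise distance ≥ 3 make ties impossible
(asserted). Ambiguous matches in user-supplied lower-distance sets are
discarded, not split. Symbols with fewer than five reads are reclassified
as unassigned — filtering happens after correction — so sample totals stay
auditable at every stage.

**Gram statistics.** Unigram (site, symbol) and bigram (adjacent pair,
symbol pair) proportions use total parsed reads as the single denominator,
keeping all 26 encoding variables on one scale for PCA. The bigram
log2-ratio uses raw counts with a pseudocount of 0.5 per direction
(Jeffreys-style; keeps the statistic finite and sign-faithful when the
reverse bigram is unobserved) and aggregates counts over all adjacent
pairs by default (`pairs=[(1,2)]` restricts).

## Efficiency model

Features of a k-mer barcode (k=5 canonical): 4k one-hot single-nucleotide
indicators, 16(k−1) dinucleotide indicators, and one structure feature —
the folding stability of the assembled pegRNA (spacer + scaffold + RT
template with the insertion + PBS), min-max rescaled into (0,1) with the
most stable fold near 0. Folding is a Nussinov base-pair-maximisation
dynamic programme (pair weights GC=3, AU=2, GU=1; minimum hairpin loop 3)
returning minus the optimal pair score. This transparent folder was chosen
over a thermodynamic nearest-neighbour model because the regression
consumes only a monotone rescaling of stability and the DP is exactly
testable against exhaustive structure enumeration; `build_feature_matrix`
accepts any external energy function through its `folder` argument. The
shipped pegRNA template is a synthetic stand-in (the slot neighbours
sequence complementary to the spacer, so stable slot–spacer pairing lowers
the structure feature). Regression is lasso with the penalty chosen by
10-fold CV over 50 log-spaced values in `[1e-4, 10]·sd(y)` on a 70/30
train/test split (both split sizes configurable; published descriptions of
the original split disagree with each other, so neither is hard-coded).
Training-set rescaling bounds are stored in the model and reused at
prediction time.

## Downstream statistics

* **Dose–response:** four-parameter logistic on dose (equivalently a
  sigmoid in log-dose), `floor + (ceiling − floor)/(1 + (EC50/d)ⁿ)`, fitted
  by nonlinear least squares with multi-start over 5 EC50 × 4 Hill
  initialisations; dose 0 maps to the floor exactly. Flat responses raise
  `FitError` rather than returning a degenerate fit.
* **Classification:** random forest (300 trees, seeded) under
  leave-one-replicate-out cross-validation — replicates, not random rows,
  are held out, since replicate samples of one programme are correlated.
* **PCA:** centred and unit-variance scaled by default (unscaled optional);
  constant columns dropped with a warning.
* **Differential recorders:** per-symbol log2 ratio of mean edited-read
  proportions with a Welch t-test on per-replicate log2 proportions (≥3
  replicates; pooled normal approximation at 2), BH-corrected; calls
  require adjusted p below α and |LFC| above the threshold. This is a
  deliberate, simple replicate-level analogue of a negative-binomial Wald
  analysis — count-level dispersion modelling is out of scope, and calls
  on real overdispersed data would be anti-conservative at small replicate
  numbers.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analyses rely on:
Hill-coupled write rates with non-accumulating background, key-gated
ordered writing, multi-copy tapes, plasmid-abundance and sequence-bias
weighting, and substitution-error sequencing. It omits PCR amplification
bias and chimeras, indels, cell division and lineage structure, recorder
silencing, and inter-tape phasing within cells. Passing tests therefore
demonstrate correctness of the decoding and inference machinery under the
stated generative model — not performance on real sequencing data, where
flank-walk discard rates, overdispersion and efficiency drift would all be
less benign. Quantities that depend on the original study's sequencing
data (exact correlations, classifier accuracy, fitted weights) are treated
as property targets (sign, recovery within tolerance, above-chance
behaviour), not as numbers to reproduce.

## Problem sizes

Default test and example runs use 150–2,000 cells × 20 tape copies and
1,500–10,000 reads/sample; the order-recovery experiment at its full scale
(12 programmes × 3 seeds × 2,000 cells × 20 tapes) completes in a few
seconds, and the entire test suite in about a minute on one CPU.
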