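# Methods

This note documents the models, conventions and numerical choices behind
`phdsq`, in the order data flows through the toolkit.

## Probe panel design

A probe pair targets a contiguous 54-nt transcript window split at the
*ligation junction* `j` (0-based, half-open coordinates throughout; `j` is
the first base of the right arm). Candidate junctions are enumerated
exhaustively — every `j` whose two 27-nt flanks fit inside the transcript —
and filtered/ranked under four rules:

1. **Arm length 27 nt** (fixed; the unit of probe-reference mapping).
2. **Per-arm GC fraction in [0.40, 0.60]**, a hard filter. The band is
   applied per arm rather than to the 54-mer because each arm hybridizes
   independently and must sit in the same melting-temperature regime.
3. **Exon-spanning preferred, not required**: a junction whose 54-nt window
   contains an exon–exon boundary cannot template ligation on genomic DNA.
   Treating this as a ranked preference keeps single-exon genes designable.
4. **No SNP at the junction** (`j ∈ snp_positions` is excluded): a mismatch
   at the nick blocks ligation allele-specifically.
5. **Homology screen**: the candidate 54-mer must not share ≥ 1 exact
   27-mer (both `k` and the count threshold configurable) with any
   transcript of another gene. This is an exact k-mer screen against a
   user-supplied background, not a genome-wide alignment — adequate for
   panel-scale backgrounds and exactly reproducible.

Ranking is deterministic: exon-spanning candidates first, then the maximum
of the two arms' |GC − 0.5| ascending, then their mean, then the leftmost
junction. ("Closest-to-50%-GC" is ambiguous with two arms; bounding the
worse arm first, then the average, is the reading implemented.) When a gene
gets multiple pairs, junctions must be distinct. Genes with no passing
candidate are reported in a failure list, never raised. The designer is a
pure function of its inputs; a dedicated test checks equivalence with a
brute-force enumeration oracle on small transcripts.

## Library layout

The amplicon is described as an ordered list of named elements (constants,
well barcode, plate barcode, two UMIs, two arms) plus the element order on
each mate — data, not code, serialized as YAML. The shipped default is

```
P5(29) · well_bc(7) · read1_primer(39) · UMI(4) · left_arm(27) ·
right_arm(27) · UMI(4) · read2_primer(41) · plate_bc(6) · P7(24) = 208 nt
```

Read 1 carries well barcode + left UMI + left arm; read 2 carries plate
barcode + right UMI + the reverse-complemented right arm. The P5/P7 graft
sequences are the standard Illumina ones; the two primer-site constants are
this package's own fixed choices, pinned so the total equals the 208-bp
band this library design produces on gels. Any dialect change (barcode
lengths, UMI placement, which mate carries what) is a YAML edit.

## Read simulator

The simulator is the toolkit's ground-truth instrument, not a sequencing
noise model. Per well: `reads_per_well / pcr_duplication` molecules are
drawn **multinomially** over probes proportional to the well's expected
abundances; each molecule receives two independent uniform 4-nt UMIs
(stored as one 8-mer identifier; collisions are allowed to occur naturally
and are recorded in the ground truth); each molecule is emitted as exactly
`pcr_duplication` reads when that is an integer, else `1 + Poisson(d−1)`.
Substitution errors hit every written base independently at the configured
rate; indels are out of scope because ligation probes are fixed-length.
Base qualities are a constant Q30. A mandatory seed makes every run
byte-identical.

**Expression model.** Control states are per-gene expected abundances:
fibrosis genes high in KF/low in AD (fold change = `dynamic_range`),
adipocyte genes the reverse, housekeeping genes equal; base abundances are
log-uniform over `base_range`. A compound of effect size `e ∈ [0,1]` is the
linear interpolation `KF + e·(AD − KF)` per gene, times mean-one lognormal
noise of coefficient of variation `noise_cv` (default 0.1, a typical
well-to-well biological CV). Both probes of a redundant gene share the
gene's abundance, as both sample the same transcript pool.

**Defaults** (`dynamic_range = 10`, `base_range = (250, 2000)` arbitrary
units) emulate a *balanced* probe pool: ten-fold signature-gene separation
between the control states, with the abundance span capped so every panel
gene keeps a quantifiable expected count (≳10 molecules/well) at the
platform's working depth of 10⁴ reads per well in both states. That is the
design premise of a targeted panel — probe input is tuned precisely so that
low-abundance markers stay countable.

**What the simulator does not model** — and hence what passing tests do not
show about real data: GC/polymerase amplification bias, ligation-efficiency
differences between probes, cross-hybridization, RNA degradation, quality
score structure, index hopping, and cell-number variation between wells.
Recovery statistics on simulated screens are therefore upper bounds on
real-data performance; the QC battery exists to measure the same quantities
on real runs.

## Demultiplexing and counting

Single streaming pass over the read pairs; memory scales with
panel × samples × distinct UMIs. Per read pair, variable elements are
sliced out by the layout, then:

- **Barcodes**: exact dictionary hit, else unique best within 1 mismatch
  (configurable); ties or ≥ 2 mismatches → unassigned. Barcode sets are
  generated at pairwise Hamming distance ≥ 3, so one error is always
  correctable and two never silently cross-assign.
- **Probes**: exact (left, right) arm lookup, else unique best pair with
  per-arm Hamming distance ≤ 2 (configurable), minimizing total distance;
  ties → unassigned. Indel-tolerant matching is a non-goal (fixed-length
  chemistry).
- **UMI collapse**: default counts distinct 8-mers per (sample, probe).
  Optional *directional* collapse merges a Hamming-1 neighbour `b` into `a`
  when `count(a) ≥ 2·count(b) − 1` (the standard network rule), absorbing
  phantom UMIs minted by sequencing errors; `none` counts raw reads for
  analyses that want mapping-only totals.

Counting is probe-level first; gene aggregation (summing redundant pairs)
is a separate step so probe–probe concordance QC stays possible. Reads are
conserved: assigned + per-reason failures (barcode / probe / layout) equals
input, per plate.

## Normalization and QC

CPM scales each sample to 10⁶ total counts (all-zero columns are left at
zero with a warning). Correlation, replicate fits, clustering and PCA
default to log2(CPM + 1) — count data spanning decades needs the variance
stabilization, and the replicate-fit intercepts near zero on log-scale data
match how such fits are usually reported — with a flag to disable.
Clustering uses 1 − Pearson distance with average linkage; PCA fixes signs
so the largest-|loading| gene of each component is positive, making results
bit-reproducible.

Redundant-probe concordance is reported two ways: per-gene R² across
samples (meaningful only for genes that vary across samples — a flat
housekeeping gene gives both probes nothing but sampling noise, so its
per-gene R² is near zero *by construction*), and a pooled probe-1 vs
probe-2 fit over all two-probe genes and samples, which spans the panel's
abundance range and is the panel-wide summary comparable to how such
concordance is usually displayed.

## Signature Index

`R_ij = (G_ij − G_iKF)/(G_iAD − G_iKF)`, `W_i = |log2(G_iAD/G_iKF)|`,
`SI_j = Σ_i R_ij·W_i`, then division by the screen maximum. Conventions
where the formulas are silent:

- `G_iKF`/`G_iAD` are arithmetic means of control-replicate CPM (median
  available as a toggle); SI is computed on gene-level CPM.
- Genes with `G_iAD = G_iKF` are excluded (`W_i = 0`, `R_ij` undefined):
  the axis is singular there and carries no directional signal; excluded
  genes contribute exactly zero.
- A single zero control mean falls back to a pseudocount of 1 inside the
  weight only; the `R_ij` denominator always uses raw means.
- After normalization, negative SIs are clipped to 0 (division by the
  maximum cannot bound negatives); clipping is flagged in the result.

Because SI is linear in the profile, a noise-free interpolated compound at
effect size `e` has raw SI exactly `e·ΣW_i`, and normalized SI `e` whenever
an AD-state sample is the screen maximum — the basis of the parameter-
recovery tests. Z′ uses sample standard deviations (ddof = 1) over control
SIs; verdict bands: ≥ 0.5 excellent, (0, 0.5) acceptable, ≤ 0 poor;
identical means report −∞/fail.

Hits are compounds whose normalized SI reaches the AD controls' mean; a
configurable margin (default 0.05) flags near-hits. Ties break by sample id
for determinism.

## Problem sizes and degenerate inputs

The test suite exercises small simulations (4–20 wells, 0.3–2 k reads/well)
for logic tests and full-scale runs (96 wells × 10⁴ reads/well) for the
distributional checks: round-trip exactness, effect-size recovery
(r ≥ 0.95 with ample margin across seeds), replicate fits and probe
concordance; these complete in seconds to ~15 s each on one CPU. Degenerate
inputs follow the contracts above: transcripts < 54 nt raise a no-candidate
error, zero-abundance profiles and non-positive screen maxima raise, empty
homology backgrounds warn and pass, single-sample clustering returns a
trivial tree, and a controls-only screen still yields a Z′ report with an
empty hit table.

## Known limitations

- The homology screen is exact-k-mer only; it will not catch mismatched
  near-homologs a BLAST-style search would.
- UMI directional collapse is quadratic per (sample, probe) UMI family —
  fine at targeted-panel depths, not meant for shotgun-scale families.
- The SI is a single-axis statistic: compounds that move expression off the
  KF→AD line (toward some third state) score low even if biologically
  interesting; composite multi-signature scoring is out of scope.
- Simulated FASTQ quality strings are constant; quality-aware consensus
  calling is deliberately unsupported.
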