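# Methods

This note documents the models behind each module, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices that matter.

## Bioenergetics (`sipsyn.thermo`)

Reactions are stoichiometric maps over a species table carrying elemental
composition, charge, phase and standard Gibbs formation energies at the
biochemical standard state (pH 7, 298.15 K, 1 M / 1 bar — the Thauer
convention, under which the proton's formation energy is
RT·ln 10⁻⁷ = −39.95 kJ/mol). `balance_check` enforces exact element and
charge conservation before any energy is computed.

In-situ free energy is ΔG = ΔG°′ + RT·ln Q with R = 8.31446×10⁻³
kJ·mol⁻¹·K⁻¹. Aqueous activities are molar concentrations over 1 M; gases
are partial pressures over 1 bar (so 1 Pa = 10⁻⁵); liquid water is excluded
from Q; pH deviations from 7 enter as ν(H⁺)·RT·ln 10·(7 − pH). The default
temperature is 298.15 K: the canonical −21 kJ/mol figure for syntrophic
butyrate oxidation arises at 25 °C (at the 35 °C incubation temperature the
same conditions give −23.7), so energy calculations default to the standard
temperature and the incubation temperature is passed explicitly where it
belongs (gas volumes). Activity coefficients, Gibbs–Helmholtz temperature
corrections and acid–base speciation are deliberately out of scope; all
inputs are activities.

`threshold_activity` inverts ΔG(a) in closed form,
ln a = (ΔG_target − ΔG°′ − RT·ln Q_rest)/(ν·RT); because ΔG is affine in
ln a this is exact, and re-substitution reproduces the target to < 10⁻⁹
kJ/mol (verified against a bisection oracle in the tests).

`partition_energy` divides each guild's exergonic yield by the chain total;
it refuses non-negative yields since a fraction of "energy captured" is
meaningless for an endergonic step. The shipped formation energies are
Thauer-1977-style values, which give +48.2 kJ/mol for butyrate oxidation;
the widely quoted +53 kJ/mol standard value evidently rests on a different
source table, so every calculation that depends on ΔG°′ takes it as an
explicit input rather than deriving it from the table.

COD arithmetic uses complete oxidation C_cH_hO_oN_n + (c + (h−3n)/4 − o/2) O₂
(nitrogen leaving as ammonia), giving 1.82 g COD/g butyric acid and
3.99 g COD/g CH₄; 64 g COD corresponds to 1 mol CH₄, and gas volumes use
22.414 L/mol at 273.15 K scaled ideally to the requested temperature
(25.3 mL CH₄ for the 40 mM / 10 mL microcosm feeding at 35 °C). COD is
conserved through methanization to machine precision (property-tested).

## Synthetic SIP generator (`sipsyn.sip_synth`)

The generator emulates the observable layers of a DNA-SIP experiment:

* **Community** — n populations (default 50) with lognormal(0, 1) relative
  abundances, GC uniform on [0.35, 0.65], genome lengths uniform on 2–6 Mb;
  a chosen subset (default 2, matching a two-degrader outcome; 5 in the
  broader recovery checks) assimilates the labeled substrate to a ¹³C atom
  fraction of 1.0, everyone else stays at natural abundance (1.1 %).
* **Gradient** — DNA mass (∝ abundance × genome length) spreads over
  buoyant density as a Gaussian with σ = 0.003 g/mL around
  ρ = 1.660 + 0.098·GC + 0.036·(atom¹³C excess), binned into 24 fractions
  spanning 1.66–1.78 g/mL. A `carryover` fraction of each population's DNA
  (0.01 in the pipeline defaults, 0 in the raw simulator) smears uniformly
  across the gradient. This models the cross-fraction contamination real
  CsCl gradients always show — it is the reason ¹²C control heavy fractions
  contain DNA from the whole community and can serve as a sequencing
  baseline. Without it, the unlabeled form of a labeled population would
  have structurally zero heavy-window mass and the count model would be
  degenerate.
* **qPCR** — per-fraction target mass times lognormal noise with CV 0.1
  (multiplicative assay noise; mean preserved).
* **Counts** — a population's expected read share is its window mass over
  the window total; counts are negative-binomial around depth × share with a
  shared dispersion (default 0.05), or exactly multinomial in the
  deterministic test mode. Defaults: duplicate microcosms per condition,
  5×10⁵ reads per sample.

The simulator does **not** emulate read-level errors, assembly or binning
artifacts, partial labeling kinetics, genome-content differences between
strains, or gradient physics beyond the Gaussian-plus-smear shape. Passing
tests therefore demonstrate that the inference chain is correct when its
distributional assumptions hold, not that those assumptions hold for any
particular real gradient.

Density scale: on the Schildkraut relation used here, fully labeled DNA of
35–65 % GC organisms bands at ≈ 1.73–1.76 g/mL, so the pipeline's default
sequencing window is 1.73–1.77 g/mL. Published experiments often report
absolute windows (e.g. 1.70–1.705 g/mL) on differently calibrated gradients;
`select_heavy_fractions` keeps that conventional window as its default and
everything is overridable.

## Heavy-fraction selection (`sipsyn.fraction_select`)

Profiles are normalized to their maximum (making selection invariant to
absolute copy numbers), replicates are averaged per condition after linear
interpolation onto a common density grid (gradients align by density, not
fraction index), and fractions are selected where the ¹³C/¹²C ratio is
≥ 2.0 inside the density window. The 2.0 default reflects the ~2.0–2.2×
ratios typical of clearly labeled targets. A zero ¹²C signal yields a +∞
ratio with a warning rather than an error, and an empty selection warns
rather than fails. Besides the fixed window, an argmax mode centers the
window on the maximum finite ratio for exploratory use.

## Enrichment calling (`sipsyn.enrichment`)

A from-first-principles implementation of the size-factor-normalized
negative-binomial Wald test:

* **Size factors** — median-of-ratios against the geometric-mean reference
  over features positive in all samples, rescaled to geometric mean 1; if no
  feature qualifies, a positive-subset fallback is used with a warning.
* **Dispersion** — per-feature method-of-moments on normalized counts with
  the residual variance pooled within conditions, then moderated toward a
  parametric trend α(μ) = a₀ + a₁/μ with weight d₀/(d₀ + df), prior df
  d₀ = 8. With duplicate microcosms each feature has only 2 residual df, so
  the trend dominates — the moderation that makes a Wald test usable at this
  replication level.
* **Wald test** — per-feature NB GLM with log link, design ~condition,
  size factors as offsets, fitted by vectorized IRLS (≤ 100 iterations,
  10⁻⁸ relative deviance tolerance, fitted means floored at 10⁻⁸, a 10⁻¹⁰
  ridge for numerical safety). No pseudocounts are added — the NB handles
  zeros natively. log₂FC = β₁/ln 2; z = β₁/SE(β₁) against the standard
  normal; two-sided p. All-zero features are reported as NA and excluded
  from the BH denominator.
* **Calling** — enriched ⇔ log₂FC > 0 and p below α = 0.05 on the
  BH-adjusted p-value by default (a `--raw-p` switch exists). BH is the
  default because median-of-ratios normalization recenters fold changes on
  the unlabeled majority, leaving ~50 near-null features per run: at raw
  p < 0.05 a couple of false positives per experiment are expected by
  construction, while BH keeps the expected false-discovery rate at α.

Measured behavior (test suite): null type-I error 0.053 at p < 0.05 over 20
seeds; exact recovery of 2 labeled populations among 50 in 19/20 seeds; mean
sensitivity 1.0 and FDR 0.017 with 5 labeled populations; fold changes agree
with DESeq2 (pydeseq2) within 0.3 log₂ units on strongly enriched features.
DESeq2's extras (Cook's distance, LFC shrinkage, independent filtering) are
intentionally omitted — they are not identifiable or not useful at n = 2+2.

## Genome comparison (`sipsyn.genome_compare`)

ANIb-style fragment ANI with a self-contained deterministic aligner:
1020 bp non-overlapping fragments (terminal remainders under half length
discarded, > 20 % N dropped); exact 16-mer anchors on both strands propose
diagonals (k-mers sampled every 4 bp, ≤ 8 positions per k-mer, ≤ 50
diagonals scored) and the best ungapped full-diagonal placement gives
identity = matches/aligned length and coverage = aligned/fragment length.
Fragments must reach ≥ 30 % identity and ≥ 70 % coverage; ANI is the mean
passing-fragment identity averaged over both directions. With i.i.d.
substitution at rate μ the estimator tracks 100·(1 − μ) within ±0.3 points
(tested at μ = 0.5–2 %). Pairs with no alignable fragment get a NaN sentinel,
imputed to 70 % ANI for clustering (the conventional floor of the ANI scale).
Absolute values can differ from BLAST-based ANIb by under a point on close
genomes, which the threshold-based calls tolerate.

Clustering is Ward's minimum-variance linkage on 100 − ANI, with flat cuts
at distance 1 (ANI ≥ 99 %, sequence-discrete populations) and 5 (ANI ≥ 95 %,
species), boundary-inclusive; genomes are processed in id-sorted order so
results are input-order invariant, and the dendrogram is exported as Newick.

## Pipeline (`sipsyn.pipeline_io`)

`run_pipeline` chains community → gradients → qPCR selection → counts →
enrichment → ANI → thermodynamic summary, writing TSV/FASTA/Newick
intermediates and a schema-versioned JSON report. One config seed feeds
named per-stage substreams (community, qPCR, counts, genomes), so stages are
independently reproducible and an identical config yields a byte-identical
report. A stage failure aborts with the stage named. The synthetic ANI stage
demonstrates population delineation by generating, for each labeled
population, its genome plus a 0.5 %-mutated variant (same population) and an
8 %-mutated relative (different species).

Problem sizes throughout (50 features × 4 samples, 100 kb genomes, 20-seed
Monte Carlo batches) are chosen so the full suite runs in well under a
minute while keeping the statistical checks sharp.

## Known limitations

* The NB Wald test at n = 2+2 leans on the dispersion trend; features with
  wildly atypical dispersion are moderated toward it.
* The aligner is ungapped; indel-rich divergence depresses coverage rather
  than identity, so ANI for distant pairs (< ~90 %) is driven by which
  fragments still pass filters.
* The generator's labeling is all-or-nothing; partial atom enrichment is
  representable (any atom fraction in [0.011, 1]) but the pipeline defaults
  do not exercise it.
* Thermodynamics treats all ΔG°′ inputs as authoritative; no internal
  consistency check between a quoted ΔG°′ and the species table is enforced
  when the explicit-input path is used.
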