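# Methods

## Data model

A corpus is a set of small datasets of two kinds. *Profile* datasets record
qualitative Class-1 phosphosite detections (localization probability,
A-score). *Differential* datasets compare a test condition against a control
and report, per site, a linear fold change and a p-value. Site identity is
(UniProt-style accession, residue ∈ {S, T, Y}, 1-based position on the
canonical sequence); gene symbols are display metadata only and never enter
joins except in the biomarker overlay, where gene-level sets are the native
currency. Tables are TSV with a mandatory header, UTF-8, and `.`/empty for
missing values. Within a dataset, duplicate rows for one site are collapsed
to the smallest-p row; if duplicates classify to opposite directions the
site is dropped from that dataset entirely (conservative — the data give no
basis for choosing).

## Direction calls

An observation is Class-1 when localization probability ≥ 0.75 **or**
A-score ≥ 13, a missing metric failing its own clause. (Published
descriptions of this filter alternate between "or" and "and"; "or" is the
usual Class-1 convention and is the default, with `class1_mode="and"`
available.) A Class-1 observation with p < 0.05 is called *increased* when
fold change ≥ 1.3 and *decreased* when ≤ 0.76; everything else — including
significant changes inside the (0.76, 1.3) band — is *not callable* and
contributes to nothing downstream. All bounds are inclusive where stated
(1.3 and 0.76 are calls; p = 0.05 is not significant). Fold changes are
linear test/control ratios throughout; no log transform is applied.
Note the default down-bound 0.76 is slightly asymmetric to the up-bound
(1/1.3 ≈ 0.769); a symmetric configuration is one constructor argument away.

## Predominance

Each site of the query protein gets two counts: distinct profile datasets
with a Class-1 detection, and distinct differential datasets with a Class-1
report (a companion column counts datasets with an actual direction call —
the two notions differ and both are emitted). Counts are converted to dense
1-based ranks (ties share a rank) and combined as their product; the
smallest rank product is the predominant site, ties broken by larger
differential count, then position. The principle being operationalized is
"frequent in both corpora"; rank product was chosen over rank sums or count
products because it is scale-free across corpora of very different sizes and
insensitive to the long tail of singleton sites. Note that the selection is
meaningful only in the context of the full site list: excerpting the top
few sites can reverse the outcome, because dense ranks compress.

## Co-modulation statistics

For an anchor site *t* and a partner site *o* on another protein, every
differential dataset where both carry a call contributes one count to the
2×2 table (rows: anchor I/D; columns: partner I/D). The concordant one-sided
exact test is the upper hypergeometric tail of the (I,I) cell given the
margins (Fisher's exact test, alternative "greater"); the discordant test is
the opposite tail, computed as the upper tail of the (I,D) cell — the same
quantity, but summing small terms upward keeps very small p-values accurate
and makes the partner-label-flip symmetry bit-exact. Any zero margin returns
p = 1. Because the two tails of one table satisfy p⁺ + p⁻ ≥ 1, at most one
can fall below any α ≤ 0.5; the implementation asserts this.

The co-modulation ratio is r⁺ = (n_ItIo + n_DtDo)/(n_ItDo + n_DtIo), with
r⁻ its reciprocal. Zero denominators are kept semantically distinct: a ratio
with nonzero numerator is +∞ (all-concordant; passes any finite cutoff,
serialized as `Inf`), an all-zero table is undefined (NaN, serialized as an
empty cell; never high-confidence).

A partner is high-confidence when (1) its one-sided p < α (default 0.05, raw
— Benjamini–Hochberg q-values are emitted per tail family as an auxiliary
column but do not participate in classification), (2) the sign-matched ratio
*strictly exceeds* `cutoff_fraction` (default 0.10) times the number of
datasets in which the anchor carries a call, and (3) its co-callable
datasets span ≥ 3 distinct studies and ≥ 3 distinct normalized experimental
conditions (trim + case-fold; guards against multi-time-point and
replicated-condition over-representation). The cutoff rule compares a
dimensionless ratio against a fraction of a dataset count; this is
units-heterodox but is the field's stated rule and is implemented literally
— an anchor called in 72 datasets yields the cutoff 7.2.

**A consequence worth knowing.** For a partner co-callable in *n* ≤ 72
datasets with per-dataset concordance 0.9, the discordant count is
Binomial(n, 0.1) and P(r⁺ > 7.2) = P(d < n/8.2) ≤ ~0.78 for every n ≤ 72
(it would take n ≳ 300 to reach 0.9). The literal ratio rule therefore caps
single-partner sensitivity at concordance 0.9 around 0.7–0.8 regardless of
co-observation rates — exactly what the fixture recovery run measures
(sensitivity ≈ 0.74, precision ≈ 1.0). The rule is strict rather than
sensitive; partners it passes are very reliably real.

### Symmetries

Concordance is symmetric in the two pair members: inverting *either*
member's calls exchanges the concordant and discordant cells and swaps
p⁺ ↔ p⁻ and positive ↔ negative exactly (partner flip: bit-exact by
construction; anchor flip: exact to hypergeometric identity). Inverting both
members rotates the table 180° and leaves p-values, ratios and
classifications invariant. The acceptance suite tests all three.

## Annotation overlays

All overlays are pure filters/joins over the high-confidence rows — they
never alter a statistic. Binary interactors match by unordered accession
pair with the anchor protein, tagging every high-confidence site of an
interactor (coordinated multi-site modulation stays visible). Upstream
regulators require a kinase→substrate record targeting the anchor's exact
residue and position (kinase-of-the-protein alone does not qualify);
downstream substrates require the partner's own site to be a recorded
substrate of the anchor kinase. Enzyme partitioning maps accessions to
kinase/phosphatase and attaches per-site activity effects
(induces/inhibits/both/unknown). Biomarker overlap intersects case-folded
gene symbols per disease, retaining the specific phosphosites. The shipped
annotation tables are synthetic, hand-curated stand-ins assembled for the
fixture corpus; live database retrieval is deliberately out of scope for
reproducibility.

## Synthetic corpus generator

The generator draws directions first and samples measurement values
conditionally on them, so every emitted row classifies back to its planted
direction under the default thresholds — tests target the analysis, not
threshold jitter. Defaults (the documented study conditions): 90
differential datasets over 5 studies × 6 condition codes (round-robin), the
anchor callable in exactly 72 of them (0.8 × 90, an exact count) with
direction Bernoulli(0.5); 50 positive partners at concordance 0.9 and 10
negative at 0.1, each co-observed with probability 0.7 per dataset (a
realistic rate for frequently detected sites); 500 background sites observed
with probability 0.3, directions independent, 20% of observations
deliberately not callable; 40 profile datasets populate the profiling
counts, with anchor-protein sibling sites at staggered profile/differential
frequencies so predominance ranking has structure to find. Callable fold
changes are threshold × exp(Exponential(0.4)) on the appropriate side,
p-values uniform below 0.049, localization probabilities uniform on
[0.75, 1], A-scores missing 30% of the time. A truth record (per-dataset
directions, expected pair tallies, planted signs) is emitted alongside and
is exactly recomputable from the files.

What the generator does *not* emulate: raw spectra, peptide-level evidence,
batch effects, inter-site correlation beyond the planted anchor coupling, or
realistic intensity distributions. Passing recovery tests therefore shows
the statistics behave as designed under the assumed sampling model, not that
the pipeline is robust to real-data pathologies (normalization drift,
shared-peptide ambiguity, study heterogeneity).

A separate, fully deterministic 12-dataset demonstration corpus (perfectly
concordant/discordant named partners, 7 anchor-up/5 anchor-down) backs the
annotation-overlay examples, where stochastic planting cannot guarantee that
specific named sites clear the strict ratio rule.

## Numerical and design notes

- Exact tests go through `scipy.stats.hypergeom` survival functions; the
  test suite checks them against exhaustive enumeration in rational
  arithmetic for all tables with margins ≤ 12 (|Δp| < 1e-10) and against
  `scipy.stats.fisher_exact`.
- BH q-values via `statsmodels.stats.multitest.multipletests`.
- Analysis problem sizes (90 datasets, ~560 tested partners, 2000 simulated
  null pairs of 30 datasets in the calibration check) keep the full suite
  and drivers comfortably interactive while leaving planted-effect recovery
  statistically meaningful.
- Determinism: one seeded `numpy` generator stream per corpus; identical
  seeds give byte-identical fixture files; the pipeline itself has no
  randomness.
- Ties and degenerate inputs: empty corpora yield empty outputs, not errors;
  an anchor with no callable dataset is an error; a protein with one site
  has an empty co-occurrence matrix.

## Known limitations

- Direction calls trust each study's own statistics; raw intensities are
  never re-tested.
- The anchor's callable-dataset count sets the ratio cutoff; anchors with
  few callable datasets get low cutoffs and correspondingly noisier
  high-confidence sets.
- Redundancy support counts all co-callable datasets, not only
  concordance-supporting ones (the stricter alternative is not
  distinguishable from the stated rule and this reading is the more
  conservative filter-passer).
- Site positions are canonical-isoform coordinates; no isoform or proteoform
  arithmetic is attempted.
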