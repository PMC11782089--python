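# Methods

This note documents the models, numerical choices and limitations behind
each analysis arm, and what the synthetic-data generators do and do not
emulate.

## Melting-curve analysis (`meltcurve`)

**Model.** Fraction non-denatured at temperature T (°C) follows the
three-parameter sigmoid f(T) = (1 − p)/(1 + exp(b − a/T)) + p with plateau
p ∈ [0, 1), slope parameter b (unitless) and a (°C-scaled). When p < ½ the
melting point has the closed form Tm = a/(b − ln(½/(½ − p))); Tm is
reported only inside [min(T) − 10, max(T) + 10] °C — beyond that the
crossing is an extrapolation artifact and is treated as undefined.

**Preprocessing.** Per temperature, sample columns are rescaled so totals
(computed over proteins quantified in all samples at that temperature, so
missingness cannot bias them) equal their across-sample mean. Proteins need
PSM evidence ≥ 2 in both conditions (inclusive). Each
protein/condition/replicate series is divided by its lowest-temperature
value; series with missing or non-positive reference are excluded and
logged.

**Fitting.** Bounded trust-region least squares (a ∈ [1e−3, 1e5],
b ∈ [1e−3, 500], p ∈ [0, 1)) from multiple starts: a data-driven guess
(plateau from the curve tail, Tm near the 0.5 crossing) plus a fixed
4-point parameter grid; the lowest-RSS solution wins. Fits that fail every
start produce a fit-failure record and the protein is excluded from testing
but counted.

**Shift test.** Null: one sigmoid on all points pooled (3 parameters);
alternative: one per condition (6), each seeded with the null solution so
RSS_alt ≤ RSS_null by construction. F = ((RSS₀ − RSS₁)/d₁)/(RSS₁/d₂).
Degenerate cases — an essentially perfect shared fit (RSS₀ ≤ 1e−12·n) or a
relative RSS improvement below 1e−6, i.e. within optimizer noise — are
assigned F = 0, p = 1: duplicated condition data must not look like a
shift.

Two degrees-of-freedom modes are available. *Theoretical* (default):
d₁ = 3, d₂ = n − 6. *Empirical*: effective (d₁′, d₂′) fitted by maximum
likelihood so that the scale-free statistics (RSS₀ − RSS₁)/RSS₁ follow
(d₁′/d₂′)·F(d₁′, d₂′) across proteins, with the top 10% trimmed and the
likelihood truncated accordingly so genuine shifts do not distort the null
fit. The theoretical mode is mildly anticonservative under multiplicative
(hence heteroscedastic) noise — on all-null simulations about 10% of p
values fall below 0.05 — while the empirical mode restores uniformity
(Kolmogorov–Smirnov p ≈ 0.6–0.9 on 300–400 null proteins). Calibration
claims in the test suite therefore use the empirical mode; hit calling on
strong spikes is insensitive to the choice.

**Hit calling.** Benjamini–Hochberg across tested proteins; hits need
adjusted p < 0.01 AND |ΔTm| strictly > 1 °C. Proteins with undefined ΔTm
in either condition cannot be hits. Direction is labeled by the sign of
ΔTm (positive = stabilized).

**Targeted melts (CETSA).** Technical replicates are averaged per
temperature, signals normalized to the mean at the lowest temperature, and
the same sigmoid fitted. Because the model's value at the lowest
temperature is slightly below 1 (typically 0.95–1.0), this normalization
rescales the curve marginally; recovered Tm carries a bias of order
0.01–0.1 °C, far below the 1 °C decision threshold.

## Morphological profiling (`morphoprofile`)

z scores use the raw median absolute deviation of the DMSO control wells
(no 1.4826 consistency factor): the profile states how many control MADs a
feature lies from the control median. Features with zero control MAD get
z = 0 and are flagged — this keeps vector lengths fixed without
manufacturing infinities. Induction uses a strict |z| > 3 cutoff.
Biosimilarity is 1 minus the correlation distance, i.e. the Pearson
correlation of the two profiles; it is undefined (explicit error) for
constant profiles. Replicates aggregate by feature-wise median, consistent
with the robust-statistics framing; profiles are computed per plate.
Reference matching flags pairs where either profile's induction is below a
threshold (default 5%), since similarity between inactive profiles carries
no phenotypic information.

## Network permutation test (`permnet`)

The database filter keeps records whose both interactors belong to the
target organism (default 9606) and whose evidence type is in a whitelist of
direct physical assays (affinity capture-western, co-purification, affinity
capture-MS); records collapse to a simple undirected graph (unordered
dedupe, no self-loops). The node universe is the endpoints of the retained
edges. Identifiers match by upper-cased symbol string; unmatched regulated
proteins are reported, not guessed. The regulated set uses strict
thresholds (|log2FC| > 0.25, padj < 0.05).

The permutation null samples k distinct nodes uniformly from the universe
B times (default 10,000) and counts samples whose induced subgraph reaches
the observed statistic (tail ≥ by default; strict > available). Both the
raw count/B estimate (which can be exactly 0, matching how permutation
results are commonly printed) and the add-one (count+1)/(B+1) estimate are
returned. A complete-enumeration exact test (bounded at 10⁶ subsets)
serves as the oracle for small graphs.

## Screen ranking (`screenstat`)

CPM uses the +1 pseudocount so log fold changes are finite. Gene scoring
walks each gene's guides down the list ranked by log2FC (descending for
enrichment screens): the j-th gene guide at overall rank r contributes the
binomial tail P(X ≥ j), X ~ Binomial(m, r/N); only guides inside the top
thr% window (default 10%) contribute, and genes need ≥ 2 guides. Tied fold
changes share their midrank — so fully exchangeable inputs give every gene
the same score — while walk order among ties is fixed by guide label for
determinism. The FDR divides the mean number of null genes (guide→gene
assignment permuted, default B = 1,000; mean aggregation, median
switchable) scoring at or above s by the number of observed genes doing so,
clipped to [0, 1] and made monotone down the ranking by a suffix minimum
(step-up coherence). This is a reconstruction of the published rank-walk
statistic from its description; parity with any specific tool release is
not claimed — validation is by spike recovery and null calibration.

## Enrichment (`rankenrich`)

The metascore makes "the worst of three scores" precise as the minimum of
three oriented percentile scores (|log2FC|, baseMean, 1 − p, each computed
across the table so larger = stronger), signed by the fold-change
direction. Percentiles put the three evidence axes on a common scale; the
minimum keeps a gene's rank only as good as its weakest evidence. The
preranked GSEA running sum increments hits by |score|^w (w = 1) normalized
to the set total and decrements misses by 1/(N − set size); ES is the
extremum. The null samples same-size gene sets from the ranked list
(nperm = 1,000), NES divides ES by the mean magnitude of same-sign null ES
("meandiv"), the nominal p uses the same-sign null pool, and the FDR
compares the observed NES against the pooled null NES across sets.
Set-size bounds default to 5–500 matched genes; if all matched scores are
zero the increments fall back to unweighted. Leading edge: members at or
before the positive extremum (at or after, for negative ES).

## Dose-response (`doseresp`)

Viability is signal over the mean control signal; the control anchor is
selectable (DMSO wells or the lowest drug concentration). The 4PL fit
multi-starts over Hill-slope signs and is reported in canonical orientation
(top ≥ bottom); EC50 is flagged undefined when the fitted span |top −
bottom| is below 1% of the response scale — a flat curve has no midpoint.
Relative AUC integrates viability (clipped at 0) over log10 concentration
via the trapezoid rule, normalized by the constant-1 area on the same grid;
the log abscissa matches the log-spaced dilution design and the relative
form makes the choice of abscissa largely immaterial. The
fluorescence-polarization normalization maps the protein+fluorophore
control to 100% inhibition and the fluorophore-only control to 0% — as the
assay protocol states it — with a switch to the conventional assignment,
because the printed convention is inverted relative to common practice and
the intent is not guessed.

## Synthetic data (`synthetic`)

Generators emulate the statistical structure of each input, not its raw
acquisition (no spectra, reads or images). All are bit-deterministic under
a fixed seed, and every perturbed entity is listed in the truth sidecar.

* **Melting tensors** — vehicle Tm ~ U(45, 55) °C, plateau ~ U(0, 0.2),
  slope b ~ U(1, 1.3)·b_min where b_min is the smallest slope keeping the
  curve ≥ 0.95 at the lowest and ≤ plateau + 0.05 at the highest gradient
  temperature (solved per protein in closed form), so every curve is
  informative across the default 37.3–62.3 °C eight-point gradient.
  Stabilized proteins shift Tm by +ΔTm with unchanged slope and plateau.
  Multiplicative log-normal noise (default CV 0.05 — a choice, not a
  measured value) applies to all non-reference temperatures; the reference
  measurement is generated exactly, so scaled fold-change curves carry
  independent noise of the stated CV. This idealizes away shared
  reference-scaling error; on real data, where dividing by a noisy
  reference correlates all points of a series, the theoretical-df F test
  becomes substantially anticonservative and the empirical-df mode should
  be used.
* **Feature tables** — a per-feature Gaussian baseline; compound wells are
  displaced along one of a few random unit phenotype axes scaled by the
  effect size, giving same-axis wells near-unit biosimilarity by
  construction. Real feature covariance and plate effects are not modeled.
* **Interaction graphs** — Erdős–Rényi or Chung–Lu (power-law expected
  degrees) wiring, annotated so records pass the default organism/evidence
  filter. Real interactome degree structure and study bias are not
  reproduced.
* **Guide counts** — log-normal library skew, gamma-Poisson (negative
  binomial) counts with Var = m + α·m² (default α = 0.05, coverage 500
  reads/guide); resistance genes multiply their active guides' (default
  3 of 4) expected counts by 2^effect before resampling.
* **Dose plates** — exact 4PL times multiplicative noise on the standard
  eight-point half-log dilution (10 → 0.003 μM) plus DMSO wells.
* **Differential tables** — regulated entities receive |log2FC| > 0.25 and
  padj < 0.05 by construction; baseMean is log-normal and loosely coupled
  to effect size so the metascore's evidence axes are not independent.

Because the generators satisfy each method's model assumptions by
construction (independent noise, exchangeable nulls, exact sigmoids),
passing recovery and calibration tests demonstrates correctness of the
statistics and code — not robustness to real-data pathologies such as
batch effects, correlated features, missingness patterns or identifier
mismatch.

## Problem sizes

Simulation-based checks use 1,000 proteins (8 temperatures × 2 conditions
× 2 replicates) with 20 spiked +3 °C shifts for recovery, 300–400 proteins
for null calibration, 1,000 genes × 4 guides for screen recovery, 10,000
network permutations (50,000 when validating against exact enumeration on
≤ 12-node graphs), and 1,000 enrichment permutations — sizes chosen to
match the designs the pipeline targets while keeping a full run in minutes
on one CPU.
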