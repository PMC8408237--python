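# Methods

This note documents the models, estimators and numerical choices behind
`berrysync`, in the order data flow through the pipeline.

## 1. Growth model and the synthetic cohort

Berry development follows a double-sigmoid: a green-phase sigmoid (cell
division/expansion driven by organic-acid accumulation) and a ripening
sigmoid that begins at softening. Observation starts at softening, so the
generator treats the first sigmoid as completed: relative volume is 1
before softening and

v(t) = 1 + (g − 1) · s(u),  u = (t − t₀)/T,

where `s` is a logistic (steepness k = 8) normalised so that `s = 0` at
softening and `s = 1` at net-influx arrest. Arrest is modelled as a hard
stop at 85% of the logistic course (`arrest_fraction`): growth and phloem
switch-off are a fast transition, so the berry is still growing at finite
speed when import stops, and the peak volume equals exactly
`g × softening volume`. After the peak, volume declines by evaporation at
a per-berry rate `r` (relative/day).

Per-berry parameters and their defaults (the study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| softening date | U(0, 21) d | the 2–3-week asynchrony window |
| ripening duration T | U(12, 40) d | commensurate with the asynchrony; slow and fast berries coexist |
| growth gain g | N(2.0, 0.1) | the berry roughly doubles during ripening |
| softening volume | log-normal, CV 15% | within-genotype size variance (free parameter) |
| shrivel rate r | log-normal, mean 0.2%/d, σ = 0.6 | mild, heterogeneous evaporative loss |
| volume noise | multiplicative, 0.5% | pixel-counted projected areas are precise |
| concentration noise | proportional Gaussian, 3% | HPLC / flame-photometry precision |
| picture cadence | days 0, 3, 7, 10, … | twice-weekly imaging |

Solute kinetics are tied to growth progress `p(t) = s(u)` (1 after the
peak): per-fruit sugar is `Q(t) = C·V_peak·(0.05 + 0.95·p)` with `C` the
genotype plateau (glucose + fructose, equimolar), so sugar import stops
exactly at the growth peak and concentration rises afterwards only
through volume loss. K⁺ follows sugar with a genotype molar flux ratio
(ΔK = ΔQ/ratio, 30 for Syrah, 15 for microvines) over a baseline of half
the final phloem-delivered amount. Malate concentration interpolates
geometrically from its initial to its arrest value (390→39, 480→48,
465→93 mEq/L for Syrah/MV032/MV102, consistent with 60–80% of the malate
being consumed by arrest), then the remaining amount is still oxidised at
1%/day. Tartrate amount declines linearly in `p` to its retention
fraction (0.95/0.95/0.82) and never increases.

**Observation-driven stage sampling.** Berries for the stage design are
selected and dated from the *observed* (median-smoothed) series, exactly
as stages are judged from pictures in practice: P is the observed grid
day of maximum volume, S the first picture day ≥ 14 d later, and G the
fastest berries (observed peak ≥ 18 d after softening, so they are still
growing at the 14-d probe) sampled when the observed profile crosses half
its ripening gain. Because the flat plateau makes the observed maximum
lag the true arrest by up to one picture interval, P berries are
typically sampled just *after* the true arrest — the same "P + 1" effect
a posteriori staging shows on real fruit. The truth table retains the
true softening/arrest days for audit.

What the generator does **not** emulate: xylem backflow, transpiration
dynamics, circadian effects, seed number/berry-size covariation,
heatwave-induced sugar respiration at S (a `respiration` knob exists but
defaults to 0), or read-level sequencing artefacts. Passing tests
therefore demonstrate the *statistical machinery* recovers the planted
structure under realistic noise, not that real vineyards behave this way.

## 2. Staging

Areas → volumes via the sphere-equivalent formula by default (projected
area is the only measured quantity); a prolate-spheroid mode
(`V = π/6·d₁d₂²`) is provided and recorded in output metadata. Profiles
are normalised to the (linearly interpolated) softening volume; no
extrapolation outside the observed range. Peak detection takes the argmax
of the median-of-3-smoothed series, ties to the earliest day; an argmax at
the final observation sets a "peak not yet reached" flag instead of a
date. Stage rules (defaults): P within ±3 d of the peak (the tolerance
reflecting the twice-weekly cadence), S ≥ 14 d past it, V within ±2 d of
softening, G between softening and the P window for berries that gained
≥ 0.4 in relative volume within 14 d of softening ("growing at full
speed" is a property of the berry, not of the sampling date); precedence
P > G. Days-from-peak is always recorded for audit.

**Limitation.** With the fixed 3–4-day cadence and a slow post-peak
decline, the observed peak day cannot be located more precisely than one
picture interval; at volume noise well above ~1% the ±3-d P window and
the 14-d S threshold both become unreliable against the *true* arrest
date. Stage assignment is validated against the observation-driven design
(≥ 90% agreement up to 5% noise); the observed-vs-true peak offset is the
irreducible part.

## 3. Flux accounting and arrest

Amounts are `c × V` (mol/L × mL → mmol; mEq/L × mL/1000 → mEq; malate is
divalent: 2 mEq = 1 mmol) and are normalised per berry to 1 g of pericarp
at arrest (per-berry arrest mass by default; a genotype mean is an
option), making genotypes comparable. Water amount uses the berry volume
itself (1 mL ≈ 1 g).

Stage comparisons: one-way ANOVA plus Tukey HSD (scipy's studentized
range, Tukey–Kramer for unequal n) at α = 0.05, summarised by an
insert-and-absorb compact letter display. Stages with < 2 replicates are
excluded with a warning. In pooled multi-genotype panels, genotype enters
as an additive block (amounts are genotype-centred before the stage
comparison): solute *levels* differ between genotypes even after 1-g
normalisation — sugar arrests near 0.8 mmol/g in microvines vs 1.2 in
Syrah — while the arrest *pattern* is shared, so an unblocked comparison
is underpowered by design.

Arrest rules: the default `one_sided` rule declares a solute arrested
when G separates from both P and S (below them) and S does not
significantly *exceed* P. A significant P→S decrease does not negate
arrest of import — it is evaporation for water and respiration for sugar,
both of which occur in shrivelling fruit. The stricter `shared_letter`
rule (P and S must share a letter) is available for sensitivity analysis.
"Simultaneous" requires water, sugar and K⁺ all arrested at P.

## 4. Energetics

The proton budget counts H⁺ exported to the cytosol by the tonoplast
antiport as `n × sucrose flux` with sucrose flux = hexose flux / 2
(n = `h_per_sucrose`, default 1 — the overall exchange observed in
synchronised fruit; configurable because the stoichiometry in vivo is
uncertain). Both malate fates — oxidation
(2 H⁺ + malate + 3 O₂ → 4 CO₂ + 3 H₂O) and gluconeogenesis
(2 malate + 4 H⁺ → hexose + 2 CO₂) — consume 2 H⁺ per malate, so the
scavenged fraction is `min(2·Δmalate, H_exported)/H_exported`. The
antiport equilibrium uses the electrochemical condition
`[S]cyt/[S]vac = 10^(−n·(pHcyt − pHvac)) · exp(−n·F·Δψ/RT)` with
Δψ = ψ_cyt − ψ_vac (output states the sign convention); at ΔpH = 0 and
Δψ = 0 it reduces to equality.

## 5. Expression statistics (simplified re-implementations)

The time-course and pairwise engines deliberately re-implement the
*decision rules* of the original third-party tools rather than their
internals; all reports carry a "simplified re-implementation" note.

- **CPM/RPKM**: CPM columns sum to 10⁶ pre-filter; RPKM = CPM·10³/length.
  The expression filter keeps genes with RPKM > 1 in at least one
  genotype × stage condition mean.
- **TMM**: edgeR's published recipe — 30% two-sided trim on M, 5% on A,
  delta-method precision weights, reference = sample with upper quartile
  closest to the mean, factors rescaled to geometric mean 1. Verified
  against `edgeR::calcNormFactors` to 10⁻⁵ on a frozen fixture.
- **Time-course gate**: per gene, OLS of log2(CPM+1) on stage (coded
  0/1/2), stage², genotype dummies and genotype × stage interactions
  against a control genotype; global F-test, BH-FDR across genes;
  significant = {FDR < 0.05 and R² ≥ 0.7}. The stage coding treats the
  three stages as equally spaced — stages, not calendar days, are the
  analysis unit. The raw F-test is anti-conservative on low-count genes
  (log-count heteroskedasticity); the R² gate is what controls the
  significant set (null rate ≪ nominal), and the filter removes the worst
  offenders first.
- **Model profiles**: the 24 profiles are the unit-step pairs
  (δ₁, δ₂) ∈ {−2..2}² minus (0,0), as mean-centred 3-vectors
  [0, δ₁, δ₁+δ₂]. Gene stage means are computed per genotype on the log
  scale, mean-centred within genotype (expression level cannot drive the
  clustering) and averaged across genotypes; assignment maximises Pearson
  correlation. Shape merge: A = monotone increasing (δ₁, δ₂ ≥ 0),
  B = monotone decreasing, C = up-peak at P (δ₁ > 0 > δ₂), D = down-peak.
  Zero-variance genes are unassigned.
- **Pairwise DE (S vs G)**: normalised counts on TMM effective library
  sizes; per-gene method-of-moments NB dispersion shrunk toward a fitted
  `a + b/mean` trend (prior df 10 against 4 residual df at n = 3); Wald
  test on the log fold change with
  `SE² = Σ_groups (1/n)(1/μ + α)`; BH-FDR at 0.05; pseudocount 0.5 on the
  normalised scale stabilises low counts.
- **Concordance**: genes significant in every genotype list with one
  direction are common (up/down); with mixed directions, discordant.
- **Overview**: PCA on gene-centred log2(CPM+1) (top 500 variance genes);
  correlation-distance, average-linkage sample dendrogram.

## 6. Ranking

`difference = CPM_S − CPM_G` on TMM-normalised stage-mean CPMs;
`variation = round(100·difference/CPM_G)` with half rounded away from
zero (reproduces the printed −99 for −98.99). Ranking sorts the union of
the time-course and pairwise DEG lists by descending |difference|, ties
broken lexicographically by gene id, so ranks are a permutation
independent of input order; both directions are ranked in one merged
list. The bundled 35-gene reference table is reproduced by these rules:
integer variation exactly for the eight golden genes and within ±1
elsewhere (the published integers were computed from unrounded stage
means), differences within ±1 CPM, rank order concordant.

## 7. Promoter CREs

TSS per gene from two annotations by the longest-transcript rule (the
more upstream candidate on the gene's strand wins; one annotation
frequently loses the 5′UTR). Promoters are the 1500 nt upstream of and
excluding the TSS, stored 5′→3′ in gene sense (last base adjacent to the
TSS), clipped at contig edges with a flag; GFF3 is 1-based inclusive,
internal arithmetic 0-based half-open. Motifs are IUPAC consensus strings
matched exactly (degeneracy as character classes), all overlapping
matches on both strands; a hit's offset is the distance of its
TSS-proximal end from the TSS.

The positional Z-score is a reconstruction (the original formula is not
public): for k hits at offsets dᵢ, the statistic is the summed linear
proximity weight `S = Σ (P − dᵢ)/P`, standardised by the exact
finite-population moments of the weight over the P − L + 1 valid offsets
under independent uniform placement. It responds to motif length (valid
offset count), frequency (k) and position, is analytically calibrated
(null mean 0, sd 1, verified by simulation), and sums — rather than
maximises — over multiple hits so promoters with repeated proximal sites
score higher. No hit is an explicit *absent* state, distinct from z = 0;
absence is imputed to 0 only inside clustering distances (Euclidean, Ward
on both axes). Cross-set stability is summarised by the correlation of
cophenetic distances and the adjusted Rand index of flat clusters at
fixed k. Exact matching (not PWM log-odds) is intentional and matches the
scanning regime the analysis was designed for.

## 8. Orchestration and reproducibility

A single `PipelineConfig` carries every threshold (α = FDR = 0.05,
RPKM > 1, R² ≥ 0.7, 1.5-kb promoters) and the seed; it round-trips
through JSON. `run_pipeline` writes TSV/JSON/FASTA/GFF3/Newick outputs
plus a manifest with seeds, thresholds, package versions and SHA-256
checksums of every output; identical configurations produce byte-identical
bundles. All randomness flows through `numpy.random.default_rng` seeded
from the config.

Problem sizes in the default pipeline and test suite — 12 berries per
genotype cohort, 200-berry artefact cohorts, 1000–4000-gene count
matrices, 10⁴ Z-score null draws — were chosen so each module's
statistical claims are testable with comfortable margins while the full
suite runs in well under a minute.

## Known limitations

- The P stage is intrinsically "P + 1": the observed growth maximum lags
  the true arrest by up to one picture interval.
- The NB Wald test with method-of-moments dispersion at n = 3 is only
  approximately calibrated (raw p-values within ~2× nominal); the BH step
  and effect-size ranking downstream are robust to this.
- The time-course F-test assumes homoskedastic Gaussian residuals on the
  log scale; the R² ≥ 0.7 gate, not the p-value, is the effective
  selector.
- The positional Z-score treats hits as independent; overlapping
  self-similar motifs violate this mildly.
- Dataset-scale DEG counts from the original field experiment require the
  raw sequencing data and are outside what the synthetic cohort can or
  should reproduce; the test suite validates the machinery on planted
  truth instead.
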