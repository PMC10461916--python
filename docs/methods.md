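# Methods

## The velocity-to-growth model

The DHFR/TYMS pair is reduced to a two-enzyme cycle on a conserved folate
pool of size `fol_tot` (µM): DHFR produces THF from DHF with
Michaelis–Menten kinetics, TYMS consumes it,

    d[THF]/dt = [DHFR]·kcat_DH / (1 + Km_DH/(fol_tot − [THF]))
              − [TYMS]·kcat_TS / (1 + Km_TS/[THF]).

The steady state depends only on the reduced inputs
V1 = [DHFR]·kcat_DH, V2 = [TYMS]·kcat_TS, K̂m1 = Km_DH/fol_tot,
K̂m2 = Km_TS/fol_tot, and has the Goldbeter–Koshland closed form — the
stable root of the quadratic

    (r−1)·x² + (1 + K̂m1 + r·K̂m2 − r)·x − r·K̂m2 = 0,   r = V1/V2,

for the THF fraction x = [THF]ss/fol_tot. We evaluate it as
`x = 2q / (b + sqrt(b² + 4(r−1)q))` with `q = r·K̂m2` and
`b = 1 + K̂m1 + r·K̂m2 − r`. This form is algebraically identical to the
usual quotient but is continuous through r = 1 (where the quadratic
degenerates to a linear equation, x = K̂m2/(K̂m1+K̂m2)) and numerically
stable for extreme velocity ratios, so no branch on |r − 1| is needed.
The returned fraction is clipped to (1e−12, 1−1e−12) to protect the
downstream logarithmic/Hill evaluation. Agreement with direct ODE
integration is ~1e−14 relative (the test suite asserts 1e−6 over random
parameter sets).

Growth follows a Hill law of the measured THF readout,
g = g_min + (g_max − g_min)/(1 + (K/THF)^n), with the conventions
g(0) = g_min and monotone saturation at g_max. The model's [THF]ss is in
µM while the growth law is fit in readout units; a single scale factor
`thf_scale` bridges the two and is absorbed into fitting (the conversion
is not otherwise identifiable). Because `thf_scale`, `fol_tot` and the
concentration parameters share a scale degeneracy on metabolomics-only
data, the steady-state fit recovers concentrations up to that common
factor; concentration *ratios* and `fol_tot` are the meaningful outputs,
and the round-trip tests assert exactly that.

## Fitting

All positive scale parameters are optimized in log10 space (conditioning
and positivity for free); `g_min` alone is fit linearly with a lower
bound of 0 and `g_max` is parameterized as `g_min + Δ`, Δ > 0, so the
bound g_max ≥ g_min holds by construction. The optimizer is bounded
trust-region least squares with a seeded multi-start (default 10
restarts, ±0.5 decade Gaussian perturbations of the start). Uncertainty
is resampling-based, as in the source experiments: leave-one-out
jackknife (exactly N refits, failures recorded per index), observation
bootstrap (default B = 1000; SDs use ddof = 0 so B = 1 yields zero
spread), and a shuffle control that permutes (kcat, Km) pairs jointly
among the variants of one or both enzymes (default 50 shuffles), refits
all free parameters and reports the R² distribution next to the true-data
R². Near-inactive variants are represented by sentinel kinetics
(kcat = 1e−4 s⁻¹, Km = 1e4 µM), never by zeros.

## Counts → growth rates

Reads are consumed post-demultiplexing; a merged amplicon read must be
full-length with every base call at phred ≥ 20. Calls are codon-wise
against the wild-type reference: an exact or synonymous match is WT (the
amino acid is the unit of analysis), exactly one mutated codon inside the
sublibrary window is that mutant, anything else is rejected. Windows are
1-based codon ranges tiling the gene (default 1–40/41–80/81–120/121–159).
The WT-hopping correction subtracts, per sample,
`N_WT · Σ_codons (e/3)^H (1−e)^(3−H)` over the codons of the target
amino acid (H = codon Hamming distance to the WT codon) and floors at
zero; it is a declared stand-in for the published correction, validated
on synthetic reads.

Counts below 10 are zeroed. A mutant's trace is
f(t) = log2(N_t^mut/N_t^WT) − log2(N_0^mut/N_0^WT), with zeroed points
excluded (never imputed); a mutant absent at any of the first three
timepoints ({0, 4, 8} h) is Null, and any Null replicate nulls the
aggregated record. The slope comes from linear regression weighted by the
mutant's own counts (down-weighting poorly sampled late points); relative
growth is 1 + slope/bulk, where bulk is the vial's turbidostat growth
rate in doublings/hour — so WT maps to exactly 1 and a non-dividing
lineage to 0. Replicates aggregate to mean ± SEM.

## Epistasis

ε = rate(DHFRmut, TYMSmut) − rate(DHFRmut, TYMS-WT), defined only where
both backgrounds yield non-Null rates (the TYMS variants alone are
neutral under thymidine supplementation, which is what licenses the
additive form). Significance: two-sided Welch test across replicate
rates (zero-variance/equal-mean convention p = 1), then SGoF across the
family: while the count of p ≤ α (α = 0.05) exceeds its binomial
expectation significantly (one-sided binomial test at level α), the
smallest remaining p-value is declared significant and removed from the
family. The discovery set is a prefix of the p-value ranking; the largest
declared p is reported as the adjusted threshold. The family shrinks as
discoveries are removed — the fixed-family variant cannot declare a
fully-significant family significant in its entirety, which contradicts
the intended behavior on degenerate inputs.

Positions are clustered by k-means (k = 4, 10 restarts, seeded) on
standardized per-position profiles — mean ε, mean signed −log10 p,
fraction significant — and clusters are labeled by centroid mean-ε
ordering: negative, insignificant, positive, strong positive. Structural
context uses the minimum heavy-atom distance from a residue to the folate
C6 atom; conservation is the alignment-column Kullback–Leibler relative
entropy in nats (gaps excluded; uniform background by default; "conserved"
defaults to the top quartile), with Fisher's exact test for set
enrichment. The empirical effect-size floor for calling epistasis
defaults to |ε| ≥ 0.1 and is configurable.

## Catalytic inference

For each mutant, (kcat, Km) proposals are drawn log-uniformly over
10^±3 × the WT values and accepted when the model reproduces the
WT-normalized growth in *every* background within
max(2·SEM, 0.035) relative-growth units. Three growth values cannot pin
kcat and Km separately; in the Km ≳ fol_tot regime the acceptance region
runs along rays of constant kcat/Km, so the summary is the median
log10(kcat/Km) of accepted samples **on that ray** (Km ≥ fol_tot) —
including low-Km samples would mix in a branch where growth constrains
kcat alone and bias the median. The protocol runs 50 independent
inference repeats; the estimate is the mean of per-repeat medians with
the SD across repeats.

Diagnostics make the partial identifiability explicit: `lower_bound`
(the maximum-power corner of the sampling box is itself consistent —
the growth law is saturated and the data only bound power from below),
`upper_bound` (the minimum-power corner is consistent), `interval` (the
accepted ray-power 95% spread exceeds 2 decades), and `empty` (nothing
accepted). Only unflagged mutants carry point estimates; recovery
statistics are computed over those.

The 0.035 tolerance floor was chosen over a looser 0.05 after direct
measurement: with ±0.05 the accepted interval for mutants near the
growth plateau is grossly one-sided and the median acquires a
+0.1–0.3 decade bias; 0.035 still exceeds twice the worst-case
growth-recovery error (±0.03 at the default depth), so noise-free rows
always retain a non-empty acceptance region.

## The synthetic generator: study conditions

The generator emulates a plasmid-based saturation mutagenesis selection
in a turbidostat. Defaults, chosen once:

- **Backgrounds.** TYMS WT (kcat 5 s⁻¹, Km 20 µM, 1 µM), a partial
  loss-of-function expressed at 3× concentration so its Vmax *exceeds*
  WT (kcat 2.5 s⁻¹ — the negative-epistasis regime), an intermediate
  variant at 10-fold reduced velocity, and a near-inactive variant at
  sentinel kinetics. DHFR WT: kcat 13 s⁻¹, Km 20 µM, 1 µM.
- **Pool and law.** fol_tot = 5 µM, growth law (g_max 1, g_min 0.1,
  K 0.037, n 1) — a hyperbolic growth–THF relation. With Km at or above
  the pool size the cycle runs between zero- and first-order, so growth
  depends on each enzyme's catalytic power and the landscape varies
  along both kcat and Km; this is also the regime in which the
  catalytic-inference degeneracy takes its constant-power form. WT sits
  on the plateau at relative growth ≈ 0.99.
- **Mutational-effect prior.** log10-power offsets from WT are drawn
  from a two-mode mixture applied at *position* level (substitutions at
  one position have coherent effects): a near-neutral mode (mean −0.2,
  position SD 0.3, within-position SD 0.6) and a deleterious mode
  (mean −5.0, position SD 0.6, within SD 0.8) with weight 0.12, giving
  a bimodal growth distribution with ≈12% of mutations at or below the
  inactive floor. Km scatters 0.3 decades around WT.
- **Selection.** Timepoints {0, 4, 8, 12, 20, 24} h, triplicate vials,
  5×10⁵ reads per sample (multinomial, so depth is exact), bulk rate
  0.35 doublings/h (M9-like ~3 h doubling — slow enough that near-dead
  lineages keep countable late timepoints), WT lineage at 20× a
  mutant's initial abundance, per-replicate growth jitter SD 0.005
  (replicate biology; turbidostat replicates are near-concordant).
  Per-base error 0.001 applies only to optional FASTQ emission.
  Drift/bottlenecks between timepoints are not simulated (populations
  stay large under turbidostat dilution).

What passing tests show — and what they do not: the generator's lineages
are exactly exponential, its sequencing exactly multinomial, and its
noise uniform per base; real data add PCR jackpots, index hopping,
batch structure between vials, and mutants whose growth defects act
through stability or aggregation rather than catalysis. Recovery
statistics here therefore bound what the estimators can do when the
model family is correct; they do not certify performance on real
libraries.

## Numerical choices and limitations

- Steady-state fraction clipped at 1e−12 from both ends; Hill
  evaluation guards 0 and ∞ abundance explicitly.
- Count tables accept non-integer (corrected) counts; thresholding
  happens before, not after, correction-free analyses.
- k-means label assignment is by centroid ordering, so label names are
  stable across seeds even when cluster indices permute; degenerate
  (all-identical) profiles raise rather than silently returning one
  cluster.
- Each mutant's catalytic inference is independent (no hierarchical
  pooling), matching the source protocol; saturated and censored
  mutants are reported as bounds, never imputed.
- The steady-state model ignores the rest of folate metabolism (single
  reduced-folate pool, no dTMP flux term — thymidine is supplied), and
  DHFR abundance is one shared parameter across mutants; mutations
  acting through abundance rather than catalysis are mis-attributed by
  construction.
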