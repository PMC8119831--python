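# Methods

This note documents the models and procedures implemented in `wmnet`,
the choices made where the problem is genuinely open, and what the
synthetic validation does and does not demonstrate.

## Network construction

Nodes are the 92 parcels of a modified AAL scheme: the 45 standard AAL
regions per hemisphere (39 cortical + 6 subcortical) plus the bilateral
substantia innominata. An edge between parcels *i* and *j* exists when
at least 3 tractography streamlines connect them end-to-end; the
threshold suppresses false-positive connections from deterministic
tractography noise and is inclusive (counts ≥ 3 are kept). Retained
edges are weighted

    w_ij = count_ij · FA̅_ij / ((v_i + v_j) / 2),

the streamline count times the mean FA along the connecting
streamlines, divided by the average volume (mm³) of the two parcels to
discount parcel size. The phrase "mean FA calculated by multiplying
the number of streamlines" admits two readings; we implement
count × mean FA (equivalently the sum of per-streamline mean FA) as the
default and expose the mean-FA-only variant behind
`build_network(..., weight_scheme="fa")`. Volumes are the subject's
native-space parcel volumes; intracranial volume never rescales the
weights and enters only as a model covariate.

## Graph measures

Five local measures per node and nine global measures per network, on
the weighted undirected graph:

* **degree** k_i — count of suprathreshold edges (binarized network);
* **strength** s_i = Σ_j w_ij;
* **clustering** — Onnela geometric-mean form on weights rescaled by
  the network-wide maximum, C_i = Σ_{jh}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
  (k_i(k_i−1)), zero for k_i < 2. The variant is the Brain
  Connectivity Toolbox default; the measure is scale-free in the
  weights.
* **shortest paths** — Dijkstra over edge lengths d_ij = 1/w_ij, the
  conventional mapping for FA-weighted connectomes (stronger
  connection = shorter distance). Unreachable pairs are infinite.
* **nodal path length** L_i — mean finite distance to the other nodes;
  an isolated node gets 0 with a warning.
* **betweenness** — Brandes accumulation on the same lengths,
  unnormalized, each unordered endpoint pair counted once, equal-length
  ties shared fractionally. Group inference is invariant to the common
  normalization constant (2/((n−1)(n−2))), so none is applied.

Globals: mean degree, mean strength, mean clustering C, characteristic
path length L (mean over *reachable* pairs — disconnected pairs are
excluded rather than propagating infinities), and global efficiency
E_glob (mean of 1/d over all ordered pairs, 1/∞ = 0). An edgeless
network has L undefined (NaN, warned) and E_glob = 0.

## Null-model normalization

γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩, normalized E_glob = E_glob/⟨E_rand⟩ and
σ = γ/λ, with ensemble means over 100 matched random graphs preserving
node count, edge count and the exact degree sequence (Maslov–Sneppen
double-edge swaps). Open choices, fixed as follows:

* swap budget 10 × edge count proposals per graph (standard mixing
  heuristic, configurable); a swap finding no legal move in 100 random
  proposals is skipped and counted;
* weights travel with the rewired edges, so the weight multiset is
  preserved exactly (common toolbox behavior; the alternative of
  reassigning weights would confound topology and weight effects);
* per-subject ensemble seeds are derived from (global seed, subject
  id), so cohorts are reproducible regardless of processing order.

Self-normalization of an already-random input recovers γ, λ ≈ 1 within
single-draw sampling error; on 92-node inputs at density 0.25 the
ensemble spread keeps the ratios within a few percent of 1.

## Disease-effect inference

All models are ordinary least squares with two-sided t tests. The six
covariates — age, sex (0/1), education (years), deep and
periventricular WMH grades (ordinal 1–3, entered numerically, as the
source protocol does not state a coding), intracranial volume (mm³) —
enter every model; rows with missing values are dropped listwise and
logged.

* **Independent disease effects**: measure ~ ADCI + LBCI + covariates,
  with both flags binary (the mixed group has both).
* **Interaction screening**: the ADCI×LBCI term (1 for mixed only) is
  tested at α = 0.05; if not significant the model with the lower AIC
  is kept, ties going to the simpler model. AIC = n·ln(RSS/n) + 2k
  (Gaussian OLS up to a constant; alternative constants cancel in the
  comparison). Significance of the interaction is judged on the
  uncorrected p-value, before any FDR step.
* **Group contrasts**: two-group subset with a group indicator plus the
  covariates. In the pipeline a contrast whose subset design is rank
  deficient (a covariate constant within the two groups — possible in
  small simulated cohorts) is skipped with a warning rather than
  aborting the run; the direct `groupwise_contrast` API raises.
* **Multiplicity**: Benjamini–Hochberg step-up across the 92 nodes for
  each local measure and disease flag, and across the 14
  neuropsychological tests per cognition model. No correction is
  applied across the nine global measures, mirroring the explorative
  design this analysis reproduces.
* **Cognition models**: for every network measure with a significant
  disease effect, each of the 14 battery z-scores is regressed on the
  measure plus covariates (Model 1) and additionally on the implicated
  disease flag (Model 2), to separate network-mediated association
  from confounding by disease presence.

The 92-node sweeps use a vectorized batch OLS; it is verified against
statsmodels and a normal-equations oracle to 1e-8 in the test suite.

## Synthetic cohort generator

No imaging data accompany the analysis this package operationalizes,
so validation rests on a generator that emulates the study design:
groups of 37 controls / 22 pure ADCI / 19 pure LBCI / 36 mixed, with
covariate distributions loosely matched to the published demographics
(age ≈ 70–75 ± 6–9 y, education ≈ 9–12 ± 4–5 y, sex and WMH grade
frequencies per group). ICV is not reported per group and is invented
(1.43×10⁶ ± 1.3×10⁵ mm³, identical across groups).

The base connectome is a *modular random template*: within-lobe pairs
are 4× as likely to connect as between-lobe pairs at an expected
density of 0.25, streamline counts are log-normal (median ≈ 7,
log-SD 1 — so a realistic share of tallies sits near the 3-streamline
threshold), FA is Gaussian (0.45 ± 0.06), volumes log-normal. This is
a simulation device chosen for its small-world-like statistics, not a
claim about anatomy. Each subject multiplies template counts by
log-normal noise (log-SD 0.4, reflecting the poor between-subject
reproducibility of deterministic tractography counts), adds FA noise
(SD 0.02) and volume noise, then applies the disease scalings *before*
integer rounding; scaled counts that round below 1 delete the edge, so
scalings translate into degree and topology changes through the
streamline threshold.

Default planted effects (the study conditions):

* LBCI — count scale 0.5 on edges incident to the left caudate (the
  localized degree deficit) and 0.95 on between-lobe edges (a mild
  diffuse long-range loss);
* ADCI — FA scale 0.99 on all edges: a diffuse integrity effect with
  *no* topology change, so ADCI serves as a negative control for all
  degree-based tests and rejects at the nominal rate;
* no interaction scaling (the source analysis found none).

At the default diffuse scaling the global normalized measures respond
only weakly — deliberately, since the emulated study's global effects
were themselves marginal (p ≈ 0.04–0.05). A named configuration,
`integration_deficit_config`, strengthens the between-lobe scale to
0.75; under it the LBCI effect on λ is positive and on normalized
E_glob negative, reproducibly across seeds, and this configuration is
the study condition for direction-of-effect checks on global measures.

Cognition scores are *generated* as linear functions of the subject's
own network measures, disease flags and covariates plus Gaussian noise
(default: every score loads +0.08 per left-caudate degree unit and
−0.5 per disease flag, noise SD 1), so recovery tests have an exact
ground truth. Scores are generated from the noise-free linear
predictor, not from re-measured noisy networks.

What passing these simulations shows: the construction, measurement,
normalization and inference chain is internally correct, calibrated
under the null, and powerful enough to recover effects of the planted
kind at study size. What it does not show: anything about real
tractography — the template is distance-free, counts are independent
across edges given the template, FA noise is homoscedastic, and
cognition is exactly linear; real data violate all four.

## Numerical and degenerate-input conventions

Matrix inputs must be symmetric to 1e-8 and are symmetrized exactly
after weighting; diagonals are forced to zero. Distances use inverse
weights in double precision; L averages finite entries only.
Normalization ratios with a zero or undefined ensemble mean are
reported as NaN with a warning. Constant outcomes in batch OLS get
t = 0 (p = 1) when the coefficient is also 0. Rank-deficient designs
raise an error naming the collinear columns (QR with column
pivoting).

## Problem sizes used in validation

The test suite and the acceptance script run entirely on synthetic
data: oracle checks on 200 random networks of ≤ 8 nodes (exhaustive
path enumeration stays tractable), calibration on 1000 replicate null
designs, recovery on 100–200 replicate cohorts of 114 subjects
(degree-based, no null ensembles needed), and two full 114-subject
pipeline runs with 100-graph ensembles per subject. These sizes were
chosen so a complete validation runs in minutes on one CPU while
keeping every Monte-Carlo margin comfortable.

## Known limitations

* The generator plants multiplicative edge-set scalings only; additive
  or topologically targeted (e.g. hub-preferential) lesion models are
  not implemented.
* The rewiring null preserves the degree sequence but not the strength
  sequence; strength-preserving and geometry-preserving nulls are out
  of scope, as is latticization-based small-world normalization.
* Betweenness is not normalized; compare absolute values across
  networks of equal size only.
* OLS assumes homoscedastic residuals; planted scalings that alter
  variance between groups mildly perturb nominal error rates (measured
  rates at the default conditions remain within [0.03, 0.07]).
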