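# Methods

## Competition model and the proteomic stage

A chemoproteomic competition experiment reads out target engagement as the
dose-dependent loss of capture on an active-site affinity resin. We model
the captured fraction of a specifically bound protein with a
four-parameter logistic in competitor dose d (µM):

    f(d) = ns + (1 − ns) / (1 + (d / IC50)^h)

with IC50 the half-competition dose, h the Hill slope (default 1) and `ns`
the non-specific fraction remaining at saturating competitor. Proteins
that do not bind through the competed site (background and other
CoA-binders in the synthetic panel) are dose-flat. Capped control beads
capture `capped_fraction` of the baseline irrespective of dose.

Reporter intensities are analyzed on the log₂ scale. Channels are first
scaled so every channel total equals the mean pre-normalization total —
the single-factor analogue of normalizing on the total peptide intensity
of each channel; it preserves within-channel ratios and the grand total.
Per-dose contrasts (each treated dose vs the pooled vehicle channels) give
log₂FC = mean difference of log₂ intensities and a two-tailed two-sample
t-test p-value. Student's equal-variance test is the default: at three
replicates per group it holds its nominal size (measured type-I error
≈ 0.05 under the null), whereas Welch's correction is conservative at this
n (≈ 0.033); Welch remains available via `equal_var=False`. Zero and
negative intensities are treated as missing and excluded pairwise, never
imputed; a protein needs two finite replicates per group or its contrast
is missing. When both groups have zero variance the test statistic is
undefined and we define p = 1 for a zero difference and p = 0 otherwise.
Enrichment (affinity vehicle vs capped beads) is filtered at strict
log₂FC > 0.6 and p < 0.05.

## Clustering stage

Only proteins with p < 0.05 (strict) in at least one dose condition enter
clustering, and rows with any missing feature are dropped afterwards.
Features (per-dose log₂FC) are standardized to zero mean and unit
population variance; a zero-variance column is set to zero with a warning
rather than dividing by zero. t-SNE uses two output dimensions and
perplexity `min(30, max(5, ⌊(n−1)/3⌋))` — the cap of 30 with a
dataset-size adjustment respecting the 3·perplexity < n validity bound —
additionally clamped to n−1, which t-SNE itself requires for very small n.
PCA initialization plus a fixed seed makes the embedding deterministic.
k-means (k = 5 by default, k-means++ with 10 restarts under a fixed seed)
labels the embedding; cluster ids are relabeled by descending cluster size
so reports are stable across runs. Compactness is the mean of all
m(m−1)/2 pairwise Euclidean distances within a cluster, computed in the
2-D embedding (the tight/diffuse distinction refers to the embedded map);
singletons score 0 by definition.

Sensitive-cluster selection is automated by an explicit rule where visual
inspection would otherwise be needed: a cluster is dose-sensitive when its
centroid mean log₂FC at the highest dose is ≤ −1.0 and the centroid is
non-increasing along the dose order within a 0.1 tolerance (absorbing
replicate noise in otherwise monotone profiles). Both constants are
configurable. Candidates are sensitive-cluster proteins absent from the
complex annotation; annotated members are reported separately as positive
controls.

## Composite scoring stage

Per-model metric tables carry ipTM, LIA, LIS and pDockQ/mpDockQ for five
models per pair. LIA/LIS follow the local-interaction-score convention:
over the union of the two inter-chain PAE blocks, cells with PAE strictly
below 12 Å are interface cells; LIA is their count and LIS the mean of
(12 − PAE)/12 over them (0 with no interface cell). The cutoff and
transform are exposed in `ThresholdConfig`. pDockQ is the published
sigmoid `L/(1+exp(−k(x−x0))) + b` with x = mean interface plDDT ·
log₁₀(contacts), contacts being inter-chain residue pairs within 8 Å of
the representative atom (CB, CA for glycine); dimer constants
(0.724, 152.611, 0.052, 0.018) are the default and the multimer (mpDockQ)
fit is provided. Zero contacts return the sigmoid floor b.

Models aggregate per pair by the per-metric maximum (best-model
convention, the default); mean and best-model-by-DockQ are selectable.
Each aggregate is compared to the minimum-acceptable thresholds LIA 1610,
LIS 0.073, DockQ 0.175 with ≥ (they are minima), and the pass count maps
to the weighted constant k: 3 → 1.0, 2 → 0.75, 1 → 0.5, 0 → 0. Each of
the three metrics is min-max normalized over the whole cohort (defined 0
when the cohort has no spread — a spreadless metric carries no ranking
information), and `composite = k · (n_LIA + n_LIS + n_DockQ)` ∈ [0, 3].
ipTM is reported and used only to break ranking ties (then pair id,
lexicographically); it is not summed into the composite.

## Contact mapping stage

Inter-chain CA–CA distances come from `scipy.spatial.distance_matrix`.
Contacts are pairs strictly under 8 Å; high-confidence contacts strictly
under 6 Å with symmetrized PAE strictly under 25.7 (PAE is asymmetric; the
mean of the two directions is the default symmetrization, with min/max
selectable — 25.7 itself is treated as an opaque configurable constant).
AlphaFold3 contacts are inter-chain cells of the `contact_probs` matrix
strictly above 0.1, counted once per unordered pair. The consensus is the
pair-set intersection of the high-confidence and AF3 sets, plus the
residues appearing in at least one consensus pair. Residues are reported
1-based in the structure's author numbering; matrices are indexed in
concatenated chain-A-then-chain-B order. Hetero-atoms and waters are
ignored.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the real inputs — a TMT-style
design of {0, 0.1, 1, 10} µM × 3 replicates with capped controls (a wider
{0, 0.01, 0.1, 1, 10, 30} µM grid is available), lognormal multiplicative
reporter noise (intensities are positive and right-skewed; the noise CV
defaults to 0.15 with unit-mean noise), planted members at IC50 0.05 and
0.5 µM on a background of 290 non-specific binders, metric tables whose
planted interactors clear all three thresholds while decoys fail at least
one metric in every model, and toy interfaces with exact planted CA–CA
distances. They do not emulate peptide-level roll-up, missing-value
mechanisms, isotope impurity, batch effects, or correlated noise across
channels — so a passing planted-recovery test shows the statistical
machinery is correct, not that real-data preprocessing choices are
optimal.

Toy complexes place each chain on a straight line with residue spacing
`background + interface + 1` Å so that pulling a planted chain-B residue
directly above its chain-A partner leaves every non-planted pair at least
`background_distance` apart; placement is verified post hoc to 0.1 Å and a
chain-B residue planted against two chain-A partners raises a generation
error. With ordinary 3.8 Å backbone spacing these exact constraints are
geometrically unsatisfiable, which is why the toy geometry is deliberately
non-physical.

## Numerical choices and limitations

All boundary conventions are explicit: strict `>`/`<` for the enrichment,
significance, distance, PAE and probability filters (a value exactly at
the cutoff is excluded); `≥` for the three composite-score thresholds
(they are stated as minima). Determinism: every stochastic step (noise,
t-SNE, k-means) is seeded; rerunning a pipeline config reproduces the run
report byte-for-byte apart from its single timestamp field. Problem sizes
in the test suite (300-protein panels, 34-pair cohorts, 10 seed pairs,
1,000-instance filter sweeps, 10,000-repeat null calibration) were chosen
as the smallest sizes at which the planted effects and the calibration
bands are stable.

Known limitations: t-SNE cluster memberships are seed-dependent, so
specific published cluster compositions are not expected to reproduce
under a different seed — planted-recovery rates, not memberships, are the
validated quantity. The per-metric-maximum aggregation is one defensible
reading of "five models per pair"; mean or best-model aggregation can
reorder mid-table pairs. ipTM is never recomputed from coordinates, and
no structure prediction is performed — metric tables and structures are
inputs.
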