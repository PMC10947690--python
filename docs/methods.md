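# Methods

## The system being modelled

A membrane-anchored enzyme exchanges ligands with the bilayer and the
cytosol through six transient tunnels (2a, 2b, 2c, 2e, 3, S).  Two
per-frame observables govern usability: the tunnel's bottleneck (its
narrowest cross-section, characterised by a radius and the residues
forming it) and the minimum distance between a channel-specific pair of
gating residues near the catalytic site.  The package treats one long
equilibrium ensemble of such observations and asks: how prevalent and
permeable is each channel, which residue trios form the bottleneck,
where do the exits sit relative to the membrane, and what metastable
states do the gating distances visit?

## Synthetic data as the benchmark

All inputs are generated by `gatescape.synthetic` from a single latent
Markov chain (`GroundTruthHMM`): the hidden state emits the six gating
distances (Gaussian per state, clipped at 0.05 nm) and drives channel
detection and bottleneck radii.  One chain driving everything is a
deliberate choice — it gives every downstream estimator a recoverable
ground truth, so parameter-recovery tests are exact rather than
qualitative.

Built-in conditions (all overridable):

* per-channel detection probabilities equal the reference prevalences
  (e.g. 3129/3313 for channel 2b, 222/3313 for 2c);
* bottleneck radii are Gaussian with the reference per-channel mean/SD
  (1.77 ± 0.39 Å for 2b down to 1.16 ± 0.17 Å for 2c), *clipped* — not
  rejection-sampled — at the 1.0 Å detection floor, mirroring the
  semantics of a tunnel probe that cannot report a narrower passage;
* per-snapshot throughputs are Gaussian with the reference per-channel
  mean/SD, clipped to (0, 1];
* per-channel open-state probability targets default to
  0.681/0.662/0.374/0.171/0.284/0.390 (2a/2b/2c/2e/3/S); open-state
  emission means are drawn in 0.58–0.72 nm, closed in 0.32–0.44 nm,
  and the open subset of states is chosen by subset-sum dynamic
  programming over the stationary weights so the stationary-weighted
  open mass best matches the target;
* membrane frames are jittered planes (head plane 20 Å, tail plane
  12 Å, 1 Å Gaussian jitter, 64 lipids per leaflet over a 100 Å box)
  with per-channel exit anchors at fixed heights — the channel between
  the membrane-embedded helices at the head plane, the solvent channel
  highest above it;
* distances are in nm, structural coordinates and radii in Å (the
  field's mixed convention); conversion constants are explicit.

What the generator does **not** emulate: autocorrelated emission noise
within a state, state-dependent membrane deformation, bottleneck
residue sets correlated with gating distances, or non-planar bilayers.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to every artefact of real
trajectories.

Sizes used by the default test and acceptance runs (10–100 k frames,
2–16 trajectories, 32–64 clusters, 10 replicate models) are scaled-down
analogues of a production analysis chosen to keep full runs in the
minutes range; all entry points accept larger values.

## Channel statistics

Summaries are over detected frames only; SDs use the population
convention (divide by n), documented so tests can be exact.  Priority
is avg_throughput × snapshots / total_frames — the average throughput
counting undetected frames as zero.  An empty channel reports missing
(None) means, never 0, so downstream correlations are not corrupted.

Per-snapshot throughput is taken verbatim from the record when present;
otherwise it is computed from the radius profile as the cost integral
exp(−Σ_k Δs_k · ½(r_k⁻² + r_{k+1}⁻²)) (trapezoidal evaluation).  The
exact internal formula of tunnel-analysis tools is not published; this
form has the defining qualitative properties — strictly in (0, 1],
increasing in every radius, decreasing in length — and the aggregation
layer is independent of it whenever recorded throughputs are supplied.
Zero-length profile segments cost nothing; decreasing arc positions are
rejected.

## Bottleneck trios

A trio is admissible when all three pairwise sequence separations
exceed 3 positions; the neighbour rule is interpreted *pairwise*, since
the trivial associations it exists to remove arise between pairs.  A
trio counts at most once per frame, so c_i is a frame count and
f_i = c_i / N with N the channel's detected-frame count.  Top-k ties
break by ascending lexicographic triple for cross-platform determinism.
Radius histograms use half-open 0.125 Å bins anchored at the 1.0 Å
floor (both configurable); the per-trio counts conserve c_i exactly.
First-occurrence distances are Euclidean distances from the recorded
bottleneck location to the fixed channel start point, normalized to the
furthest trio found.

## Exit geometry

Only the leaflet in contact with the membrane-embedded helices enters
plane averages and minimum-distance searches; leaflet membership comes
from input flags and is never recomputed.  Exits exist in every frame
(the Cα anchors always exist), whether or not the tunnel was detected,
so exit series are full length.  Correlation matrices are listwise
(frames where all six series are defined); constant series yield NaN
rather than an arbitrary value.  Invariants: rigid z-shifts of membrane
and anchors together leave heights unchanged, and h_N − h_T equals the
(negated) head-to-tail plane separation for every channel.

## Gating analysis

Open/closed is a strict inequality (open ⇔ d > threshold; a sample at
the threshold is closed) — a deterministic tie rule.  The summary open
fraction pools all six channels within a trajectory, then averages the
per-trajectory percentages (population SD across trajectories); a
per-channel breakdown is also available.  Spearman correlations use
average ranks for ties; the lag scan covers 0–2000 ps in 100 ps steps
by default.  2-D histograms share their bin edges with the 1-D
histograms, so the marginals match exactly by construction.

Note on the open-fraction SD: across-trajectory scatter is governed by
the ratio of trajectory length to the chain's mixing time.  The default
generator mixes within hundreds of frames, so its across-trajectory SD
(a percentage point or two) is far smaller than what slowly-mixing real
trajectories show; the mean is the meaningful benchmark quantity.

## TICA → clustering → HMM

TICA solves C(τ)U = C(0)UΛ with symmetrized covariance estimates after
removing the global mean; eigenvalues are then real and |λ| ≤ 1, and
the columns of U are C(0)-orthonormal.  Signs are fixed by making each
eigenvector's largest-magnitude component positive.  A diagonal
regularization (default 1e-10) guards against singular C(0).  Because
the projected components are variance-normalized, pure-noise components
carry as much metric weight in k-means as slow ones; retaining only the
top components (`tica_k`) is recommended — and used by the scaled-down
recovery experiments — when the feature space is known to contain fast
noise directions.

Discretization is k-means (k-means++ seeding, deterministic under a
fixed seed).  HMM estimation strides the discrete trajectories by
lag/dt (unconditional stride), initializes from a maximum-likelihood
Markov model on the clusters coarse-grained by k-means in the space of
its leading right eigenvectors (a PCCA-style spectral split), and
refines by Baum–Welch EM (hmmlearn's categorical implementation), whose
log-likelihood is monotonically non-decreasing.  Replicate diversity
comes from seeded multiplicative log-normal perturbations of the
initial emission matrix.  Non-convergence at the iteration cap flags
the model rather than failing.  The stationary vector reported with a
model is recomputed from its transition matrix, not taken from EM.

State matching between independently estimated models (for the
Chapman–Kolmogorov test and parameter recovery) is maximum-weight
bipartite assignment on emission-distribution overlap (element-wise
minima).  The Chapman–Kolmogorov table compares T(τ)^k with a model
re-estimated at lag kτ after matching, reporting max-abs element
discrepancies for k = 2..5.

## The fractional-uncertainty criterion

Model selection scans cluster counts, lag times and state counts,
fitting many replicate models per configuration, and minimizes the mean
of

    f = ( Σ_i |μ_i − ν_i| / μ_i ) / N

over replicates; of the winning configuration the single smallest-f
replicate is returned.  Two readings of μ and ν coexist in the package,
and the distinction matters:

* **Selection score** (`selection_score`): μ is the left eigenvector of
  the transition matrix at λ = 1 (the stationary distribution) and ν
  the right eigenvector at λ = 1, each normalized to unit sum.  For a
  row-stochastic matrix the right eigenvector is constant, so ν is the
  uniform distribution (computed numerically, not assumed) and f
  scores how far the equilibrium populations deviate from uniform —
  zero exactly for a doubly stochastic chain.  Under-split models
  carry bloated merged states and over-split models starved ones, so
  across replicates the mean score dips at state counts whose
  metastable decomposition is balanced.  This is the quantity the scan
  minimizes.
* **Self-consistency check** (`stationary_two_routes`): μ and ν as two
  independent numerical routes to the stationary vector (dense left
  eigensolver vs constrained null-space least squares).  For any
  well-conditioned chain this f is at machine-precision level (~1e-13
  regardless of model quality, growing only with round-off), which
  makes it a convergence diagnostic, not a selection criterion — a
  scan of it over state counts would order models by numerical noise.

States with stationary weight below a 1e-12 floor raise a
degenerate-state error listing the offending states instead of silently
inflating f; such replicates are recorded as NaN in the scan table and
excluded from the mean.

The state-count recovery experiment uses a fixed 4-state ground truth
(`hierarchical_4state_ground_truth`): a symmetric — hence uniform-
stationary — transition matrix in which one state couples an order of
magnitude more weakly than the rest, with emission means laddered
across the 0.5 nm boundary.  The design makes the state count
identifiable by the selection score: every coarse lumping of the chain
that EM can find (1+3 at two states, 2+1+1 at three) is unbalanced,
while the true 4-state decomposition is perfectly balanced, and
over-split models starve states.  The scan over 2–8 states with 10
replicates each shows a clear minimum of the mean score at 4 states.

## Labelling, open probabilities, flux

Each hidden state's per-channel mean gating distance is the
posterior-weighted average of the strided per-frame distances; the
state is open for a channel iff that mean strictly exceeds the boundary
(default 0.50 nm; a tie is closed).  The equilibrium open probability
per channel is the stationary mass of its open states.

Reactive flux from the closed macrostate A to the open macrostate B
follows standard transition path theory: the forward committor solves
(I − T_CC)q⁺_C = T_CB·1; the backward committor is the forward
committor of the time-reversed chain T̃_ij = π_j T_ji / π_i; the gross
flux is f_ij = π_i q⁻_i T_ij q⁺_j (i ≠ j) and the total flux the gross
flux out of A, in probability mass per lag step (the unit is recorded
in the output metadata).  The boundary scan labels states per model at
each boundary in 0.43–0.56 nm (step 0.0025 nm), reports mean ±
population SD of the total flux across the model ensemble, and emits a
logged missing entry for any (boundary, channel) at which all states
fall on one side.

## Representative conformations

`sample_representative_frames` draws strided frame indices per state
with probability proportional to the posterior state memberships.  The
conformational spread measure superposes each representative frame's
gating-pair atoms onto the ensemble-mean conformation (Kabsch, via
scipy's rotation alignment; the mean is computed by aligning to the
first frame, averaging, and one refinement pass — the reference choice
is a documented convention), sums the per-frame RMSDs and divides by
the number of states to remove the bias toward models with more states.

## Known limitations

* The throughput formula is a convention, not a published definition;
  analyses that depend on absolute throughput values should supply
  recorded per-snapshot throughputs.
* EM on categorical emissions cannot identify hidden structure in
  dynamics-free (iid) data; the rank-one transition matrix it returns
  is the correct degenerate limit, but state identities are arbitrary
  there.
* The boundary scan's flux is per lag step; converting to physical
  rates requires dividing by the lag time, which is left to the caller.
* Gating-residue identities are configuration input
  (`GatingConfig.pairs`), not constants of the package.
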