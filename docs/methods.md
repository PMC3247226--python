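# Methods

## Model

The inference engine treats network reconstruction as N independent
one-to-many regression problems. For each gene *g* a multilayer
perceptron maps the (normalised) expression of *g* to the expression of
the remaining N−1 genes:

    y_j = tanh( Σ_h w′_hj · tanh(w_h · x) ),   j = 1 … N−1

There are no bias terms: with every gene rescaled to [−1, 1] the input
and target distributions are roughly centred, and a bias-free network
forces the probe of an untrained (zero-weight) network to be exactly
zero, i.e. "no inferred interaction" is the natural origin of the score
scale.

The hidden-layer width is ⌈√(1·(N−1))⌉ — the geometric-mean rule of
thumb between fan-in (1) and fan-out (N−1). Ceiling is used so the
layer never vanishes; the width can be overridden
(`LearningParams.hidden_override`).

Training is classical online back-propagation on E = ½ Σ_j (y_j − t_j)²
with momentum:

    Δw(t) = −η ∇E + α Δw(t−1)

one update per pattern, patterns reshuffled each epoch from the same
generator that initialised the weights. Online updates plus per-epoch
shuffling is the textbook reading of back-propagation for this setting;
it is cheap at these network sizes and, with all randomness derived
from one seed per gene (base seed + gene index), makes the whole
ensemble bit-reproducible and order-independent (genes can be trained
in any order, or in parallel, without changing the result).

After training, each network is probed with x = 1, the maximal
normalised expression. Because targets were normalised alongside the
input, the output for gene *j* estimates how strongly *j* co-varies
with *g*: +1 perfect correlation, −1 perfect anti-correlation, ≈0 none.
Row *g* of the correlation matrix is this probe vector with 0
reinserted at position *g* — self-regulation is excluded by
construction.

### From scores to networks

The probe is directional (drive *g*, read *j*) but evaluation is over
undirected graphs, so the two directed entries are symmetrised. The
default takes the larger magnitude, `max(|c_gj|, |c_jg|)`, because the
stronger direction is the one that identifies a regulation; `mean` and
`signed-max` are available alternatives. Anti-correlation counts as
interaction by default (absolute values), switchable off. A link is
predicted when the symmetrised strength strictly exceeds the threshold
(default 0.5, interpreted as "correlation above one half is
meaningful").

Because weight initialisation is random, repeated runs differ; the
majority-voting mode reruns inference `n_runs` times with derived seeds
(base + run·N), binarizes each, and keeps links appearing with
frequency strictly above `vote_fraction`.

## Learning parameters

| parameter | default | meaning |
|---|---|---|
| learning_rate η | 0.01 | gradient step per pattern |
| momentum α | 0.8 | fraction of previous update carried over |
| epochs | 200 | passes over the sample set |
| init_scale | 0.1 | weights start uniform in ±init_scale |
| hidden_override | none | fixed hidden width instead of ⌈√(N−1)⌉ |

The defaults were chosen once with the package's own sweep harness: on
12-node scale-free trees at data ratio 2, every cell of
η ∈ {0.005, 0.01, 0.05} × α ∈ {0.5, 0.8} scores mean MCC 0.46–0.50 —
a flat plateau with (0.01, 0.8) on top — so the defaults are not a
tuned point but the centre of a stable region. Divergence is detected
by a per-epoch finiteness check; note that with tanh activations a too
large η saturates rather than overflows, so in practice the check fires
on corrupted (non-finite) inputs.

## Synthetic data

**Topologies.** Barabási–Albert graphs grow one node at a time, each
new node attaching to `edges_per_step` existing nodes with probability
∝ (degree + 1)^power; the +1 keeps empty-degree nodes reachable and
makes `power` act as the hub-concentration knob (0 = uniform
attachment). With `edges_per_step = 1` the sample is a tree — the
sparse, hub-dominated regime typical of transcriptional subnetworks.
Erdős–Rényi graphs are G(n, p) with p = k/(n−1) so the requested mean
degree k is the expected degree; disconnected samples are kept, since
nothing in the evaluation requires connectivity.

**Expression (SLC).** Seeds S ~ U(−1, 1)^{M×N}; E = S + S·adjM. Each
gene is its own seed plus the sum of its neighbours' seeds, so linked
columns share a common term and are linearly correlated while unlinked
columns are independent. This is deliberately the *easiest* non-trivial
generative model: purely linear, noise-free, steady-state. Passing
recovery tests on SLC data shows the engine extracts linear
correlation structure reliably; it says nothing about non-linear
regulation, measurement noise, hidden confounders or the
indirect-correlation ambiguity of dense graphs, all of which real
expression data have. Degree > 1 nodes already induce correlated
neighbours (shared hub terms), which is why recovery degrades as the
attachment exponent concentrates links on hubs.

**Toy motifs.** Four 4-gene exercises (A, B, C, D) with a threshold
gate — a regulator acts only when its signal magnitude exceeds θ,
otherwise the target is uniform noise of amplitude ε:

- *single*: A inactive (0) with probability 1−p, else U(0, 1];
  active A drives B linearly (+ε noise); C, D pure noise. Truth A–B.
- *cooperative*: C = gate(s_A + s_B); truth A–C, B–C.
- *multiple*: B and C each gate(s_A); truth A–B, A–C.
- *indirect*: B = gate(s_A), C = gate(realised B); truth A–B, B–C.

The numeric settings (p = 0.5, θ = 0.5, ε ∈ [−0.1, 0.1], M = 100) are
package defaults chosen to keep the motifs' qualitative structure sharp
— strong direct links, a detectable second-order A–C correlation in the
indirect chain — and are configurable in `ToySpec`; they are
illustrative, not estimates of anything biological. All toy profiles
are linearly rescaled before return since they feed the engine
directly.

**Normalisation.** Linear rescaling maps each gene column affinely onto
[−1, 1] (constant columns to 0, the "no signal" midpoint); statistical
normalisation z-scores with the population (1/M) standard deviation
(the convention is pinned for testability; the distinction is
immaterial at the tolerances used); discretisation replaces the series
by the sign of successive differences, losing one row. The engine
requires non-raw input (tanh cannot match unbounded targets) but
accepts all three schemes, because normalisation is itself a studied
factor; z-scored targets exceed the tanh range in the tails, which is
part of what that comparison measures.

## Evaluation

Scoring is over the N(N−1)/2 unordered pairs, diagonal excluded.
Recall, precision and MCC use the 0-on-zero-denominator convention,
which keeps threshold curves total and reads "no information" as
chance level.

Threshold curves sweep evenly spaced cutoffs from 0 up to, but
excluding, the maximum observed strength. The maximum is excluded
because a strict cut there predicts the empty network for any scorer,
which would pin every curve to the uninformative point (recall 0,
MCC 0); with it excluded a perfect scorer integrates to exactly 1 and
truth-independent scorers average to 0, which are the calibration
points that make AUC_MR values interpretable. The AUC integrates over
recall (not threshold) by the trapezoidal rule, averaging
duplicate-recall points and anchoring recall 0 and 1 with the nearest
computed value — the same convention as PR-AUC, chosen for
comparability; an all-zero score matrix yields a degenerate
single-point curve with AUC 0 and a warning.

Threshold grid search evaluates every grid value (default 0.00–1.00,
step 0.01) and breaks ties toward the smaller threshold (prefer the
denser prediction when MCC cannot distinguish). The train/validation
study partitions *samples* (the topology is fixed), grid-searches the
threshold on the training half against the truth, and reports the
validation MCC at that threshold across repeated random splits.

## Protocol scale

Benchmark protocols default to desk scale: 3 topologies × 5 data
repeats, networks of ≤ 50 nodes, with per-topology error bars reported
as twice the standard deviation of the raw scores. These sizes give
stable qualitative trends (monotone improvement with data ratio,
degradation with hub concentration) in minutes on a single core; raw
per-run scores and all seeds are kept in the result object so any cell
can be replayed bit-exactly. The acceptance script uses 20-node trees
with 5 seeds per condition and 10-seed toy-motif averages for the same
reason.

## Known limitations

- SLC data is linear and noise-free; results there are an upper bound
  on what the engine achieves on realistic expression data.
- The probe uses only x = +1; a gene whose effect is asymmetric around
  the origin would be characterised incompletely.
- Tanh saturation means probe scores rarely reach ±1 and training error
  on z-scored targets has a floor in the tails.
- Dense graphs (high mean degree, strong hubs) produce correlated
  neighbourhoods the per-gene decomposition cannot disentangle; this is
  a property of the method, visible in the power-exponent sweep.
- The evaluation is strictly undirected; direction information present
  in the asymmetric probe matrix is discarded at the symmetrisation
  step.
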