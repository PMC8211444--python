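# Methods

## The models

All three models are conjunctive latent-class ("noisy and-gate") item
response models for binary responses `u_ij` of `N` examinees to `J`
items.  An examinee carries a binary attribute profile
`alpha_i = (alpha_i1, ..., alpha_iK)`; an item declares which attributes it
requires through a binary Q-matrix.  The ideal response under strategy `m`
is the conjunction

    eta_ijm = prod_k alpha_ik ^ q_jkm ,

with the empty-product convention that an item requiring no attributes has
`eta = 1`.

* **DINA** — one strategy; `P(u_ij = 1) = (1 - s_j)^eta_ij g_j^(1 - eta_ij)`
  with slipping `s_j` and guessing `g_j`.
* **MS-DINA** — `M` alternative attribute sets (one Q-matrix per strategy)
  with a *shared* `(s_j, g_j)`; solving by any one strategy suffices:
  `eta_ij = max_m eta_ijm`.
* **MMS-DINA** — a finite mixture: each examinee latently uses one
  strategy `c_i in {1..M}` with mixing proportions `pi`, each strategy has
  its own item parameters `(s_jm, g_jm)`, and the attribute profile given
  membership is `alpha_ik | c_i = m ~ Bernoulli(mu_m)`.  Marginally
  `P(u_ij = 1 | alpha_i) = sum_m pi_m (1 - s_jm)^eta_ijm g_jm^(1 - eta_ijm)`.
  With `M = 1` this is exactly the DINA model, and the package's DINA fit
  is the same code path (bit-identical draws for identical seeds).

The "mixing proportions are related to the distribution of alpha" is
implemented as exactly the hierarchy above (`alpha | c` Bernoulli with a
strategy-specific mean) and nothing more.

Strategies are identified only through their distinct Q-matrices.  If two
strategies share an identical Q-matrix the mixture components are
exchangeable; the package warns and makes no further attempt at
identification.

## Priors

`pi ~ Dirichlet(beta, ..., beta)` with `beta = 0.01`;
`mu_m ~ Beta(0.5, 0.5)`; every `s_jm` and `g_jm` follows a four-parameter
Beta `4-Beta(1, 2, 0.1, 0.5)` — a Beta(1, 2) rescaled to the support
(0.1, 0.5).  With both supports at (0.1, 0.5) the monotonicity condition
`1 - s_jm > g_jm` holds automatically; non-default supports that can break
it trigger a warning but are not forbidden.  Note that the conventional
generating truth `g = 0.1` sits on the lower support bound, so guessing
estimates are necessarily biased upward by a small amount — visible in the
recovery tables.

## The sampler

One sweep cycles five full-conditional updates:

1. `pi | c ~ Dirichlet(beta_m + n_m)` (conjugate; valid when `n_m = 0`).
2. `c_i` from its exact M-point conditional.  By default the profile
   `alpha_i` is *marginalized out* of the membership weights and redrawn
   immediately afterwards (`blocked_membership=True`): the two draws
   together are one exact joint draw of `(c_i, alpha_i)` from their joint
   full conditional, which mixes far better when the strategies are weakly
   separated.  `blocked_membership=False` gives the strictly alternating
   update that conditions on the current `alpha_i`.
3. `mu_m ~ Beta(sum alpha + 0.5, n_m K - sum alpha + 0.5)` over strategy
   members (conjugate).  The printed form of this update contains `N x K`
   where the likelihood only involves strategy-`m` members; the
   members-only count `n_m K` is the correct conjugate update for the
   stated hierarchy and is the default.  The literal full-sample variant is
   available via `PriorSpec(literal_mu_update=True)`.  Under the blocked
   kernel `mu` is updated after the profiles so that the `(c, alpha)` block
   conditions on a single `mu` value.
4. `alpha_i` exactly from its `2^K`-point conditional by enumeration
   (cap `K <= 12`, covering the shipped designs' K = 5 and 7; an
   attribute-at-a-time Gibbs fallback exists for larger K).
5. `(s_jm, g_jm)` from a truncated non-conjugate density: Bernoulli counts
   among strategy-`m` members (`eta = 1` examinees inform `s`, `eta = 0`
   examinees inform `g`) times the 4-Beta prior.  The default sampler is
   inverse-CDF on a fixed 1,024-point midpoint grid over the support —
   deterministic, robust, and exact up to a grid discretization of
   4e-4; a logit-scale random-walk Metropolis alternative
   (`item_param_method="mh"`) is provided.  Empty groups reduce to prior
   draws; no component deletion.

Initialization: `alpha_ik ~ Bernoulli(0.5)`, uniform memberships,
`mu = 0.5`, item parameters at their support midpoints.  Multi-chain runs
draw `s, g, mu` from their priors to disperse the starts.  Defaults are
chains of 10,000 sweeps with 5,000 burn-in and no thinning; all
randomness flows through one `numpy.random.Generator`, so runs are
bit-reproducible from the seed, and simulated datasets regenerate
bit-exactly from `SeedSequence([design_seed, replication])`.

### Label permutation and multimodality

When the generating truth makes strategies statistically similar (equal
item parameters, equal attribute means, equal mixing proportions — the
standard recovery-study setting), the posterior develops near-mirror modes
related by a strategy relabelling; per-examinee updates essentially never
cross between them.  Three devices address this:

* a **permutation Metropolis move** each sweep proposes exchanging two
  strategy slots of `(pi, mu, s, g)`; because the latents are redrawn from
  their exact conditionals immediately after, its acceptance ratio is the
  collapsed-posterior ratio (with a correction when the Dirichlet prior is
  asymmetric).  It is exact and cheap, and lets a chain escape a
  low-mass relabelled basin;
* **burn-in basin selection**: at one-third and two-thirds of burn-in the
  chain is restarted from every label permutation of its current state,
  each branch re-equilibrates for `basin_lookahead` sweeps (default 120),
  and the branch with the highest average collapsed log-likelihood is
  kept.  This is an initialization heuristic only — retained draws come
  from the unmodified exact kernel;
* **draw-wise relabelling for diagnostics**: convergence diagnostics
  canonicalize strategy labels per retained draw (nearest permutation to a
  common reference in the posterior-mean metric) before computing PSRF,
  the standard practice for variance-based diagnostics on mixture MCMC
  output.  `psrf_report(..., align_labels=False)` diagnoses the raw
  traces.

Parameter estimates and model-fit criteria are reported from the raw
(unrelabelled) draws; in the shipped study designs the generating truths
are label-symmetric, so relabelling would not change the recovery
aggregates.

## Model-fit criteria

Both criteria are functions of per-observation log-likelihood terms
evaluated at each retained draw.  For the mixture model two conditioning
conventions exist, and they can rank models differently:

* **conditional** (default, `criteria_likelihood="conditional"`): each
  cell is evaluated at the sampled latent state — the member strategy's
  response probability `(1 - s_j,c_i)^eta g_j,c_i^(1-eta)`.  This treats
  the two latents `alpha` and `c` symmetrically (the "conditional DIC"
  convention for mixtures) and is the convention under which the
  true-model-identification results of this model family hold: on
  mixture-generated data the fitted mixture model beats the
  single-strategy DINA model on both DIC and LPML.
* **mixture** (`criteria_likelihood="mixture"`): each cell mixes the
  per-strategy probabilities with `pi`, conditioning on `alpha` only.
  This asymmetric hybrid blurs every cell across strategies (a penalty of
  up to `log M` per discriminating cell even for a perfectly estimated
  model) and in our experiments makes the single-strategy DINA model win
  DIC on mixture-generated data — it rewards the model that concentrates
  its conditional likelihood rather than the true generating model.

From the per-sweep joint log-likelihoods `log L_r` (stored per retained
sweep together with the per-observation terms):

* `Dev_bar = -(2/R) sum_r log L_r`, `Dev_hat = -2 max_r log L_r`,
  `P_D = Dev_bar - Dev_hat >= 0`, `DIC = 2 Dev_bar - Dev_hat` (smaller is
  better).  `Dev_hat` deliberately uses the best retained draw, not a
  plug-in at posterior means.
* `CPO_ij` is the harmonic mean over draws of the per-observation
  probabilities, computed as a max-shifted log-mean-exp of negative
  log-probabilities so that values down to 1e-300 cannot overflow;
  `LPML = sum_ij log CPO_ij` (larger is better).

Per-observation terms are stored at sampling time (`R x N x J` float32),
trading memory for exactness; recovery-only studies disable the storage.
Criteria computed on different response matrices refuse to be compared
(a SHA-1 fingerprint of the data travels with the draws).

## Evaluation metrics

Across `M_rep` simulated replications with posterior means `theta_hat(m)`
and posterior standard deviations `SD(m)`:

    Bias = mean_m (theta_hat(m) - theta)
    MSE  = mean_m (theta_hat(m) - theta)^2
    SD   = mean_m SD(m)

Block aggregates (e.g. all strategy-1 slipping parameters) report the mean
of |Bias| (ABias) and plain means for MSE and SD.  The per-item biases are
effectively one-signed in these designs, making signed and absolute
aggregates indistinguishable; absolute is the safer default and a signed
option exists.

Attribute classification of EAP profiles (posterior mastery probability
thresholded at 0.5; a tie at exactly 0.5 classifies as mastered) is scored
by: `h_k` the marginal rate per attribute, `t` the proportion correct on
all K, `v` the proportion correct on at least K-1, and `z` the proportion
*mis*classified on at least K-1 attributes (interpreted as >= K-1
mismatches).

PSRF follows the Brooks-Gelman corrected form from between/within-chain
variances, without chain splitting by default (a split mode exists);
degenerate constant traces report 1.  The default flag cutoff is 1.2, with
1.05 available for conservative use.

## The data generator

`simulate_dataset` draws `alpha_ik ~ Bernoulli(0.5)` (configurable),
memberships multinomial with `pi = (1/M, ..., 1/M)` by default (the true
mixing proportions of the mixture design are a package choice — equal
weights — as no canonical value exists), and responses Bernoulli with the
selected model's response probability at the conventional truths `s = 0.3`,
`g = 0.1` for every item and strategy.  MS-DINA data use `eta = max_m
eta_ijm` at the same truths.  Two printed Q-matrix designs ship as
built-ins (30 items / 5 attributes and 40 items / 7 attributes, two
strategies each); any user Q-matrix is accepted for the other designs.

What the generator does *not* emulate: item-parameter heterogeneity,
correlated attributes, examinee covariates, missing responses, and
Q-matrix misspecification.  Passing recovery tests therefore shows the
estimator works under the stated generating law, not that the model fits
any particular empirical dataset.

## Study problem sizes

The package's replicated studies default to 50 replications of
10,000-sweep chains.  The shipped acceptance runs and the heavier tests
use 10 replications of 3,000-sweep chains (1,500 burn-in) at N = 1,000 —
posterior means stabilize well before that length at these sample sizes,
and 10 replications put the Monte-Carlo error of the table aggregates
around 0.002-0.005, far inside the +-0.03 comparison band.  The
convergence protocol runs at full length (two dispersed chains of 10,000
sweeps, N = 500).

## Known limitations

* At N = 500 with label-symmetric truths the posterior can hold two
  non-negligible relabelled modes; a 10,000-sweep chain cannot equilibrate
  the mode *weights*, so mixing-proportion diagnostics can exceed the
  cutoff on unlucky datasets even after relabelling.  Longer chains (or
  the permutation move given more sweeps) resolve it.
* The exact profile update enumerates `2^K` states; beyond `K = 12` the
  fallback sweep is a plain Gibbs scan with the usual slow-mixing caveats.
* Guessing parameters inherit a small positive bias from the prior support
  excluding the conventional truth `g = 0.1` (see Priors).
* No missing-data handling, polytomous responses, higher-order attribute
  structure, WAIC/Bayes factors, or automatic selection of the number of
  strategies.
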