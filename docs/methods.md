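# Methods

`meavocab` analyses multi-electrode-array (MEA) recordings of cultured
cortical networks whose spontaneous activity consists of network bursts —
brief (~100–250 ms) events recruiting a large fraction of the 120
electrodes.  The package treats each network's bursts as realizations of a
finite vocabulary of spatiotemporal patterns behaving like discrete
transient attractors: nearby initial states converge onto a common
trajectory, and the between-realization variability shrinks over the course
of a burst.  Everything downstream — evoked-response matching, stimulation
site selection, and the before/after plasticity statistics — is built on
that vocabulary.

## Preprocessing

Spike events (threshold crossings, per electrode, in ms) are convolved with
a unit-mass Gaussian kernel (σ = 2 ms, truncated at ±4σ; per-bin mass by
Gaussian CDF differences, so total mass equals the spike count to <0.01%)
and integrated over half-open 5 ms bins anchored at the recording start.
Around each stimulation pulse, all electrodes are masked for the first
5 ms (the electrical artifact spans the array) and the six stimulating
electrodes are masked from the pulse to the end of the evoked response
(detected burst end, or a conservative 300 ms fallback); masked cells never
enter sums or correlations.

## Burst detection and extraction

Bursts are detected on the summed (masked) activity trace.  σ is the
standard deviation of the whole epoch's trace — bursts and silence alike —
recomputed per network and per epoch.  An upward crossing of 4σ triggers an
event; the event extends backward and forward to the surrounding 0.5σ
crossings, which define its start and end.  Triggers falling inside one
0.5σ-exceedance run merge into a single window, and windows clipped by the
recording edges are excluded (an incomplete matrix would bias every
correlation).  Analysis keeps the first 100 ms from the burst start
(20 bins × 120 electrodes); shorter bursts are zero-padded and flagged.
The 120-d activity of the first 5 ms bin is the burst's *initial state*.
A configuration switch allows anchoring the analysis window at the 4σ
trigger instead of the 0.5σ start; the start anchor is the default because
the threshold that *defines* the burst is the one the initial state should
follow.

## Similarity metrics

For bursts `X1, X2 ∈ R^{120×20}`:

* **corr2** — Pearson correlation of the flattened matrices, the primary
  similarity measure and the scale on which the network threshold θ lives.
* **COM distance** — each burst is projected to the 2-D path of its
  activity centre of mass, `com(t) = Σ_n x_n X[n,t] / Σ_n X[n,t]` with
  `x_n` the electrode positions in mm.  The distance is the summed per-bin
  Euclidean distance between two paths (mm·bins).  The centre of mass is a
  weighted *average*: the normalizing denominator keeps every path inside
  the array.  Bins with zero total activity have no defined COM; the
  distance sums over bins valid in both bursts and is rescaled by
  T/valid-count so values stay comparable.
* **spatial-profile correlation** — Pearson correlation of the time-summed
  per-electrode profiles (which electrodes participated, regardless of
  when).

plus the **initial-state correlation** between first-bin vectors.  A metric
with zero variance or no jointly valid bins is *missing* (NaN), never
silently zero; missing values exclude the pair from graph edges.

## Thresholds and the similarity graph

Across burst pairs, each metric's marginal is bimodal: a minority mode of
same-attractor pairs and a majority bulk of different-attractor pairs.  Per
metric, a two-component Gaussian mixture is fitted and the threshold is the
equal-posterior point in the valley; an initial-state-correlation threshold
is fitted the same way once and paired with each metric.  Three numerical
details matter in practice: components are initialized at sample quantiles
(the similar mode holds only ~1/k of the pairs, and an unguided fit tends
to split the dominant bulk instead); the COM-distance marginal is fitted on
the log scale (a right-skewed positive bulk); and a three-component fit is
allowed when BIC prefers it, with component means split into similar/rest
groups at the largest gap (the bulk is itself structured, one shoulder per
template pair).  If the similar component is not separated from its
neighbour by at least the sum of their standard deviations, the fit refuses
and demands a manual override — an automatic threshold on an effectively
unimodal marginal would be arbitrary.  All thresholds can be pinned
verbatim by overrides.

A pair is linked under a metric when it passes both that metric's threshold
and the initial-state threshold; summing the three binary graphs gives a
symmetric integer-weighted (0–3) similarity graph with zero diagonal.

## Spectral clustering

Zero-degree bursts are unclassified a priori.  On the remaining graph the
normalized symmetric Laplacian `L_s = D^{-1/2} (D − S) D^{-1/2}` is formed
from the integer weights used directly as affinities, and the k
eigenvectors with the smallest eigenvalues, rows normalized to unit length,
embed the bursts.  k defaults to the eigengap heuristic (largest gap in the
first 25 eigenvalues), overridable.  k-medoids — an alternating
(Voronoi-style) iteration with 20 seeded random restarts, keeping the
lowest total within-cluster distance — assigns labels; k-medoids is
implemented in-package because no installed library provides it.  Clusters
holding fewer than 2% of all bursts are dissolved into the unclassified
set; *percent explained* is `100·(B − unclassified)/B`.  Worked example:
1017 bursts with 151 unclassified give 85.15 ≈ 85%.

## Evoked responses

The array tiles into 20 disjoint stimulation sites of 6 adjacent electrodes
(3 rows × 2 columns, numbered column-major over blocks).  Each probed site
receives 30 pulses 10 s apart.  The stimulating electrodes are excluded
from every correlation involving an evoked burst.  A spontaneous cluster
*explains* one evoked repetition when the spontaneous bursts with
`corr2 > f_th·θ` to it (the reduced threshold accommodates the different
initial states of evoked bursts) amount to at least m% of all spontaneous
bursts and the plurality of that similar set belongs to the cluster
(unclassified bursts do not vote; ties break toward the cluster with higher
mean correlation to the response).  Defaults `f_th = 0.88`, `m = 0.5%`;
on the synthetic studies the assignment is stable across the grid
f_th ∈ {0.85, 0.88, 0.9} × m ∈ {0.5%, 1%}.

Per site, **robustness** is the median pairwise corr2 among its responses
and **existence** the size of the smallest cluster set jointly explaining
≥50% of them (greedy by explained count; ∞ if unreachable).  Site selection
ranks by robustness and enforces two quantitative stand-ins for what is
otherwise a visual procedure: *uniqueness* (within-site correlations must
stochastically dominate across-site ones; one-sided Mann–Whitney at 0.05)
and *distinctness* (average-linkage clustering of 1 − median cross-site
correlation must place the chosen sites in different branches at a
configurable cut).  A site qualifies for the plasticity analysis when
robustness ≥ 0.8 and existence ≤ 2 (both configurable; the qualification
region is reported graphically in the source experiments without printed
bounds).  The *stimulated* cluster of a qualifying site is the one
explaining most of its repetitions; *non-stimulated* clusters are those
explaining zero repetitions of all selected sites; clusters in between
enter neither group.

## Plasticity statistics

The central statistic compares, for a reference pattern (a cluster's
bursts), the correlation samples to the spontaneous population before and
after stimulation:

    dCDF(α) = α − CDF_after(x_α),   x_α = Q_before(α),  α ∈ {0.75, …, 0.95}

with a type-1 (inverse-CDF) empirical quantile and a right-continuous
(≤-counting) empirical CDF, and reference self-pairs excluded from the
samples.  Values lie in [α − 1, α]; negative values mean the
high-correlation tail shrank — the pattern is disappearing from the
spontaneous vocabulary.  The α grid runs 0.75–0.95 in steps of 0.025
(configurable).  For group comparisons, values are optionally z-scored
within network (pooling that network's pattern × α values) before pooling
across networks, removing between-network differences in correlation scale
and baseline drift; the per-α one-sided test that one group's effect is
larger (more negative) is a Mann–Whitney U, replaced by an exact
permutation test on the difference of means when both groups have ≤12
values — the source experiments report p-values without naming a test, and
an exact test is the safest default at n = 11 vs 5.

**Evoked variability** (does the response stereotype?): responses are
grouped into chronological 30-minute windows; each window's value is the
mean Euclidean distance of its flattened responses from the window mean,
and the series is normalized by the first window (empty windows are NaN
gaps; an all-zero series is defined as all ones and flagged).

**Basin analysis** (do the same initial states still lead to the same
bursts?): the candidate set per epoch holds the bursts whose initial-state
correlation to the reference cluster's medoid initial state exceeds the
clustering initial-state threshold (an "any member" criterion is available),
and the dCDF is computed between the epochs' within-candidate pairwise
corr2 samples.

## The synthetic generator

No public recordings accompany the source experiments, so a seeded
generator plants a known vocabulary and every analysis is validated as
parameter recovery.  A template is a moving 2-D Gaussian bump: a cubic
spline through random control points (clipped to the array) times a
single-peaked envelope (saturating rise × exponential decay).  Templates
are rejection-sampled until all pairs have noiseless corr2 < 0.6 and path
starts ≥ 2.5 mm apart — distinct attractors occupy distinct initial-state
regions.  A realization offsets the path start (Gaussian, σ = 0.6 mm) and
the per-electrode gains (σ = 0.3), both decaying with a 30 ms half-life:
early bins vary between repetitions, late bins converge — the attractor
signature the convergence profile measures.  Spikes are emitted per
electrode by thinning a homogeneous candidate stream against the intensity
evaluated on a 1 ms grid (exact for that intensity), on top of a 0.2 Hz
baseline, with event times stored to 0.1 ms.  Burst onsets follow a renewal
process — a 1 s refractory gap plus an exponential waiting time whose mean
is calibrated so the realized rate equals the configured 8/min.

Several defaults are calibrated to the phenomenology reported for real
cultures rather than derived from first principles: the envelope starts at
~50% of peak (network bursts recruit abruptly, and the first 5 ms must
carry an informative initial state); the bump starts at half its 2.5 mm
width and widens with a 20 ms time constant (bursts ignite locally, and
initial states of different patterns must not overlap); and the peak
multi-unit rate is 4 kHz, which places the Poisson-noise ceiling on
within-pattern corr2 near 0.9, where the within-site correlation
distributions of real recordings sit.  Evoked responses start from activity
pinned to the site's 6-electrode centroid, blend into the mapped template's
path over 12 ms, and carry 0.7× the spontaneous realization noise (the
stimulus pins the trajectory); non-robust sites draw a random template at
2× noise on every pulse.  In "after"-epoch stimulation sessions the noise
scale ramps down linearly (1.0 → 0.3) over each site's own pulse sequence,
so responses grow more stereotyped.

The planted plasticity effect: in the after epoch each stimulated
template's weight drops to a residual 0.02.  The removed probability mass
is *not* renormalized onto the surviving templates — those keep their
before-epoch frequencies — but becomes *remapped* bursts: bursts still
launched from a stimulated template's initial-state region whose flattened
basin no longer pulls them in.  A remapped burst starts exactly on the old
pattern and then diverges (the realization noise grows, rather than decays,
with an 8 ms half-life, at 6× amplitude).  This choice is deliberate and
was selected over two alternatives that fail structurally: convex mixtures
of surviving templates are mutually similar smeared patterns (pairwise
corr2 0.6–0.9) and masquerade as a new attractor, and independent novel
trajectories relate to the surviving patterns generically, which distorts
the non-stimulated patterns' dCDF at low α.  A corrupted non-converging
realization keeps the bulk relation to every *other* pattern essentially
unchanged while removing the high-similarity tail of its own — exactly the
planted effect the statistics must recover — and directly models the
mechanistic observation that the same initial states lead to divergent
bursts after stimulation.

What the generator does **not** emulate: biophysics (no synapses or
plasticity rules), slow drift of patterns over hours, burst-duration and
amplitude correlations, unclassifiable background bursts in the before
epoch, and electrode-specific noise statistics.  Passing recovery tests
therefore shows the *analysis* is correct and well-calibrated under the
stated generative assumptions, not that real cultures satisfy them.

## Reference studies and problem sizes

The packaged studies (`meavocab.scenarios`) use 9 templates; the
spontaneous-recovery study runs a 2.1 h epoch (~1000 bursts) and a full
20-site probe; the plasticity study runs 2 h before/after epochs with three
stimulated templates at weight 0.20 each (robust stimulation sites evoke
prominent vocabulary patterns — the same prominence visible in the source
experiments' example cluster) and 8 reference bursts per cluster, keeping
the reference set small relative to its cluster so that excluding
reference self-pairs does not deplete the before-epoch sample.  The null
calibration renders bursts directly as expected-count matrices from the
realization model (skipping spike emission and detection, which are
validated separately), which makes 100 independent control comparisons
cheap.  These sizes keep each study in the minutes range on one CPU while
holding Monte-Carlo noise on the dCDF well below the planted effect
(multinomial noise on a pattern's frequency scales as 1/√B).

## Known limitations

* The bimodal threshold fit needs a few hundred burst pairs and genuinely
  separated modes; sparse or drifting recordings will (correctly) force
  manual thresholds.
* The eigengap heuristic inherits spectral clustering's weaknesses for
  unbalanced or chained clusters; `k` should be overridden when the
  spectrum is ambiguous.
* dCDF values at the low end of the α grid sit in the bulk of the
  correlation distribution and are sensitive to compositional change of
  the population, not only to the reference pattern's fate; conclusions
  should weight the full α range.
* The basin analysis keys on initial-state similarity to a single medoid;
  patterns with extended or overlapping initial regions blur the
  candidate sets.
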