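# Methods

This note documents the models, estimators and numerical choices behind
`vigilnet`, what the synthetic cohorts do and do not emulate, and the known
limitations.

## Signal model and band extraction

A recording is a (channels × samples) matrix of sensor amplitudes in
microvolts with a 19-channel 10–20 montage in the canonical order
Fp1, Fp2, F7, F3, Fz, F4, F8, T3, C3, Cz, C4, T4, T5, P3, Pz, P4, T6, O1,
O2 (nodes 1–19). No reference scheme is assumed; recordings are consumed
as given.

Alpha activity is isolated with a dyadic DWT of depth `levels` (default 9).
The detail level kept is the one whose band [fs/2^(L+1), fs/2^L] contains
10 Hz — level 5 at fs = 500 (7.8125–15.625 Hz), re-derived from the same
rule for other rates, an error if no level within the requested depth
qualifies. Two numerical choices differ from the most common textbook
defaults, for cause:

* **Wavelet: `db8`** (8 vanishing moments). The dyadic crossover at
  7.8 Hz sits close to 10 Hz; with `db4` only ~84 % of a pure 10 Hz
  sine's energy lands at level 5, whereas `db8` captures ~95 % while
  staying a short, widely used orthogonal filter. Any PyWavelets
  orthogonal basis can be substituted (`wavelet=` everywhere).
* **Boundary handling: periodization.** Symmetric extension makes the
  coefficient set redundant, so coefficient energy no longer equals
  signal energy and the alpha energy ratio loses its clean
  interpretation. Periodized transforms are orthogonal whenever the
  length divides 2^levels (exact energy conservation; used by the tests)
  and perfectly invertible always. Wrap-around edge effects are
  negligible at minutes-long segments.

Optional denoising applies the universal soft threshold
λ = σ̂·√(2 ln n), σ̂ = median(|d₁|)/0.6745 (finest detail level), shrinking
every detail coefficient by sign(c)·max(|c|−λ, 0). The default is off:
the synthetic data carry no artifacts, and thresholding is validated
separately on noisy-sine fixtures.

The **alpha energy ratio** of a region is the mean over its channels of
(energy of alpha-level detail coefficients) / (total coefficient energy).
A zero-energy channel contributes 0 with a warning rather than NaN, to
keep batch pipelines total. Segmentation into stages (default 600 s; the
synthetic presets use 60 s, see below) floors the sample count and
discards the remainder.

## Connectivity

γᵢⱼ = |Σₜ sᵢ(t)sⱼ(t)| / √(Σₜsᵢ(t)²·Σₜsⱼ(t)²) on the alpha-band signal,
computed literally without mean-centring: band-limited signals are near
zero-mean, so this tracks the absolute Pearson correlation closely, and
the uncentred form is the definition adopted here (a centred variant is a
flag). The lag is fixed at zero — no lag search. The matrix is assembled
from the upper triangle and mirrored, so symmetry is exact and the
diagonal exactly zero; "energy" of the matrix is the sum of squared
elements (a sum of absolute values is deliberately not offered as the
default because squaring matches the signal-energy convention used for
the band ratios).

The estimator is deliberately mixing-prone: no leakage correction,
orthogonalisation or phase-based substitute is applied. The premise of
the whole framework is that sensor mixing is constant over time, so the
*classification* of connection patterns — not the individual link values —
carries the state information.

## Connection-cluster classification

Each node and all links incident to it form a connection cluster, encoded
as the node's N−1 connectivity strengths. Agglomeration starts from N
singletons and repeatedly merges the pair of clusters at minimal distance
(ids 1..N for leaves, N+s for the cluster born at step s), with the
Euclidean inter-node distance lifted to clusters by single linkage by
default (the arg-min merge formulation reads most literally as
nearest-member distance; complete and average are selectable). Distances
between clusters are maintained by Lance–Williams updates; a brute-force
re-clustering that recomputes every cluster distance from member vectors
each step serves as the test oracle.

**Distance pairing.** Euclidean distance between two self-deleted rows
compared *by position* is not invariant under channel renumbering: for a
third node k between i and j, position pairing compares i's strength
toward k with j's strength toward a different node. The package therefore
pairs attributes by the node they point to — the N−2 strengths toward
common third nodes are differenced, and the mutual pair (Fᵢⱼ, Fⱼᵢ) pairs
with itself, contributing zero by symmetry. This keeps exactly M = N−1
pairings per comparison and makes the whole procedure independent of
electrode numbering. Generic-vector agglomeration (`agglomerate`) keeps
plain positional Euclidean distance for arbitrary feature vectors.

**Determinism.** Equal-distance candidate pairs merge in lexicographic
(i, j) id order. Cutting at Z (default 4) undoes the last Z−1 merges;
each surviving cluster is ranked by the step at which its id is absorbed
into a later merge — earliest absorbed = Class 1, last = Class Z ("the
most different"). When two cut clusters are absorbed by the same merge
(always the case for the first merge above the cut), the cluster holding
the lower canonical node index takes the lower class. Consequence: class
ranks are permutation-equivariant except within such a tie, where the two
adjacent ranks may swap under renumbering; the partition itself is always
equivariant.

With Z = 4 every class is used exactly once per stage, so *some* node
always carries class 3 and 4 even in a featureless network; interpreting
high classes is only meaningful jointly across stages and subjects, which
is how both the tests and the acceptance script aggregate them.

## Louvain comparator

The comparison method is greedy two-phase modularity maximisation on the
same weighted graph (weights γᵢⱼ), via networkx, with the node sweep
order randomised by an explicit seed — the algorithm is order-dependent,
and pinning the seed makes runs reproducible while leaving its inherent
instability visible across seeds. Reported Q is the weighted modularity
(1/2m)·Σᵢⱼ[Aᵢⱼ − kᵢkⱼ/2m]·δ(cᵢ,cⱼ); tests verify every returned partition
against a direct double-sum evaluation, and an edgeless network returns a
single community with Q = 0.

## Differential entropy and statistics

Default DE estimator: Gaussian closed form ½·ln(2πeσ̂²) with the unbiased
sample variance, in nats (base-2 available); alpha-band EEG over
minute-scale windows is well approximated as Gaussian, and the closed
form is what makes DE practical as a feature. A Freedman–Diaconis
histogram plug-in (−Σ p̂ᵦ·ln(p̂ᵦ/w) over occupied bins) is retained to
check for departures; on 10⁵ unit-normal samples it agrees with the
closed form to ≲ 0.01 nats. Zero variance (or fewer than two distinct
values for the histogram) is an error, not a silent −∞. DE is computed
per node per stage on the alpha-band reconstruction, then averaged over
the frontal and parieto-occipital seven-channel regions.

The rank-sum test uses midranks; `exact` mode enumerates all C(n₁+n₂, n₁)
group assignments (valid under ties; default whenever n₁+n₂ ≤ 16) and
reports p = min(1, 2·min(P(U≤u), P(U≥u))); `normal` mode uses the
tie-corrected variance and a ±0.5 continuity correction. Complete
enumeration of the untied n₁ = n₂ = 8 null shows the normal approximation
tracks the exact p to < 0.01 wherever the exact p ≤ 0.3 and to ≤ 0.011
globally (the worst case sits at mid-range p ≈ 0.45, far from any
decision threshold); this matches scipy's asymptotic implementation
exactly. No multiple-testing correction is applied by default — the
per-segment tests are reported as-is, mirroring common practice in this
literature; that is a known interpretive caveat, not an endorsement.

## Synthetic cohorts

The generator emulates the two arms of a prolonged (1 h, six 10-min
stages) simulated-driving protocol with 14 subjects per arm, 19 channels
at 500 Hz. Per stage, every channel of a driven region receives the same
narrowband source — a sinusoid at the subject's alpha frequency
(10 ± 0.5 Hz between subjects) with a slow random amplitude envelope
(knots every 2 s, SD 0.2) — scaled by that region's stage gain, plus two
independent per-channel noise terms: broadband white noise (SD 1) and an
8–13 Hz filtered background (SD 1). The in-band background represents the
uncoordinated alpha activity every sensor picks up; without it,
band-limited correlation saturates for arbitrarily weak sources, which
real sensor EEG does not do. All channels then pass through a fixed
leakage matrix W, Wᵢⱼ = exp(−dᵢⱼ²/2·spread²) on a schematic 2-D layout
(spread 0.2, in head-radius units) — volume conduction that is constant
across time, stages and subjects. At spread 0.2 nearest-neighbour leakage
is ≈ 0.28 while next-nearest is < 0.05, enough to blur the matrices
without welding regions together.

Preset gains (chosen once, from the phenomenology the two arms should
exhibit, and fixed):

| arm | region | stage 1…6 gains |
|---|---|---|
| control | frontal | 2.5, 2.0, 1.2, 0.6, 0.4, 0.25 |
| control | parieto-occipital | 0.3, 0.8, 1.4, 2.0, 2.5, 3.0 |
| radio | frontal | 4.0, 3.5, 3.5, 3.5, 3.5, 4.0 |
| radio | parieto-occipital | 0.5 throughout |
| radio | auditory (T3, T4) | 3.0, then 0 |

The control arm realises the frontal→posterior migration of strong alpha
coupling; the radio arm keeps frontal sources strong in every stage (and
at larger overall amplitude than control, so regional DE separates the
arms at every stage) with an auditory burst only while the stimulus is
novel. Preset stages are 60 s rather than 600 s — the correlation,
clustering and DE estimators operate on 30 000 samples per stage, ample
for stable estimates, and a full two-cohort run completes in well under a
minute; full-length stages are one constructor argument away.

What the generator does **not** emulate: eye-blink/EMG artifacts, 1/f
background spectra, alpha spindle burst structure, nonstationary mixing,
inter-regional true coupling, or subject-level topography differences.
Passing end-to-end tests therefore show that the pipeline recovers a
known spatial-spectral ground truth through realistic leakage and
in-band noise — not that it would resolve every ambiguity of real scalp
EEG.

## Degenerate inputs and tie policy, summarised

* zero-energy channel → error in connectivity (named channel); zero
  signal in the alpha ratio → 0 with a warning.
* equal merge distances → lexicographic id order; equal absorption step →
  lower node index gets the lower class.
* Z = 1 → all nodes class 1; Z = N → every node its own class.
* table files without a sampling rate → explicit error demanding `fs` or
  a sidecar.
* EDF writing quantises to 16 bits over each channel's physical range;
  round-trips are exact only to that step.

## Limitations

* Merge-order classes are relative within a stage; absolute class values
  are not comparable across networks with different overall contrast.
* Single linkage chains: in dense low-contrast networks the cut can
  isolate singletons rather than regions (complete/average linkage are
  provided).
* The zero-lag correlation inherits every known sensor-space confound by
  design; conclusions about anatomical coupling are out of scope.
* DE values depend on amplitude scale (ln σ); only contrasts across
  stages/groups on a common scale are meaningful.
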