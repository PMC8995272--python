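# Methods

`mrfviz` analyzes the *encoding capability* of MR-fingerprinting (MRF)
flip-angle sequences: how distinguishable the signal evolutions of different
(T1, T2) tissue combinations are. The pipeline has five stages — signal
simulation, dimensionality reduction, registration, color-coding, and
quantitative measures — each described below together with the design
choices that were genuinely open.

## Signal model

MRF signals are simulated with the extended-phase-graph (EPG) formalism for
an unbalanced FISP sequence. The EPG state is the set of configuration
amplitudes (F+_k, F-_k, Z_k) indexed by integer gradient dephasing order k.
Per repetition:

1. RF rotation by the flip angle α about a fixed axis,
2. readout of the k = 0 transverse amplitude (the acquired signal),
3. T1/T2 relaxation over TR with E1 = exp(−TR/T1), E2 = exp(−TR/T2) and
   regrowth of Z_0 toward unit equilibrium (M0 = 1),
4. a unit dephasing shift of all transverse states (ideal spoiler).

Assumptions: perfect spoiling (integer shift per TR), no diffusion, no
B1+ inhomogeneity, no off-resonance, single-compartment tissues, no TE
decay on the readout. The RF phase is constant at 90° (rotation about y),
which keeps every configuration amplitude *real*; the recorded signal is
the signed real F+_0 amplitude. A signed real signal is required because
the downstream reducers (t-SNE, SVD) operate on real matrices.

The optional inversion pulse is an instantaneous 180° rotation followed by
a recovery delay `ti_ms` before the first excitation. The delay is not
dictated by the sequence definition; the default is one TR (15 ms), and it
is configurable. With this convention the first post-inversion excitation
produces a negative signal for short delays and crosses zero at
TI = T1·ln 2, the classical inversion-recovery null — both are tested.

Retained dephasing orders are capped at min(L+1, 101) by default. High
orders decay as E2^k per TR, so for the T2 range used here (≤ 300 ms,
TR 15 ms) the truncated amplitudes are far below double precision noise;
the cap is configurable, and the EPG kernel is validated against an
independent isochromat (many-spin) Bloch simulation to < 1e−3 per
timepoint (observed agreement is at machine precision, because equally
spaced isochromats represent all dephasing harmonics below the spin count
exactly).

## Relaxation grid

The default grid spans T1 = 20–2000 ms in 30 ms steps (67 values) and
T2 = 10–300 ms in 10 ms steps (30 values), keeping only combinations with
T1 > T2 — 1855 entries. Endpoints are inclusive. Entries are ordered
lexicographically by (T2, T1), so fixed-T2 tissue slices are contiguous;
this ordering is stable and is stored alongside the signal matrix in the
HDF5 layout (`/signals`, `/grid/t1`, `/grid/t2`, `/grid/entries`).

## Dimensionality reduction

Both reducers consume the raw signal matrix (1855 × 1000 at full scale);
no Z-scoring or other standardization is applied.

**t-SNE.** scikit-learn's TSNE with PCA initialization and a fixed budget
of 1000 iterations. Default perplexity: 750 for 2D embeddings, 200
otherwise — large relative to the 1855 entries because the dictionary is a
smooth two-parameter manifold rather than a clustered point set.
Barnes–Hut gradients are used for ≤ 3 output dimensions; above that the
exact O(n²) gradient is used (tree-based approximations only support up to
3 output dimensions). Which engine ran is recorded in
`Embedding.params["engine"]`.

A numerical subtlety: with PCA initialization the whole optimization is
deterministic, so repeated "runs" would be bitwise identical and a
stability analysis would be vacuous. The seed therefore enters through a
small Gaussian jitter added to the PCA initialization — standard deviation
1e−6, i.e. 1% of the conventional 1e−4 init scale — emulating the
intrinsic run-to-run stochasticity of t-SNE while keeping same-seed runs
exactly reproducible.

**SVD.** Entries are projected onto the top-k right-singular vectors of
the signal matrix (scores U·Σ truncated to k columns). Signs are fixed by
requiring the largest-magnitude loading of each singular vector to be
positive, which makes results deterministic and makes k-dimensional scores
nest inside (k+1)-dimensional ones.

## Registration

Embeddings of the same grid are compared after mapping them into a common
frame. Because every embedding point corresponds to a known (T1, T2)
entry, point correspondences are known and the optimal similarity
transform (isotropic scale, rotation/reflection, translation, minimizing
the sum of squared point-pair distances) has the classical closed-form
least-squares solution; no iteration is performed, since iterating cannot
improve a global closed-form optimum. Reflections are allowed by default
because embedding chirality is arbitrary; a rotation-only mode exists.
Degenerate (all-coincident) moving sets are rejected. The convention
throughout is to register everything to the *first* run of the *first*
sequence's embedding (E1).

## Color-coding

Embedding coordinates are mapped affinely into CIE L\*a\*b\*: for 2D,
(x, y) → (a\*, b\*) over [−80, 80]² at fixed L\* = 70; for 3D, the axes map
to L\* ∈ [25, 90] and a\*, b\* ∈ [−80, 80]. The affine map is anchored to
the bounding box of the reference embedding, so registered embeddings
share one color frame and equal coordinates give equal colors across maps.
The L\* = 70 plane and symmetric a\*/b\* ranges were chosen for wide sRGB
coverage; all are configurable, and only the *relative* color structure is
meaningful. Lab → sRGB uses the standard D65 conversion with out-of-gamut
channels clipped after conversion (clipping is the simplest gamut policy
and leaves in-gamut colors untouched; the round trip is exact to ~1e−6
in gamut). The dictionary map raster places T1 left→right and T2
bottom→top, with the unsampled T1 ≤ T2 triangle masked in light gray.

## Quantitative measures

For a set of entry vectors d_i the similarity matrix is

    S_ij = ||d_i − d_j||_2,   then   S ← 1 − S / max(S),

giving unit diagonal and values in [0, 1]. The global maximum is taken
over the *full* matrix before any tissue selection, so slice values remain
on a common scale (per-slice rescaling is available for sensitivity
analysis). Tissue slices fix one axis: white matter T2 = 80 ms (64
entries on the default grid), gray matter T2 = 110 ms (63 entries); the
iteration analysis instead fixes T1 (830 and 1340 ms on the default grid).

The scalar measure is ε = ||I − S_slice||_1 / M with M the slice size.
The ℓ1 norm admits two readings and both are implemented:

* `induced_l1` (default): maximum absolute column sum of I − S, over M;
* `entrywise_mean`: Σ|I − S| over M².

Lower ε means stronger diagonal structure, i.e. better encoding; ε = 0
iff the slice is the identity. Input conventions: the "full" source uses
ℓ2-normalized dictionary rows, SVD scores are likewise row-normalized,
t-SNE coordinates enter raw. Because distances are invariant to rigid
motion and the rescale absorbs global scale, ε is invariant under any
similarity transform of the coordinates — registration cannot change it
(tested numerically).

## Synthetic sequence generators

No machine-readable flip-angle trains are distributed with the published
sequences this methodology is typically applied to, so the package ships
generators for the two archetypes plus an iteration series:

* **smooth lobed train** ("Jiang-like"): repeating half-sinusoid lobes
  (~200 excitations per lobe) with per-lobe maxima drifting in the 10–70°
  band, inversion pulse on, 1000 angles, TR 15 ms;
* **jagged random train** ("Sommer-like"): i.i.d. uniform angles in
  [0, 70°], same length/TR/inversion;
* **iteration series**: linear interpolation from a flat 12° low-contrast
  train toward a structured 5-lobe train, emulating successive iterates of
  a sequence-optimization loop. The lobe count is fixed (not
  length-proportional) so the contrast structure — and the monotone
  decrease of ε along the series — is preserved at the shorter train
  lengths used in fast tests.

These fixtures reproduce the *qualitative* structure of the published
trains, not their values. Consequently the package's ε values land in the
same regime as published ones (~0.77–0.88 on the full source) and
reproduce ordering properties (removing the inversion pulse raises ε for
both WM and GM; full-rank SVD equals the full source; ε decreases along
the iteration series), but exact published table values require importing
the original trains through `read_sequence`. What passing tests show is
therefore correctness of the machinery and of these ordering/identity
properties — not agreement with any specific published sequence.

## Problem sizes and runtime choices

Full-scale analyses (1855 × 1000 dictionaries, perplexity-750 t-SNE) are
used for the grid, EPG, SVD-consistency and stability checks; unit tests
use a coarse 38-entry grid with 150-angle trains, where a full t-SNE run
takes a fraction of a second. A full-scale Barnes–Hut t-SNE run takes
tens of seconds; dictionary simulation is vectorized over all grid
entries and takes a few seconds.

## Known limitations

* The EPG model omits TE decay, diffusion, B1+/B0 effects, slice profiles
  and multi-compartment tissue — adequate for comparing encoding structure,
  not for quantitative signal prediction of a scanner acquisition.
* t-SNE determinism is tied to the scikit-learn version; embeddings (and
  hence colors) are reproducible only under a fixed library version.
* The Lab scaling constants are a visualization choice; absolute colors
  are not comparable across different reference frames.
* High-dimensional t-SNE (> 3D) uses the exact gradient and scales as
  O(n² · d) per iteration, which is slow beyond a few thousand entries.
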