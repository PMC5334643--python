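# Methods

This note documents the three models implemented in `serpintraffic` — their
assumptions, parameters, numerical choices, and known limitations — and what
the synthetic-data generator does and does not emulate.

## 1. Lattice aggregation model (`serpintraffic.aggregation`)

### Model

Protein monomers occupy sites of an `Lx × Ly × Lz` cubic lattice
(default `100 × 100 × 25`), periodic along x and y and closed along z; the
two z-boundary layers represent the compartment's exit/entry surface.  The
dynamics is a continuous-time Markov jump process simulated exactly with the
Gillespie algorithm: at each step the waiting time is exponential in the
total propensity and one event is chosen with probability proportional to
its propensity.  Infeasible moves (into occupied sites, through the closed
walls) never enter the event catalogue, so no rejection sampling occurs.

Events and propensities:

| event | propensity | notes |
| --- | --- | --- |
| injection | `k_in` per **empty** boundary site | new monomer is inactive |
| ejection | `k_out / i³` per boundary-touching entity | whole entity removed; `i = 1` for monomers |
| diffusion | `k_D` per free neighbouring site | free monomers only |
| activation | `k_A` per inactive monomer | activated monomers can bond |
| latency | `k_L` per active monomer | latent monomers never bond (they still diffuse and eject) |
| bond formation | `k_H` per adjacent eligible pair | see eligibility below |
| reptation | `k_R / i²` per free site adjacent to either chain end | whole chain slides one site |
| end rotation | `k_E` per free site adjacent to an endpoint's neighbour | endpoint relocates |
| kink flip | `k_K` per 90° corner whose diagonal partner site is free | corner monomer flips |
| fragmentation | `k_f` per internal bond | size-1 fragments become **active** monomers |

Bond eligibility: both partners must be bondable (a non-latent free monomer
or a chain endpoint), at least one partner must be an active monomer or
already polymerized, and the two ends of one chain may not close into a
ring.  Polymer–polymer joining is endpoint-to-endpoint only.

An *aggregate* is a polymer with at least `min_size` monomers
(default 10, configurable; the clearance–aggregation monotonicity holds for
`min_size ∈ {2, 10}`).

### Parameters

Time is measured in units of `1/k_in` and all rates are quoted in units of
`k_in`.  The shipped defaults are this package's own calibration, chosen so
that the aggregation transition falls inside `k_out/k_in ∈ [10⁻¹, 10³]` on
the default lattice:

`k_D = 10, k_H = 10, k_R = 1, k_E = 1, k_K = 1, k_f = 0.01, k_A = 1, k_L = 0`.

`k_out` is the control parameter swept in production runs.  The biological
reading — vesicular export capacity rising or falling, e.g. with membrane
composition — enters only through `k_out`; no mapping from any biochemical
quantity to a `k_out` value is implied.

### Numerics

`event_catalogue` / `gillespie_step` are the readable pure-Python reference
semantics.  Production runs (`run_until`, `sweep_kout`) execute in a numba
kernel that stores, per lattice site, the summed propensity of all events
anchored at that site, updates only the neighbourhood of each applied event,
and samples through a Fenwick tree (O(log N) per event).  Chain metadata
(length, boundary contacts, opposite end) is cached at both endpoints so
every propensity is a local function of a site's neighbourhood.  Exactness
safeguards: a full rebuild of the tree every 2²⁰ events against float
drift; an audit mode that recomputes all propensities from scratch every
`audit_interval` events and errors on any deviation > 10⁻⁹ (used in tests);
and a test asserting per-site equality between the kernel's propensities and
the Python catalogue on randomized states.

Degenerate geometry: with lattice extent 2 along a periodic axis the +x and
−x neighbours coincide; the per-direction event multiplicity is kept (a
move to that site carries rate `2 k_D`), consistently in the kernel, the
reference catalogue, and the test oracle.

Randomness: a PCG32 stream inside the kernel, seeded from the user seed via
`numpy.random.SeedSequence`; replicate seeds derive deterministically from
`(seed, grid index, replicate index)`.  Identical seeds give bit-identical
trajectories.

### Validation

* Event catalogue equals an independent brute-force enumeration, event by
  event, on handcrafted and randomized small states.
* Injection/ejection-only dynamics on a 2×2×2 lattice match the direct
  master-equation solution (`expm(Qt)`) within total-variation 0.02.
* The mass ledger (injected − ejected = units present) holds exactly at
  every recorded sample.
* Reduced problem sizes used in tests: 32×32×12 lattice, `t_obs = 10/k_in`,
  10 replicates for the monotonicity check; the acceptance script uses
  24×24×10 with `t_obs = 5/k_in`.

### Limitations

Aggregate counts *saturate* at very slow clearance (the lattice fills and
mass moves into longer chains rather than more chains), so the
count-vs-`k_out` curve has a plateau below `k_out/k_in ≈ 1`; rank
correlations across a grid that includes two plateau points can tie.  There
is no off-lattice structure, no chain stiffness, and no explicit vesicle —
clearance is a single rate.

## 2. Membrane–coat budding model (`serpintraffic.vesicle`)

### Model

Two-dimensional cross-section, read literally from the polygon picture: the
membrane is a **closed** polygon of `N_m` nodes (default bond `b = 1`,
preferred turn angle 0, stiffness `K_m`); the coat is an **open** polygon of
`N_s = N_m/10` nodes with stiffness `K_s` and preferred turn angle `θ_s`.
Both resist bending through the angular spring `E = Σ_v (K/2)(θ_v − θ0)²`
in the signed turn (exterior) angle; closed chains sum over all `N`
vertices, open chains over the `N − 2` interior ones.  Bond inextensibility
is approximated by stiff harmonic springs (`k_bond = 2000` energy/length²;
max strain < 1% in all accepted runs).

The node-count ratio `N_m/N_s = 10` reflects the size ratio between coat
subunits and lipid spacing, so the coat bond is `b_s = 10 b` and the coat
arc spans ~90% of the membrane perimeter.  Each coat node is then a
point-like adhesion pin — a coat node binds whatever membrane lies within
the cutoff, which makes its binding energy insensitive to local curvature.
(Prototypes with `b_s = b` cannot bud at all: a short dense coat loses a
large fraction of its adhesion when it curls, so strong adhesion irons it
flat, and a 10-node unit-bond coat closes into a circle too small to hold
membrane.)

Interactions:

* **Adhesion**: truncated-and-shifted 12-6 Lennard-Jones, depth `ε_LJ`,
  `σ = b`, `r_cut = 2.5σ`, node-to-node between membrane nodes and the
  *inner* coat nodes.
* **Rim caps**: the terminal node at each coat end is purely repulsive
  (WCA, `σ_cap = 1.2`).  The membrane binds the coat's membrane-proximal
  face; with fully symmetric adhesion the membrane otherwise curls around
  the coat ends to reach the outer face, an artifact this removes.
* **Membrane self-exclusion**: WCA between non-bonded membrane nodes
  (`σ_ev = 0.9 b`, `ε_ev = 1`), so the chain cannot self-cross at the neck.

### Budding protocol

From a pseudo-circular equilibrium (regular membrane polygon; coat arc one
LJ-minimum distance outside it, preferred angle set to its resting geometry;
FIRE-quenched so every node force < 10⁻⁶), `θ_s` is ramped linearly to
`1.05 × 2π/(N_s − 2)` — slightly past ring closure — over 10⁵ steps and held
for 6×10⁵ steps.  The coat tightens into a ring; membrane in excess of the
ring's capacity extrudes through the coat opening and pinches off behind a
neck.  Dynamics: velocity Verlet with per-node viscous drag `−γv`
(`γ = 0.3`; with `γ = 0` the integrator is symplectic and conserves energy,
which tests verify to < 10⁻⁴ over 10⁵ steps — the pairwise terms run over
Verlet neighbour lists, skin 0.5, rebuilt on half-skin displacement, which
is exact by construction).  `dt` defaults to the stability bound of the
stiffest (bond) mode, `0.25/√(2 k_bond)`.  The dynamics is deterministic;
randomness enters only through a 10⁻⁸ initialization jitter.

The long hold matters: neck closure is a slow collective motion, and half
the hold leaves necks visibly open.

### Outcome classification

From the final configuration:

* **detached** — adhesive binding energy `|E_adh| < 1` (model units, with
  `K_s = 1`): the interface is mechanically irrelevant.  A geometric
  contact count cannot express this at zero temperature, because a released
  coat has nothing to push it away and *rests* on the membrane (measured:
  contact fraction stays 1.0 at `ε_LJ = 0.02`, where binding is 0.5% of the
  elastic scale).
* **vesicle** — the membrane wraps ≥ 300° of the circle fitted to the coat
  contact patch *and* the neck gap is ≤ 1.5σ.  The neck gap is the closest
  approach between membrane nodes at least 12 apart along the ring — a
  global pinch measure that is robust to fragmented contact sets.
* **stable_no_vesicle** — bound interface without a closed bud.

Runs with non-finite coordinates or bond strain > 5% are flagged `failed`
and withheld from classification.

### Phase diagram

Default grid: `K_m/K_s ∈ {0.3, 0.7, 1.5, 4, 10}` ×
`ε_LJ/K_s ∈ {0.03, 0.15, 0.7, 1.7, 3}` at `N_m = 100` (reduced size;
`N_m = 200` behaves the same but four times slower).  The observed topology:
detached at the weakest adhesion for every stiffness; vesicles in the
soft-membrane/strong-adhesion corner; a bound-but-unproductive interface for
stiff membranes; one vesicle→no-vesicle crossing per adhesion column.

Limitations: at `K_m/K_s ≲ 0.2` together with `ε_LJ/K_s ≳ 3` the excess
membrane invaginates into the coated body instead of extruding (a
zero-temperature metastability), so the default grid starts at 0.3.  There
is no thermal noise, no hydrodynamics, no 3D curvature energy, and the
"vesicle" is a 2D cross-section; scission itself (bond fission at the neck)
is outside the model.

## 3. Spot quantification (`serpintraffic.spots`)

Pipeline per image pair:

1. **Noise threshold** — Otsu's between-class-variance maximizer when it
   genuinely separates two populations (separability η ≥ 0.8); on
   effectively unimodal histograms — sparse bright puncta over a flat
   background, where Otsu is known to split the noise bulk instead — a
   robust noise floor, median + 4.5 MAD-σ.  Pixels below the threshold are
   zeroed.  (The 4.5 keeps the expected count of surviving noise pixels
   ≪ 1 in a megapixel image; surviving outliers would otherwise become
   wavelet impulses against the zeroed background.)
2. **Detection** — à-trous (undecimated) B3-spline wavelet decomposition;
   detection on plane 2 only (the "scale = 2" setting).  Significant
   coefficients exceed `(threshold/100) · 3 · σ̂_w`, with `σ̂_w` the robust
   MAD estimate of the plane's noise computed on the *raw* image's plane
   (on the thresholded copy the MAD collapses to zero), so the conventional
   `threshold = 100` is the standard 3σ cut.  Significant pixels are
   grouped by 8-connectivity; centroids are intensity-weighted.
3. **Size filter** — keep spots with area strictly greater than 3 px.
4. **Nuclei** — Otsu, hole filling, distance-transform watershed with
   seed maxima at least 10 px apart, components ≥ 50 px counted.
5. **Ratio** — spots / nuclei over the whole image (no per-cell
   assignment), undefined when no nuclei are found.

Statistics between conditions use the two-sample KS test
(`scipy.stats.ks_2samp` behind `ks_two_sample`; exact method for
`n_a·n_b ≤ 10⁴`, asymptotic otherwise), validated in tests against a direct
ECDF computation and a full permutation enumeration on small samples, and
calibrated to a type-I error of 0.05 ± 0.02 over 2000 null replicates.

## 4. Synthetic data (`serpintraffic.synthetic`)

PLA-like pairs: nuclei are smooth near-elliptical blobs (semi-axes 8–12 px,
axis ratio ≥ 0.85, sigmoid edges) placed without overlap; spots are Gaussian
puncta (`σ = 2` px by default) confined to cytoplasmic disks around nuclei,
pairwise ≥ 4σ apart and ≥ 3σ from the border so centroid tests are clean.
Photon model: Poisson shot noise on (signal + background of 200 counts)
plus Gaussian read noise (SD 3); the planted amplitude is solved from the
requested peak SNR = amplitude / noise-SD-at-peak.  Output is 16-bit TIFF
plus CSV/JSON ground truth; generation is bit-reproducible per seed.

What this does *not* emulate: autofluorescent cytoplasm texture, uneven
illumination, out-of-focus light and 3D PSFs, spot brightness heterogeneity,
or clustered (non-resolvable) PLA signals.  Passing recovery tests on these
images therefore demonstrates correctness of the detector's logic, not
performance on difficult real micrographs.

## 5. Orchestration

A top-level seed fans out to per-stage and per-replicate seeds through
`numpy.random.SeedSequence` tuples, every output file is checksummed into
`manifest.json`, and reruns with the same config and seed reproduce
identical checksums for deterministic stages.  Unknown config sections or
keys are errors naming the offending entry.
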