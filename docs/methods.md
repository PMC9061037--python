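# Methods

`nanodamage` predicts the yield and complexity of radiation-induced DNA
damage across scales: nucleotide-resolution target geometries, a stochastic
energy-deposition and radical-chemistry surrogate, direct/indirect damage
induction, clustering into a seven-way double-strand-break (DSB) taxonomy,
whole-nucleus yields, analytic dose/LET correlations, and voxel-wise RBE
maps for proton versus photon beams.  This note records the model, its
assumptions, the calibrated parameters and the known limitations.

## DNA target geometries

Three volumetric models of B-DNA represent each backbone and base as one
discrete volume carrying a 1-based genome index:

* **sphere** — backbone spheres of radius 0.240 nm, base spheres of
  0.208 nm, centred inside a 1.15 nm helix envelope;
* **quarter_cylinder** — central base half-cylinders (r = 0.5 nm) and
  backbone annular quarter-sectors out to r = 1.15 nm, 0.34 nm thick;
* **half_cylinder** — as above with half-sector backbones, so the full
  annulus is sensitive.

All models use a 0.34 nm rise and a 36° twist per base pair (10 bp/turn),
place paired volumes directly opposite (no major/minor groove) and carry a
material density of 1.407 g cm⁻³.  Point-in-volume tests are analytic per
shape in the local helix frame, accelerated by a KD-tree over the per-bp
axis points; where volumes of adjacent base pairs touch, the nearer axis
point claims the point.

Composite targets:

* **pBR322 plasmid** — 4361 bp on a closed circle (radius ≈ 236 nm) lying
  in the coverslip plane, surrounded by a 2.4 nm water torus.  Base-pair
  separation is the shortest arc.
* **solenoid chromatin fibre** — 102 histone cylinders (r = 3.3 nm,
  h = 5.7 nm), 6 nucleosomes per turn on a 12.5 nm solenoid radius,
  198 nm long, 37 nm across, inside a 203 nm × 42 nm water envelope.
  Each histone is wrapped by 1.65 superhelical DNA turns.  The wrapped
  versus linker split is not uniquely determined by the stated totals; we
  use 120 bp wrapped per histone and 60 bp per linker (101 linkers), which
  reproduces the 18 300 bp total exactly: 102·120 + 101·60 = 18 300.  Both
  are constructor arguments.  Linker paths are straight segments between
  wrap endpoints; when the contour length exceeds the gap the per-bp
  spacing is compressed (a geometric idealisation — the linker path is not
  resolved), and a linker too short to span the gap at 0.34 nm/bp raises a
  configuration error.  A 3.5 nm axial margin keeps end-nucleosome wraps
  inside the envelope caps.

## Track-structure surrogate

The package does not transport particles with real cross-sections.  It
reproduces the *output contract* of an event-by-event track-structure code:
point energy deposits `(x, y, z, energy, ionisation flag, track id)` and OH
radical trajectories.  Externally produced event lists can be injected
through the same tabular interface, replacing the surrogate entirely.

Deposits are generated as **spurs**: interaction sites are Poisson along
the path with linear density `LET / mean_site_energy` (1 keV/µm ≡ 1 eV/nm),
each site carrying `1 + Poisson(µ)` point deposits spread with a 1 nm
Gaussian, site energies exponential.  Sites are displaced off the track
axis by an exponential penumbra law (mean 2 nm).  Defaults:

| parameter | default | meaning |
|---|---|---|
| `mean_site_energy_ev` | 40 | mean energy per spur (eV) |
| `spur_extra_deposits` | 1.5 | Poisson mean of extra deposits per spur |
| `spur_sigma_nm` | 1.0 | spur spatial spread (nm) |
| `ionisation_fraction` | 0.8 | deposits flagged as ionisations |
| `penumbra_mean_nm` | 2.0 | radial displacement scale (nm) |

The spur structure is the standard picture of energy-loss clustering in
radiation chemistry and is what allows the nucleus model's acceptance
fraction (below) to calibrate to a physically sensible value.

The photon reference beam ("co60") is an electron with LET_t = 0.2 keV/µm
whose primary energy is drawn from a Compton (Klein–Nishina) electron
spectrum of the 1.17/1.33 MeV lines at equal intensity, computed at run
time; its support ends at the 1.33 MeV line's Compton edge (≈ 1.118 MeV).

**OH chemistry.**  Radicals spawn at ionisation sites with a G-value of
2.5 per 100 eV (configurable; jittered ≤ 0.5 nm from the parent deposit)
and random-walk with per-axis step variance `2·D·dt`
(D = 2.8×10⁻⁹ m² s⁻¹, dt = 1 ps) for at most 1 ns.  A trajectory ends at
the first step endpoint inside a histone (scavenged, no damage) or inside
any DNA volume (reaction — damage decided by the indirect model), else at
the time limit.  Diffusion constants, time step and G-value are surrogate
choices (a real track-structure code supplies its own chemistry); all are
configurable.  Radical–radical reactions are represented only implicitly by
the finite tracking window — only OH–DNA outcomes affect damage scoring.

## Damage induction

**Direct.**  Deposits inside DNA volumes are summed per primary lineage and
per volume.  Three conversion models:

* `energy_range` (default): damage probability 0 below 5 eV, 1 at
  37.5 eV, linear between;
* `threshold`: damaged iff the sum strictly exceeds 17.5 eV;
* `ionisation`: damaged iff ≥ 1 ionisation occurred in the volume.

**Indirect.**  Every radical reaching a DNA volume reacts there and is
consumed.  With probability `P_Ind` (backbones) or 0.8 (bases) the reaction
records damage; otherwise it is a reaction without damage.  `P_Ind` is not
a free choice: it is calibrated by bisection so that the Co-60 reference
produces a 35:65 direct:indirect split of backbone damage (see below).

A volume is damaged at most once per exposure; when both stages hit the
same volume the direct record wins (the physical stage precedes the
chemical one).

## Clustering and the seven-way taxonomy

Damaged backbones on opposite strands separated by ≤ 10 bp (shortest arc on
circles) join transitively into one cluster; a chain spanning more than
10 bp is still a single DSB.  Damaged bases within ≤ 3 bp of a converged
cluster's extremities attach to it (nearest extremity, lower bp on ties); a
base on the same nucleotide as a damaged backbone is dropped before
clustering (removed with the backbone during repair).  Remaining isolated
backbones pair greedily with the nearest opposite-strand isolated base
within 10 bp to form *potential* DSBs, which are never promoted to real
DSBs.  Categories: isolated base, isolated backbone (SSB), potential DSB,
simple DSB (2 backbones), simple DSB + base, complex DSB (≥ 3 backbones),
complex DSB + base.  Yields are reported per Mbp or Gbp per Gy, with a
650 Da/bp conversion available for per-mass literature comparisons.

## The two assays

**Plasmid.**  Dry pBR322 on a coverslip, protons perpendicular, direct
damage only.  Dose is set through fluence: Φ = D·ρ/L (1 keV/µm =
1.602×10⁻¹⁰ J/m) and the disc radius R = √(N/πΦ) with N = 5000 primaries
and D = 2000 Gy by default (R ≈ 0.952 µm at 10 keV/µm).  Primaries too far
from the DNA ring to reach any volume are skipped analytically; events are
generated in a thin axial window around the plasmid plane, which is the
only region where deposits can intersect DNA.  A coverslip backscatter
surrogate (mirroring a configurable fraction of events at the slab plane)
is off by default.

**Chromatin fibre.**  One primary per exposure starts on the envelope
surface with an inward random direction; direct + indirect damage are
clustered per primary.  Outputs: DSB-category probabilities, the indirect
backbone-damage fraction, per-primary complexity samples (category,
backbone and base multiplicities, isolated-damage types) that feed the
cell model's library.

**P_Ind calibration.**  The physics/chemistry realisation is simulated
once; for candidate `p` the expected indirect backbone count is
Σ_v (1−(1−p)^k_v) over backbone volumes with k_v radical reactions (volumes
already broken directly are excluded), giving a smooth strictly monotone
objective for bisection against the 0.65 target.  Under the surrogate
defaults the calibrated `P_Ind` is ≈ 0.2–0.3 (a code with real
cross-sections arrives at a different balance of direct deposits versus
radical flux, hence a different `P_Ind`; the anchored quantity is the 0.65
fraction, which is reproduced to ± 0.01).  The acceptance runs use a
bisection tolerance of 0.008 so the guaranteed band around 0.65 lies inside
the ± 0.01 band around the reported 0.648.

## Whole-nucleus model

A spherical nucleus (r = 2.5 µm, unit-density water; the 1.407 g cm⁻³
applies to DNA volumes, not bulk nucleus) inside a 5 µm half-length
cytoplasm box receives dose via uniform random chords (two uniform surface
points).  Tracks are added until the delivered energy over the nucleus mass
reaches the dose; the last track is truncated deposit-by-deposit so the
delivered dose lands within 1 % even at high LET where one track carries a
large energy share.  A fraction `acceptance_fraction` of deposits is
accepted; accepted deposits become strand breaks with the linear
5–37.5 eV probability and a fair-coin strand label.

**Acceptance calibration.**  The acceptance fraction was bisected once so
that the proton run at the photon-equivalent LET (0.2 keV/µm) yields
4.2 DSB/Gbp/Gy, the literature photon rate that also anchors the photon
cell model — making the model continuous at the reference LET.  Under the
spur surrogate this lands at **0.151**, the packaged default.

Breaks cluster with a modified DBSCAN: pair linkage requires opposite
strands within 3.4 nm (the spatial equivalent of 10 bp), chains merge
transitively; clusters are DSBs, singletons SSBs.  Nucleotide-level detail
(category, multiplicities) is then drawn from the chromatin-fibre library
at the nearest LET bin; isolated breaks draw isolated-backbone /
isolated-base / potential-DSB labels at the library frequencies.  A library
key backed by fewer than 20 DSB samples warns that draws will be noisy.

**Photon cell.**  DSB counts are Poisson with mean 4.2 × 6 Gbp × dose,
positions uniform in the nucleus, SSBs from a uniform draw on the 25–40
SSB:DSB interval, complexity from the Co-60 library.

## Yield correlations and mapping

Per category, per-cell yields (6 Gbp) follow `Yield(D, L) = D·(a·L² + b·L
+ c)`.  Because the model is exactly linear in dose, fitting regresses
yield/D on L (ordinary or 1/σ² weighted least squares; asymptotic standard
errors from the covariance).  A versioned reference parameter set is
packaged (`data/reference_correlations.json`) and is the default for the
clinical mapper, so mapping needs no simulation.  Summing the four category
constants at D = 1 Gy, L → 0 and dividing by 6 Gbp gives 4.2 DSB/Gbp/Gy.

The mapper applies the correlations voxel-wise to co-registered dose and
track-averaged LET grids (MetaImage I/O, CSV fallback; LET is taken as
given — no dose-averaged conversion) and forms RBE maps against the photon
reference, by default the same correlations at L = 0.2 keV/µm so RBE ≡ 1
at the reference LET; any callable photon reference can be plugged in.
Voxels with zero photon yield are masked, as are voxels below a display
threshold (default 10 % of maximum dose).  Synthetic fixtures (a 1-D
pseudo-SOBP with rising LET and a 3-field-like phantom) support tests.

## Problem sizes

Simulated sample sizes are chosen to resolve each quantity, not to match
the original study's scale: fibre exposures use 10³–10⁴ primaries per
setting (calibration 2–3×10⁴ pooled), the plasmid assay tens of repeats of
the 5000-primary exposure, the photon cell 2500 exposures, nucleus runs
5–60 repeats.  Standard errors are reported alongside means throughout.

## What the surrogate does and does not show

Passing tests demonstrate the *mechanistic chain* — geometry, clustering
rules, calibration procedures, normalisations, trends — under a generator
that emulates track structure statistically.  They do not validate absolute
damage magnitudes that depend on real interaction cross-sections: plasmid
yield magnitudes, absolute fibre DSB probabilities per LET, and
patient-plan RBE values are covered by qualitative substitutes (sphere
model underestimates the cylinder models; DSB yield per primary is
non-decreasing in LET; indirect effects are the majority of backbone damage
across LET and enrich complex DSBs; RBE_complex rises monotonically along a
pseudo-SOBP).  Other known limitations: no DNA adducts or non-break
chemistry, no repair or time-dependent potential-DSB conversion, no
heterochromatin variants, a single radical species, and a straight-line
linker idealisation in the fibre.
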