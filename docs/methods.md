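# Methods

## The measurement model

The package treats a native-MS titration as a four-stage measurement:

**Ion positions.** A neutral species of average mass *M* observed with *X*
adducts of mass *m*ₐ at charge *z* appears at

    m/z = (M + X·mₐ + z·mₚ) / z

with the proton mass *m*ₚ = 1.00728 Da as the charging mass. Average (not
monoisotopic) masses are used throughout: the instruments this targets do not
resolve isotopes on a 13.7 kDa protein. The H-atom convention
(1.00794 Da) differs by < 0.01 Th at z ≥ 7 and is invisible at the 1-decimal
reporting precision; both conventions are accepted by the ladder functions.

Two reference masses for RNase A are carried as separate constants:
`RNASE_A_MASS` (13,681.29 Da, implied by the singly protonated reference
value 13,682.3 used to build the published ladders) and `RNASE_A_MASS_1RTA`
(13,690.3 Da, computed from the PDB 1RTA sequence). They disagree by ~9 Da
and the source material does not reconcile them; the ladder fixture uses the
former because it is what reproduces the reference ladder and windows. One
row of the published dC₅-bound ladder (z = 5) sits exactly 0.1 above what
either charging-mass convention yields; tests therefore hold bound-species
cells to ±0.1 and free-protein cells exactly.

**Integration windows.** A window spans a species' adduct series at one
charge state, padded by `half_width` = 0.5 Th beyond the extreme ladder
positions (the value implied by the published ranges), closed at both ends.
`detect_window_overlap` flags pairwise intersections and scan-range escapes;
`max_safe_adducts` grows the adduct range until a conflict appears — this is
the mechanism behind the X ≤ 5 restraint: with X = 6 the bound +8 window
would cross the 1950 Th scan cap toward the free-protein +7 series starting
at 1955.5.

**Total ion abundance.** All scans of an acquisition are averaged point-wise
(profile data on a shared grid; centroids may be pooled and binned with an
explicit bin width), and intensities are summed inside each window. Both
window boundaries are inclusive. No baseline subtraction or smoothing is
applied by default, matching how the reference abundance tables were
produced.

**The ratio estimator.** R = Ab(PL)/Ab(P) is taken as [PL]eq/[P]eq, giving

    Ka = R / ([L]₀ − (R/(1+R))·[P]₀),    Kd = 1/Ka

Algebraically, (R/(1+R))·[P]₀ is the implied [PL]eq and the denominator the
implied free ligand; when measured abundances are proportional to solution
concentrations this inverts the 1:1 mass-action equilibrium exactly (this is
property-tested to machine precision). Ka ≤ 0 occurs iff
[L]₀ < (R/(1+R))·[P]₀ and is reported verbatim with `valid=False` — masking
it would hide the main diagnostic of response bias, lost charge states, or
nonspecific binding. Internal units are molar everywhere; µM appears only in
the reporting layer, where R is rounded to 2 decimals and Kd (µM) to 1
decimal, half-up.

**Replicate statistics.** Sample standard deviation (n−1) and
%RSD = 100·SD/mean. The per-concentration Kd is the mean of per-replicate Kd
values, not a fit to pooled abundances; the quoted ±0.1 µM spread at 40 µM is
the replicate SD under this reading. No global multi-concentration fit is
attempted — the estimator is defined per titration point.

## The synthetic-data generator

`SimulationConfig` defaults encode the study design: [P]₀ = 40.9 µM in every
sample; ligand at 0/5/10/20/40 µM with 6 replicates of the blank and 3 of
each titration point; Kd = 2.2 µM; dC₅ (1383.9 Da) on RNase A; acquisition
grid m/z 1500–1950 so that only the +8 charge state of free and bound
protein is observable.

Per sample: the 1:1 equilibrium is solved in closed form (smaller root of
the binding quadratic, guarded against float overshoot at the stoichiometric
limit; residual |PL·Kd − P·L| < 10⁻¹²·P₀ is asserted by tests). Each species'
signal is spread over a truncated-geometric adduct distribution
(`adduct_decay` = 0.45 over X = 0..8, chosen to mimic the monotone decline of
adduct intensity seen on intact-protein spectra while leaving visible
intensity at X = 5) and a charge-weight map (default all mass at +8). Every
ion is a Gaussian of `peak_sigma` = 1.5 Th — a realistic ion-trap peak width
for a +8 protein ion — with area proportional to concentration × response ×
charge weight × adduct weight; `counts_per_molar` = 1.8 × 10¹² scales summed
window counts to the magnitude of the reference data (~7 × 10⁷ for 40.9 µM
free protein).

**Noise.** Replicate-to-replicate scatter in infusion ESI is dominated by
spray/transmission drift that moves the whole spectrum together — in the
reference data the free and bound abundances co-vary strongly within a
replicate. `noise_cv` (default 0.15, matching the ~≤20 % RSD regime of the
reference tables) is therefore applied as one log-normal factor per
replicate shared by all species and scans, plus independent per-point
log-normal shot noise with the same CV. Consequence: abundance %RSD ≈
noise_cv, while R (a within-spectrum ratio) stays nearly noise-free — which
is also why per-concentration Kd recovery from 3 noisy replicates lands well
within 25 % at the highest ligand concentration.

**Failure-mode switches.**

* `response_bias` ρ — the complex ionizes/transmits ρ× the free protein, so
  measured R = ρ·R_true. Apparent Ka goes negative exactly when
  ρ·R/(1+ρ·R)·[P]₀ > [L]₀ (property-tested against brute force). ρ = 3 at
  [L]₀ = 5 µM reproduces the negative-Kd artifact.
* `charge_weights` / `charge_weights_bound` — mass assigned to +7/+6 falls
  outside the 1500–1950 grid and is simply lost; a bound-specific map
  emulates charge-state redistribution of the complex.
* `nonspecific_kd` — a weak second site (sequential P+L⇌PL, PL+L⇌PL2 solved
  by bracketed root-finding on free ligand) converts PL into PL2, whose ions
  fall outside the bound window: bound abundance dips at the top
  concentration (hook effect).

No claim is made about which mechanism operated in the reference experiment;
the switches exist to reproduce each artifact class qualitatively.

**What the generator does not emulate:** ESI droplet physics, isotope
structure, detector saturation, space-charge effects, m/z-dependent
transmission, or scan-to-scan drift within an acquisition. Passing recovery
tests therefore show the analysis chain is self-consistent and unbiased
under the stated noise model — not that real spectra satisfy R = [PL]/[P].

## Numerical choices

* **Grid commensurability.** The default simulation grid step is 0.0125 Th.
  Both ligand masses shift the +8 ladder by an exact multiple of this step
  (1383.9/8 = 172.9875 = 13839 × 0.0125; 1408.0/8 = 176.0), so the free and
  bound windows sample their peak ladders with identical phase: edge
  truncation at the ±0.5 Th pads cancels exactly in the ratio, and the
  noise-free pipeline returns Kd_true to ~10⁻¹³ relative. A step that broke
  this commensurability would still recover Kd to ~10⁻³ (edge-phase error),
  which is why the step is part of the design rather than a free knob.
* **Rounding** is half-up at display only (`_rounding.round_half_up`);
  full precision is carried internally. Banker's rounding would flip several
  reported 1-decimal cells.
* **mzML support** is a deliberately compact reader/writer pair (stdlib XML,
  base64/zlib, 32/64-bit float arrays, accession-driven) covering the MS1
  profile/centroid subset this package produces and consumes; it
  round-trips bit-exactly within float tolerance and is property-tested.
* **Degenerate inputs.** Empty adduct ranges and zero-width windows raise;
  a window with no spectrum points warns and returns 0; blank (L₀ = 0)
  samples are excluded from Ka fitting and logged, since the estimator is
  undefined there; an exactly zero Ka denominator raises rather than
  returning ±inf.
* **Problem sizes.** Tests and the acceptance script run the simulator at
  its default design (18 samples, ≤5 scans each, 36,001-point grid) or
  smaller slices; statistics that need tight sampling distributions (the
  %RSD band check) use 30 replicates of a single titration point instead of
  inflating the whole design.

## Known limitations

* Single-charge-state analysis: the estimator sums only ions inside the
  acquired window; abundance in unobserved charge states biases R, which is
  precisely the artifact the simulator's leakage switch demonstrates. A
  multi-charge-state R is out of scope because the reference acquisition
  could not observe +7/+6 for the bound species.
* Replicate SD is the only uncertainty propagated; no error model on the
  abundances themselves.
* The two reference protein masses (ladder-implied vs sequence-derived)
  remain unreconciled by design.
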