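# Methods

## Model

### Pair potentials

`chbe.potential` evaluates the 12-6 and 12-6-4 Lennard-Jones + Coulomb
pair energies analytically. Internal energy units are kcal/mol (the unit
in which C_ij coefficients are tabulated); binding free energies are
kJ/mol (the unit in which chelator affinities are reported), with
explicit converters (`kcal_to_kj`, factor 4.184). The Coulomb prefactor is
the AMBER-convention e² value, 332.0522 kcal mol⁻¹ Å e⁻². Per-atom-type
parameters combine by Lorentz–Berthelot rules (geometric-mean ε, summed
r_min/2); the pairwise C_ij is never combined — it is looked up in a
per-pair override table, since pair specificity is the entire point of the
parameterization. The module applies no cutoff or switching function: it
is an analytic evaluator, and the toy sampler applies minimum-image
truncation itself.

### Affinity conversion and cycles

Experimental stability constants convert as ΔG = −RT ln K₁ and
dissociation constants as ΔG = +RT ln K_d (R = 8.31446×10⁻³
kJ mol⁻¹ K⁻¹, default T = 298 K), so "more negative = tighter" throughout.
Which sign a dataset's log K_d column carries is a perennial source of
confusion, so the conversion is driven by an explicit `ConstantKind` and
the thermodynamic-cycle orientation by an explicit `CycleSign`. Replicated
electrostatic+polarization legs combine as mean ± sample SD (n−1; zero for
a single replicate); a fixed −ΔG_VdW = 9 kJ/mol preset is provided for
workflows that hold the small, nearly constant van-der-Waals leg fixed
across related complexes.

### The C_ij solve

For the reference chelator the linear response model is

    ΔG_sim(C_O, C_N) = ΔG′(0,0) + m(O)·C_O + m(N)·C_N,

with gradients fitted by OLS with a free intercept (a default-anchored
variant exists behind the `anchor` argument for sensitivity checks).
ΔG′(0,0) is back-extrapolated from the default-parameter energy and
carried at full precision: rounding it to one decimal moves the solved
Y³⁺ C_N by ~1.5%, which is why the pipeline is strict about unrounded
intermediates. The second chelator enters through two ratios only: its
experimental-to-reference binding-energy ratio (scales ΔG′(0,0)) and its
denticity ratios ρ_O, ρ_N (scale the gradients; defaults 3/4 and 1/2 for
NTA against EDTA, configurable per chelator pair). The 2×2 system

    ΔG_exp,ref  = z + m_O·C_O + m_N·C_N
    ΔG_exp,oth  = z·(ΔG_exp,oth/ΔG_exp,ref) + ρ_O·m_O·C_O + ρ_N·m_N·C_N

is solved exactly; its determinant m_O·m_N·(ρ_N − ρ_O) is reported as a
diagnostic, and |det| < 10⁻¹⁰ raises a singular-system error rather than
falling back to a pseudo-inverse (equal ratios make the rows
proportional). Negative solutions are returned flagged `physical=False`,
not raised: they are the signal that the inputs cannot support the linear
model — exactly what happens when the second chelator's own gradients and
zero references are used directly (`solve_cij_direct`), which reproduces
the motivation for the ratio-based scheme. An over-determined ≥3-chelator
least-squares extension (`solve_cij_lstsq`) is provided and explicitly
labelled as an extrapolation beyond the exactly determined two-chelator
scheme.

## RDF analysis

g(r) is histogrammed at 0.01 Å resolution (configurable) into half-open
bins [r, r+dr) reported at bin centers, normalized by exact
spherical-shell volumes (4/3)π(r₂³−r₁³) — identical to 4πr²dr to second
order in dr/r but unbiased in the innermost bins — the bulk density, and
the frame count. Periodic frames use the minimum-image convention and
require r_max ≤ L/2 with ρ = N/V; open-boundary frames estimate ρ from
the outer 10% of the r_max sphere, falling back to the whole-sphere mean
when that shell is empty (as for an isolated solvation shell). The choice
of ρ cannot bias the coordination number: CN integrates 4πρr²g(r) with
the same shell volumes used in normalization, so ρ cancels and CN equals
the mean per-frame count inside the first minimum.

Feature detection is deliberately separated from quantification:

- **First peak** — first local maximum (5-bin window, window shrinking at
  the ends) of a 5-bin moving-average copy of g exceeding 1.5, searched
  from r = 0.5 Å outward. The threshold sits midway between the bulk
  level (1) and typical first-shell peak heights (≥2): a threshold at the
  bulk level would fire on any upward counting fluctuation of a
  structureless curve, and the sub-0.5-Å region is excluded because no
  ion–ligand pair approaches that closely while its near-zero shell
  volumes let single counts explode g(r). The IOD is then the vertex of a
  least-squares parabola fitted to the *raw* bins within ±0.1 Å of the
  peak bin, falling back to the raw bin center if the fit opens upward.
- **First minimum** — first local minimum of the smoothed copy after the
  peak, excluding the final window (the curve boundary is not a minimum),
  ties broken toward smaller r. A minimum is *clear* if its smoothed
  value falls below half the smoothed peak height; otherwise the result
  is flagged (`minimum_clear=False`) and a CN range over all candidate
  minima is reported, mirroring how shell boundaries blur when binding
  modes interconvert. Integration always uses the raw curve; smoothing is
  detection-only. A curve with no detectable peak raises `NoPeakError`;
  the CLI surfaces it as a flagged report, not a failure.

Known limitation: on sparsely sampled trajectories (expected counts of
order 1 per bin at the peak region) the threshold detector can still fire
on noise; the cure is sampling, not tuning — the toolkit's own fixtures
use hundreds of frames.

## Toy sampler

`chbe.sampler` is a single-particle Metropolis Monte-Carlo sampler: one
ion plus n identical solvent sites in a cubic periodic box, ion–site
pairs on the 12-6-4 potential, site–site pairs on 12-6 + Coulomb, all
under minimum-image truncation (no Ewald — at desk scale only the
equilibrium ensemble matters, and the anchor tests compare against exact
Boltzmann quadrature of the same truncated potential). Moves displace one
uniformly chosen particle by a uniform perturbation in [−s, s]³; zero-ΔE
moves are always accepted, so a fully non-interacting system has
acceptance exactly 1. Energies are tracked incrementally and verified
against fresh totals in the tests. All randomness flows through one
`numpy.random.default_rng(seed)`; identical seeds give bitwise-identical
traces. Initial placement rejects positions whose interaction energy
exceeds 10⁴ kcal/mol, with a 2000-attempt budget per site before raising.

The default solvent site is TIP3P-oxygen-like (r_min/2 = 1.768 Å,
ε = 0.152 kcal/mol, charge −0.834 e with an implicit neutralizing
background) — a fixture convention, not a physics claim. What the sampler
emulates is the *statistics* a real solvated-ion trajectory feeds into
RDF analysis: shell structure, counting noise, frame correlation. What it
does not emulate: water–water hydrogen bonding, polarization, long-range
electrostatics, dynamics, or chelator geometry — so passing the RDF and
sampler tests validates the analysis chain, not any simulation protocol.

`make_shell_fixture` bypasses sampling entirely: sites uniform on a
sphere with Gaussian radial jitter give frames whose ground-truth IOD
(the radius) and CN (the site count) are known by construction.

## Test and anchor design

- Statistical checks ("within 3 Monte-Carlo standard errors") are applied
  where the normal approximation to the counting noise holds: for the
  fine-binned ideal-gas curve, bins with expected count ≥ 10 must have
  ≥ 99% of |z| ≤ 3 (the Gaussian rate is 99.73%), no |z| ≥ 5, and reduced
  χ² within 3σ of 1; a literal all-bins assertion over ~400 bins would
  fail by chance most of the time at any sample size. The 2-body MC
  histogram uses 22 coarse (0.2 Å) bins with large counts and is held to
  a strict max |z| ≤ 3 against quadrature of r²e^(−βu).
- The solver's brute-force oracle scans C_O, C_N ∈ [0, 300] at 0.05
  resolution. Where m(N) is small the squared-residual surface is a
  near-degenerate valley and the grid argmin can sit a couple of cells
  away *along the valley*; equivalence is therefore asserted as: C_O
  within one cell, and both system-row residuals at the grid argmin
  within one cell's worth, |A|·(0.05, 0.05).
- The c4-monotonicity anchor runs the 2-body system at three c4 values
  (50, 150, 300 kcal mol⁻¹ Å⁴; 120k steps, saved every 10): increasing
  the r⁻⁴ attraction must never lengthen the sampled IOD nor deplete the
  first shell. A 12-site bath shows the same trend but its first minimum
  is too noisy at desk-scale sampling for a strict per-run assertion.
- Problem sizes throughout (≤ 500 frames, ≤ 150k MC steps, ≤ 250 gas
  sites) are chosen so the whole suite runs in about a minute on one
  core while keeping every statistical band at least ~3σ wide.

## Reference data

The packaged CSVs (`chbe/data/`) carry the published EDTA/NTA chelator
summary — experimental and simulated binding energies, fitted gradients —
and the default and chelator-derived C_ij coefficients for Ca²⁺, Mg²⁺,
Y³⁺ and La³⁺. Published inputs are printed at one decimal (energies) and
three decimals (gradients); propagating those roundings through the
pipeline moves the solved coefficients by up to ~1.5% and the
back-extrapolated references by up to ~0.06 kJ/mol, which is the
tolerance context for any comparison against the published tables.
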