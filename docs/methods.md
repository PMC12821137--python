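# Methods

## Model

The package implements two segment-activity-coefficient models on binned
sigma-profiles.

**COSMO-SAC (2002).** The liquid is treated as an ensemble of pairwise
interacting surface segments. For compound *i* with cavity area *A*ᵢ (Å²)
and volume *V*ᵢ (Å³),

- nᵢ = Aᵢ/a_eff independent segments, a_eff = π r_eff²;
- residual part nᵢ Σₘ pᵢ(σₘ)[ln Γ_S(σₘ) − ln Γᵢ(σₘ)], with Γ the
  self-consistent segment activity coefficients of the mixture (S) and of
  the pure liquid *i*, both at the mixture temperature;
- combinatorial part: Staverman–Guggenheim with rᵢ = Vᵢ/r₀, qᵢ = Aᵢ/q₀,
  coordination number z = 10.

The segment exchange energy is

ΔW(σₘ,σₙ) = (α′/2)(σₘ+σₙ)² + c_hb·max(0, σ_acc − σ_HB)·min(0, σ_don + σ_HB)

with σ_acc = max(σₘ,σₙ), σ_don = min(σₘ,σₙ) and
α′ = f_pol·0.3·a_eff^{3/2}/ε₀. The misfit part is a non-negative penalty
for imperfectly complementary segments; the hydrogen-bond part is an
attraction active only when the positive density exceeds the cutoff σ_HB
and the negative density lies below −σ_HB.

**COSMO-SAC-HB2.** Segments additionally carry a hydrogen-bond class
(water/hydroxyl/amine donors; water/hydroxyl/nitrogen/other acceptors),
the sigma-profile is split per class, and c_hb is looked up per
donor-class–acceptor-class pair from a table of eight constants. Pairs
that are not a donor against an acceptor get no hydrogen-bond term. The
shipped pair→constant mapping gives water and hydroxyl donors/acceptors
dedicated constants and lets nitrogen and other (ether/carbonyl) acceptors
share one constant per donor type; the mapping is configuration-driven
(`hb_pair_map`), since different parameter releases group the pairs
differently, and any user table can replace it. The misfit term is applied
to hydrogen-bonded pairs as well by default (`hb_misfit=True`), with a
flag to disable it because published implementations differ on this point.

Degenerate but exact consequences used as test anchors: a pure compound
has ln γ = 0 identically; two compounds with identical profiles form an
ideal mixture; a zero-charge ("conductor") surface reduces ln γ exactly to
the combinatorial term; as T → ∞ the Boltzmann factors flatten and ln γ →
ln γ^SG; with all eight HB2 constants equal and profiles whose activated
segments carry matching donor/acceptor classes, HB2 reproduces the 2002
model.

## Fixed constants and parameters

| symbol | meaning | value / default | unit |
| --- | --- | --- | --- |
| ε₀ | misfit dielectric prefactor | 2.395×10⁻⁴ | e²·mol·kcal⁻¹·Å⁻¹ |
| R | gas constant | 1.98721×10⁻³ | kcal·mol⁻¹·K⁻¹ |
| z | coordination number | 10 | – |
| r₀ | volume normalizer | 66.69 | Å³ |
| q₀ | area normalizer | 79.53 | Å² |
| f_pol | polarization factor | preset | – |
| r_avg | charge-averaging radius | preset (1.1–1.6) | Å |
| r_eff | standard segment radius | preset (≈1.2) | Å |
| σ_HB | hydrogen-bond cutoff | preset (0.007–0.0115) | e/Å² |
| C_HB… | hydrogen-bond constants | preset | kcal·mol⁻¹·Å⁴·e⁻² |

The five fixed constants follow the 2002 Lin–Sandler conventions and live
on `ParameterSet` so alternates can be tested. The five presets reproduce
the published universal-parameter tables for the three quantum-chemistry
levels digit for digit; the published table prints σ_HB with the unit
e/Å, which this implementation reads as e/Å² — the unit conventional for a
threshold applied to the sigma axis of the profile.

## Sigma-profile construction

- Grid: 51 bins on [−0.025, 0.025] e/Å² (odd count so σ = 0 is a bin
  center). Configurable; charge densities outside the grid raise by
  default, with an opt-in clamp-to-edge mode for unusually polar cavities.
- Averaging kernel exactly as in the model section; the self term is
  included; no extra decay factor is applied (an optional multiplier in
  the exponent exists for literature variants, default 1).
- Each segment's area is assigned to the two bins bracketing its averaged
  σ by linear interpolation. This conserves area exactly and removes
  grid-resolution artifacts: doubling the bin count moves fixture ln γ^∞
  by well under 2%.
- Hydrogen-bond classes are assigned per atom by simple connectivity rules
  (bond = distance < 1.3× the sum of covalent radii): H on a water oxygen
  → water donor, H–O → hydroxyl donor, H–N → amine donor; water O,
  hydroxyl O, N, and H-free O (ether/carbonyl) are the acceptor classes.
  Each segment inherits the class of its nearest atom. Classification and
  energetic activation are deliberately orthogonal: acceptor segments keep
  their label even when |σ| < σ_HB.

## Numerical choices

- **Segment fixed point:** damped successive substitution on ln Γ (mixing
  factor 0.5), tolerance 1e-8 (max |Δ ln Γ|), max 500 iterations,
  convergence failure raises with the residual history. The fixed point
  couples only populated (class, bin) entries; afterwards ln Γ is
  evaluated once on the full lattice so unpopulated bins carry defined
  values and profile algebra stays total.
- **IDAC:** evaluated in the analytic dilute limit (solvent profile as the
  mixture; combinatorial term in ratio form, which is finite at x = 0),
  not at a tiny finite mole fraction. Agrees with the x = 1e-8 finite
  evaluation to better than 1e-5 on fixtures.
- **Bubble temperature:** Brent root finding on Σ xᵢγᵢ(T)Pᵢ^sat(T) − P
  with γ re-evaluated per iterate; explicit bracket check.
- **Antoine correlations:** one internal convention (natural log, kPa, K);
  declared dialects (log₁₀, mmHg/bar/Pa/atm, °C) are converted once at
  construction. Vapor phase ideal, no Poynting correction — adequate below
  a few bar, which is the model's intended pressure range.
- **LLE:** 201-point Gibbs-energy-of-mixing scan, lower-convex-hull
  double-tangent construction for initial phase guesses, then a 2×2
  isoactivity solve in logit coordinates (keeps compositions in (0,1));
  accepted only if both activity residuals < 1e-8 and the phases are
  distinct (Δx > 1e-4). Temperature sweeps seed each solve with the
  previous tie line and fall back to the full scan.
- **Fitting:** Nelder–Mead with scipy's standard coefficients on
  log-transformed parameters (positivity without penalties), simplex
  tolerance 1e-6 in log space, objective tolerance 1e-12. Parameter-box
  violations during simplex exploration return a large objective value
  rather than raising. When multiple HB2 constants are freed they share
  one simplex. The r_avg scan rebuilds every profile from the stored
  cavity geometry at each grid value and re-estimates the remaining free
  parameters; failed nested fits are recorded and skipped.

## Synthetic fixtures

The generator emulates COSMO cavities so the package is testable without
quantum chemistry: near-uniform Fibonacci-lattice segments on
atom-centered spheres (COSMO-type radii, ≈1.17× van der Waals), points
buried inside neighboring spheres culled so segments tile the union
surface, and σ\* from smooth angular Gaussian lobes — negative on polar
hydrogens, positive on acceptor heteroatoms, matching the sign convention
of apparent screening charges. Total charge is shifted exactly to a target
(default 0). The library spans the chemistries the model distinguishes:
alkane (nonpolar), water (donor+acceptor), alcohol (hydroxyl), ketone
(carbonyl acceptor) and amine. Lobe amplitudes (±0.026–0.032 e/Å² raw)
were chosen so that after averaging the donor and acceptor surfaces extend
beyond the hydrogen-bond cutoffs — i.e. the fixtures genuinely exercise
the hydrogen-bond channel, like real associating molecules.

What the fixtures do *not* emulate: real electronic structure (lobe shapes
are idealized Gaussians), conformational flexibility, dispersion-dominated
surfaces, and realistic area/volume ratios for large molecules.
Consequently, passing tests demonstrate the correctness of the
thermodynamic machinery (identities, consistency, oracle agreement,
recovery of generating parameters), not the predictive accuracy of the
published parameterizations on real systems — the latter requires real
sigma-profile databases and experimental collections outside this
package's scope, which is also why the recovery experiments use a
synthetic generating parameter set (single-constant variant, f_pol = 0.9,
r_avg = 1.2 Å, r_eff = 1.2 Å, σ_HB = 0.007 e/Å², C_HB = 4000) rather than
any shipped preset: identifiability, not parametrization, is what they
test. Problem sizes used throughout: ~200–500 segments per fixture
molecule, 51-bin profiles, 60-record synthetic IDAC datasets (20 ordered
fixture pairs × 3 temperatures).

## Known limitations

- No dispersion correction; mixtures whose non-ideality is
  dispersion-driven (e.g. perfluorinated refrigerants) are outside the
  model's reach, as is mixing-enthalpy prediction.
- Carboxylic-acid vapor-phase dimerization is not modeled.
- Binary LLE only (no multicomponent flash), and no critical-region
  renormalization: tie lines near a consolute point inherit the model's
  classical flat-Gibbs behavior.
- The GAMESS reader targets the layout of the open LVPP sigma-profile
  database dialect; other GAMESS COSMO printouts are rejected explicitly
  rather than guessed at.
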