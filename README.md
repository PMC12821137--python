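# cosmosac

Predictive liquid-phase activity coefficients from COSMO sigma-profiles:
the COSMO-SAC (2002) model and its multi-constant hydrogen-bond variant
COSMO-SAC-HB2, with sigma-profile construction from TURBOMOLE/GAMESS
continuum-solvation output, infinite-dilution activity coefficients (IDAC),
vapor–liquid and liquid–liquid equilibrium prediction, and the
universal-parameter estimation protocol.

The package targets thermodynamicists and process engineers who need
activity coefficients for mixtures with little or no experimental data.
Unlike group-contribution methods, COSMO-SAC needs only each molecule's
apparent surface-charge distribution (the sigma-profile), so any compound
with a COSMO calculation is in scope.

## The model

A COSMO calculation tiles the molecular cavity with segments carrying
apparent surface-charge densities σ\* (e/Å²). These are spatially averaged
with radius *r*<sub>avg</sub>,

σₘ = Σₙ σ\*ₙ wₘₙ / Σₙ wₘₙ,  wₘₙ = [rₙ² r²avg/(rₙ² + r²avg)] · exp(−d²ₘₙ/(rₙ² + r²avg)),

and binned into a sigma-profile p(σ). Activity coefficients follow from

ln γᵢ = nᵢ Σₘ pᵢ(σₘ)[ln Γ_S(σₘ) − ln Γᵢ(σₘ)] + ln γᵢ^SG,

where nᵢ = Aᵢ/a_eff, Γ solves the segment self-consistency equation

ln Γ(σₘ) = −ln Σₙ p(σₙ) Γ(σₙ) exp(−ΔW(σₘ,σₙ)/RT),

the exchange energy combines electrostatic misfit and hydrogen bonding,

ΔW = (α′/2)(σₘ+σₙ)² + c_hb · max(0, σ_acc − σ_HB) · min(0, σ_don + σ_HB),

with α′ = f_pol · 0.3 · a_eff^{3/2}/ε₀, and γ^SG is the
Staverman–Guggenheim combinatorial term. COSMO-SAC-HB2 splits the profile
into hydrogen-bond donor/acceptor classes and replaces the single constant
c_hb with a table of up to eight constants indexed by the donor–acceptor
class pair.

Five published universal-parameter sets ship as named presets —
`HB2-FINE`, `HB2-BP-TZVP`, `COSMO-SAC-FINE`, `HB2-HF-TZVP` and
`COSMO-SAC-HF-TZVP` — one per model variant and quantum-chemistry level
(BP-TZVPD-FINE, BP-TZVP, HF-TZVP).

VLE uses modified Raoult's law (y·P = x·γ·P^sat, ideal vapor, Antoine
correlations); binary LLE uses the gamma–gamma isoactivity criterion with a
Gibbs-energy tangent construction. Parameter estimation minimizes the
average absolute deviation (AAD) of ln γ^∞ with Nelder–Mead, and the
averaging radius is optimized indirectly by a grid scan with nested refits.

Because quantum-chemistry output is not required, a synthetic fixture
generator (`cosmosac.fixtures`) builds physically plausible COSMO cavities
— Fibonacci-lattice segments on atom spheres with smooth charge lobes — so
the entire pipeline runs and is tested self-contained.

## Worked example

```sh
$ cosmosac fixtures --out-dir cosmo/ --seed 7
$ cosmosac idac --solute cosmo/water-like.cosmo --solvent cosmo/alkane-like.cosmo \
    --params HB2-FINE -T 298.15
solute      solvent      T_K     ln_gamma_inf        gamma_inf
water-like  alkane-like  298.15  2.6607088824115883  14.30642707946423
```

A strongly polar, hydrogen-bonding solute in a nonpolar solvent is highly
non-ideal: ln γ^∞ ≈ 2.66, i.e. the solute's escaping tendency is about
14× its ideal-solution value. The same pair demixes below the consolute
point; the gamma–gamma solver finds the tie line:

```sh
$ cosmosac lle --profile-1 cosmo/water-like.cosmo --profile-2 cosmo/alkane-like.cosmo \
    --t-min 298.15 --t-max 298.15 --n-temps 1
T_K     x1_alpha            x1_beta             residual
298.15  0.1722272469072785  0.8992903638074025  3.3306690738754696e-16
```

Both coexisting phases carry identical activities for each compound to
~1e-15. The same workflow works with real TURBOMOLE `.cosmo` files (or
GAMESS-dialect files via `--dialect gamess`).

Library use mirrors the CLI:

```python
from cosmosac import ParameterSet, build_profile, idac, parse_turbomole_cosmo

params = ParameterSet.from_preset("HB2-FINE")
mol = parse_turbomole_cosmo(open("water.cosmo").read())
profile = build_profile(mol, params.r_avg, split_hb=True)
```

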