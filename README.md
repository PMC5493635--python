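# blinkcomp

Eigen-analysis of image stacks of blinking fluorophores: which parts of
the data actually carry super-resolution information, and how do
blinking statistics weigh them?

A camera records K frames of M blinking point emitters (quantum dots,
switchable dyes, fluorescent proteins) at N pixels, giving a stack
**I** (N × K).  With emitter images stacked as columns of a system
matrix **G** (N × M) and per-frame photon counts **S** (M × K), the
stack is **I = G S**.  For independent, statistically identical
emitters with per-frame count mean μ and standard deviation σ, the
stack Gram matrix decomposes exactly as

    J = I Iᵀ  →  K G O Gᵀ,   O = σ² I_M + μ² L_M
    J = c₁ C₁ + c₂ (C₂ − C₃)

    c₁ = K M (σ² + M μ²)              c₂ = K (M − 1) σ²
    C₁ = (1/M²)  G̃ G̃ᵀ                 (G̃ = Σ_m ḡ_m, the mean image)
    C₂ = (1/M)   Σ_m ḡ_m ḡ_mᵀ
    C₃ = (1/(M(M−1))) Σ_{m'≠m} ḡ_m' ḡ_mᵀ

with the exact identity **M C₁ = C₂ + (M−1) C₃**.  C₁ is the rank-one
outer product of the mean image — it only enhances contrast.  C₂
(cross-pixel, auto-emitter) squares the effective PSF and so resolves
√2 beyond the diffraction limit; C₃ (cross-pixel, cross-emitter)
sharpens further.  Because c₂/c₁ < 1 always, the mean image dominates
the raw stack; super-resolution methods succeed by isolating C₂/C₃
content.  The package builds this entire chain on synthetic 1-D scenes:

- `optics` — Airy/Gaussian 1-D PSFs, emitter/pixel geometry, system matrix
- `kinetics` — truncated-power-law on/off blinking, Poisson photon counts,
  μ²/σ² statistics
- `stacks` — stack assembly, Poisson noise at a given peak SNR, TIFF I/O
- `components` — O, C₁/C₂/C₃, c₁/c₂, reconstructed and empirical J
- `metrics` — FWHM, minima-to-maxima ratio R, magnitude-vs-separation
  curves and their inflection points
- `musical` — eigenimages, signal/null subspace split, MUSIC
  pseudo-spectrum f(r′) = (d_PS/d_PN)^α, peak counting
- `sofi` — second-order SOFI (lagged temporal auto-cumulant) and its
  relation to the components
- `experiments`/`cli` — YAML-configured, seeded experiment presets

## Worked example

Two emitters 100 nm apart imaged by 10 pixels of 100 nm, with a
222-nm-Rayleigh Airy PSF (system FWHM 187 nm):

```sh
blinkcomp components --preset example2 --out demo/
```

prints (abridged)

```json
{
  "M": 2, "K": 500, "mu": 1.0, "sigma": 1.0,
  "c1": 3000.0, "c2": 500.0, "c2_over_c1": 0.1667,
  "magnitude_C1": 0.4916, "magnitude_C2": 0.5491,
  "rank_C1": 1, "rank_C2": 2,
  "identity_residual": 0.0,
  "R_mean_image": 1.0
}
```

Read: the mean-image term outweighs the super-resolution term six-fold
(`c2_over_c1` = 1/6 at μ = σ); C₁ is exactly rank one while C₂ has one
mode per emitter; the component identity holds to machine precision;
and `R_mean_image` = 1 says a 100-nm pair is *not* resolved by the mean
image — it is resolved by C₂, whose two-point threshold is 118 nm
versus 172 nm for the mean image.

Blinking statistics at frame time T = 10 ms across dark/bright
time-scale ratios (`blinkcomp blinkstats --preset blinkstats_T10ms
--seed 1 --out demo2/`):

| τ_max,b/τ_max,d | μ (photons) | σ (photons) | μ²/σ² |
|---|---|---|---|
| 0.01 | 4.0 | 21.9 | 0.034 |
| 1    | 199.9 | 96.6 | 4.28 |
| 100  | 396.0 | 20.0 | 393 |

Long dark states (ratio 0.01) give μ²/σ² ≪ 1 — the regime in which the
stack is implicitly biased towards super-resolution content and
localisation microscopy operates.  With a binary on/off emitter model
the ratio necessarily grows with the duty cycle (see
`docs/methods.md`), so the nearly-always-on regime is unfavourable.

MUSIC pseudo-spectra on a dense scene (8 emitters, 10 nm apart, 40
pixels of 100 nm, noiseless):

```sh
blinkcomp musical --preset eight_emitters_10nm --out demo3/
```

recovers **exactly 8 peaks** at the emitter positions from C₂ and C₃,
and a single broad peak from C₁ — the cross-pixel matrices carry the
resolving power; the mean image does not.

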