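# afterglow

An edge-triggered diffusion model of "conflicting" afterimage effects.

Brief exposure to a chromatic shape (the *inducer*, I₀) followed by an
achromatic outline (the *remaining contour*, I₁) can leave two opposite
percepts: a surface filled with the **complementary** color of the inducer
(the *negative* effect, as in "filling in the afterimage after the image")
or with the **same** color (the *positive* effect, as in the color dove
illusion).  Which one wins is decided not by separate mechanisms but by
where the remaining contour falls relative to the inducer's chromatic
edges.  `afterglow` implements a computational model in which both effects
emerge from a single filling-in process: after stimulus offset the edge
signals rebound with reversed sign, and those reversed edges act as the
*sources* of a diffusion of color across the surface.

## The model

1. **Opponent transform.** The inducer is mapped pixelwise into opponent
   color space, `(O_RG, O_YB, O_BW) = O · (R, G, B)ᵀ`, with the orthonormal
   matrix rows `(1,−1,0)/√2`, `(1,1,−2)/√6`, `(1,1,1)/√3`.
2. **Double-opponent edge response.** Each opponent channel is convolved
   with the discrete Laplace kernel `L` (center 1, 4-neighbors −¼) — a
   stand-in for center-surround double-opponent receptive fields:
   `DO = I_OPP ∗ L`.
3. **Off response.** At stimulus offset the edge signal reverses sign:
   `off = −DO` (the rebound that seeds complementary color).
4. **Weighted sources.** The remaining contour modulates source strength
   multiplicatively, `w = α·𝟙_{∂Ω₁} + β` with `α = 1.3 > β = 0.1`: a
   contour that overlaps chromatic edges amplifies them; one that misses
   them all multiplies zeros and is inert (the overlap rule observed
   psychophysically).
5. **Zone-separated Poisson solves.** The steady state of the diffusion
   (heat) equation reduces to a Poisson problem per opponent channel,
   `∇²O_p = −off · w`, solved once with sources restricted to the
   chromatic zone Ω (negative effect) and once restricted to Ω̄ (positive
   effect), with white borders, by Gauss–Seidel iteration.
6. **Combination and rendering.** `O_p = (O_p,pos + O_p,neg) / (max|O_p,pos|
   + max|O_p,neg|)`, inverted back to RGB and rendered on white.

## Worked example

Predict the classic single-ring demonstration — a cyan annulus whose outer
edge remains as a black circle — and classify the percept per region:

```sh
afterglow report --fixture ring_outer
```

```json
{
  "fixture": "ring_outer",
  "regions": {
    "interior": {
      "hue_projection": -0.0177,
      "classification": "negative"
    },
    "annulus": {
      "hue_projection": -0.0190,
      "classification": "negative"
    },
    "surround": {
      "hue_projection": 0.0000,
      "classification": "none"
    }
  }
}
```

`hue_projection` is the mean chromatic component of the normalized percept
projected onto the inducer's hue direction: negative means the region fills
with the complementary color (reddish, for the cyan ring), positive with
the inducer's own hue.  With the **outer** contour the enclosed interior
classifies *negative* (complementary), as above; rerunning with
`--fixture ring_inner` flips it to *positive* (+0.0157, same hue) — the
same machinery, opposite percepts, selected purely by contour placement.

Other entry points:

```sh
afterglow demo --figure fig5 --out out/      # spiral demonstrations, PNG panels
afterglow generate --fixture stars_vanlier --out stim/   # stimulus PNGs + region masks
afterglow predict --inducer my_inducer.png --contour my_contour.png --out pred.png
```

All stimuli are generated programmatically (`afterglow.stimuli`); there are
no external data dependencies.

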