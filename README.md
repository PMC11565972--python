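# coilpeaks

Quantifying the conformational ensembles of intrinsically disordered protein
regions from frozen-state 2D NMR cross-peak shapes.

When a disordered protein is flash-frozen, every conformer it was sampling is
trapped, and a low-temperature ¹³C–¹³C correlation spectrum (e.g. DNP MAS
DARR) shows a cross-peak that is the *population-weighted superposition* of
the chemical shifts of all trapped backbone conformations.  The shape of a
Cα–Cβ (or Cα–CO) cross-peak therefore encodes the fractions of α-helical,
random-coil, β-strand and positive-φ backbone conformations at that site.
`coilpeaks` implements the analysis end to end:

1. **Statistical-coil reference** — sample a poly-alanine *host–guest*
   peptide ensemble (guest residue at the center, N = 10,000 conformers)
   from a restricted coil library of Ramachandran basins, map each
   conformer's (φ, ψ) to Cα/Cβ/CO shifts through a smooth periodic shift
   surface, histogram the shift pairs and apply 1.5 ppm Gaussian line
   broadening.  This is the no-preference baseline every experiment is
   compared against.
2. **Constrained mixture decomposition** — fit a cross-peak region with 1–4
   axis-aligned 2D Gaussians under bounded "peak motion" (centers may move
   only a small excursion from their initial guesses).  Fractional
   populations are analytic component volumes, `A·2πσ₁σ₂`, normalized over
   components.  Peaks above and below the homonuclear diagonal are fit
   independently with the same component count and reported as
   mean ± SD (two-fit sample SD, `|p_a−p_b|/√2`).
3. **Classification** — each fitted component is assigned to
   α-helix / random coil / β-strand via reference mean ± 2 SD shift windows
   (positive-φ via an anchor point), with an `extreme_beta` flag for
   components beyond the β window in the extended-shift direction.
4. **Synthetic data** — every reported cross-peak decomposition (alanine,
   glycine, leucine × statistical coil / 8 M urea / frozen monomer / fibril
   fuzzy coat) ships as a named synthetic fixture with ground truth, so the
   whole chain is testable without experimental downloads.

It is aimed at solid-state NMR spectroscopists and IDP structural biologists
who want a reproducible, scriptable version of this peak-shape analysis.

## Worked example

Full statistical-coil prediction + decomposition for alanine, leucine and
glycine guests:

```bash
coilpeaks reference-run --n 10000 --seed 1 --out-dir run
```

prints (values are percent of cross-peak volume per conformational class):

```json
{
 "A": {"alpha": 16.6, "coil": 60.7, "beta": 15.6, "positive_phi": 7.1},
 "L": {"alpha": 8.0,  "coil": 64.5, "beta": 20.6, "positive_phi": 6.8},
 "G": {"coil": 100.0}
}
```

Reading the alanine row: fitting four Gaussians to the predicted
statistical-coil Cα–Cβ cross-peak, ~61% of the volume sits in the
random-coil component near (53.2, 18.6) ppm, ~17% in the α-helical
component near (55.3, 18.0) ppm, ~16% in the β-strand component near
(51.3, 21.0) ppm and ~7% in the positive-φ component near (53.3, 16.0) ppm;
the glycine Cα–CO prediction collapses to a single broad coil Gaussian at
(44.7, 174.2) ppm with ≈3 ppm FWHM.  `run/coil_A.tsv` holds the per-component
centers, widths and percentages.

The same stages are available as composable commands
(`simulate-coil`, `predict-shape`, `synth`, `fit`, `classify`, `report`)
with files between them, and as a Python API:

```python
import coilpeaks as cp

dec = cp.coil_decomposition("A", ("CA", "CB"), k=4, n=10_000, seed=1)
for cc in dec.classified:
    print(cc.label, round(100 * cc.fraction, 1), cc.component.center)
```

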