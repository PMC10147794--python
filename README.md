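# scoliofe

Patient-specific finite-element simulation of scoliotic curve progression
with region-specific, stress-modulated vertebral growth.

The pipeline mirrors the clinical modeling workflow for adolescent
idiopathic scoliosis (AIS):

1. **landmarks** — 9 landmarks × 17 vertebral levels (T1–L5, 153 points);
   biplanar (frontal/lateral) to 3D triangulation and CSV I/O.
2. **template** — reduced parametric normative hexahedral spine model
   (vertebral-body blocks + shared-node tied IVD blocks + posterior /
   ligament tension-only springs) with hex mesh-quality metrics (scaled
   Jacobian, aspect, skewness, warpage, quad corner angles).
3. **morphing** — dual-kriging morph (kernel `K(h)=h`, linear drift) of the
   template onto patient landmarks; exact control interpolation and affine
   reproduction.
4. **materials** — chronological-age scaling of adult material cards, spine
   flexibility ratio `SFR = (CAS − CALB)/CAS`, and flexibility-scaled IVD
   modulus `E = E_baseline (1 − C·SFR)` with `C = 0.3`.
5. **fem** — small-strain linear-elastic hex + spring solver with
   anisotropic eigenstrain (growth) loading, tension-only spring iteration,
   the two-pass anti-gravity protocol, and volume-weighted IVD quadrant
   stress extraction.
6. **growth** — 663 growth coefficients (17 levels × 13 regions × 3
   directions); Hueter-Volkmann law `G = G_m [1 + β(σ − σ_m)]` with
   `β = 0.4 − 0.08·Risser` (MPa⁻¹, floored at 0); staggered 6-month
   interval stepping.
7. **metrics** — automated Cobb (exhaustive end-vertebra maximization),
   kyphosis, lordosis, apical axial rotation, vertebral wedging, and
   comparison tables with the 8° acceptance threshold.
8. **synth** — synthetic patient generator with prescribed curvature
   angles; the test substrate replacing clinical radiographs.

## CLI

```sh
scoliofe synth --out bundle --thoracic-cobb 40 --patient-id p1
scoliofe reconstruct bundle/p1/landmarks_biplanar.csv --out lm3d.csv
scoliofe morph lm3d.csv --out patient.vtk          # + .quality.json
scoliofe simulate --landmarks lm3d.csv --profile bundle/p1/profile.yaml \
    --out run/ --seed 1                            # indices.csv, stresses
scoliofe measure patient.vtk --out indices.csv
```

Every command writes a `manifest.json` (config hash, version, timing) into
its output directory. Meshes are ASCII VTK legacy unstructured grids with a
`.meta.json` sidecar carrying springs/constraints/node groups.

## Conventions

Global frame: +x anterior, +y patient-left, +z superior; mm, MPa, N.
Stress is tension-positive inside the solver and growth law;
compression-positive only in reported quadrant-stress tables. Angles in
degrees, displayed to 0.1°; SFR to 2 decimals; moduli to 1 decimal.
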