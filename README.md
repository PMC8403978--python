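# aquapore

Layer-resolved structural and dynamical analysis of water confined in
finite cylindrical nanopores.

Water inside a nanometre-scale pore does not behave like bulk water: it
organises into concentric cylindrical layers about the pore axis, orients
preferentially at the wall, loses tetrahedral order in the contact layer,
rewires its hydrogen-bond network, and exchanges with the reservoirs at the
pore mouths. `aquapore` turns the standard battery of analyses for this
system — density profiles and maps, orientation, tetrahedrality, hydrogen
bonding, survival and restricted mean-square displacement — into a tested,
reusable pipeline for time-ordered trajectories of rigid three-site water
(one oxygen, two hydrogens; Å/ps units). It ships synthetic trajectory
generators with exact ground truth, so every stage is verifiable without
running molecular dynamics.

## What it computes

Given a trajectory and a pore geometry (axis, radius *R*, length *L*,
membrane slab):

- **Density** — cylindrically averaged ρ(r), azimuthally averaged 2-D
  maps ρ(r, z), axial density of the contact layer, and automatic layer
  segmentation at the minima of ρ(r) into *inner*, optionally *middle*,
  and *contact* layers.
- **Orientation** — the angle β between the projection of the H–O–H
  bisector onto the plane normal to the pore axis and the outward radial
  direction; radial profiles of ⟨cos β⟩ and ⟨|cos β|⟩. For uniformly
  random orientations ⟨cos β⟩ = 0 and ⟨|cos β|⟩ = 2/π ≈ 0.6367.
- **Tetrahedrality** — the six angles γ subtended at each oxygen by its
  four nearest neighbours (minimum image), and the orientational order
  parameter

      q = 1 − (3/8) Σ_{i<j} (cos γ_ij + 1/3)²,

  which is 1 for a perfect tetrahedron (all cos γ = −1/3, γ ≈ 109.5°),
  0 on average for an ideal gas, and −3 when all four neighbours share one
  direction. Distributions P(γ) and P(q) are resolved per layer.
- **Hydrogen bonds** — geometric criterion (O–O ≤ 3.5 Å and donor
  O–H · O→O angle ≤ 30°, both boundaries closed); per-molecule counts
  n_HB, per-layer means, bond typing (contact–contact, contact–inner,
  inner–inner, middle–\*), and plain-text network export.
- **Dynamics** — the survival function S(t) = n(t)/n(0) of continuously
  pore-resident molecules, and the residence-restricted MSD split into
  axial (z) and planar (xy) components. In a sealed pore the components
  plateau at L²/6 and R² respectively; plateau values are also reported as
  linear distances √MSD.

## Worked example

```bash
# 1. make a synthetic trajectory: ideal gas in an R=7 Å, L=26 Å pore
aquapore generate --kind uniform_gas --n-molecules 500 --n-frames 20 \
    --seed 1 --output gas.xyz
# -> wrote 20 frames to gas.xyz (ground truth: gas.xyz.truth.json)
# -> geometry: R=7.00 Å, L=26.00 Å, axis origin [10.0, 10.0, 21.0]

# 2. analyse it end to end
cat > run.yaml <<EOF
input: gas.xyz
output: gas_out
geometry: {radius_R: 7.0, length_L: 26.0, axis_origin: [10.0, 10.0, 21.0]}
grid: {dr: 0.5, dz: 1.0}
layers: {override_boundaries: [3.5]}
dynamics: {origin_stride: 2}
EOF
aquapore all --config run.yaml
# -> outputs written to gas_out
```

`gas_out/` then holds one CSV per observable plus `summary.json`. For this
gas the radial density is flat at N/(πR²L) ≈ 0.125 Å⁻³ within counting
noise, the orientation profile sits at ⟨|cos β|⟩ ≈ 0.64, and
`summary.json` reports an inner-layer mean q near 0 — the ideal-gas
anchor (the contact layer sits lower, ≈ −0.12 here, because wall-adjacent
molecules lack neighbours on the wall side) — along with the layer
boundaries, mean n_HB, MSD plateau estimates and their linear distances. The same library calls are available from Python
(`aquapore.radial_density`, `aquapore.detect_hbonds`, …) on any trajectory
in extended-XYZ or columnar dump format.

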