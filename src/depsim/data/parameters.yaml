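# Device, media and particle parameters for the tapered-microelectrode DEP model.
# Lengths in the units stated per key; conductivities in S/m.

media:
  di_water: {conductivity: 2.0e-4, relative_permittivity: 78}
  dmem_f12: {conductivity: 2.3, relative_permittivity: 80}
  dmem: {conductivity: 1.5, relative_permittivity: 80}

beads:
  # Effective conductivity follows sigma_bulk + 2 Ks / r; table_conductivity is
  # the rounded two-significant-figure value usually quoted for these beads.
  ps_3p2um:
    diameter_um: 3.2
    relative_permittivity: 2.56
    bulk_conductivity: 1.0e-16
    surface_conductance: 2.0e-9
    table_conductivity: 2.5e-3
  ps_4p8um:
    diameter_um: 4.8
    relative_permittivity: 2.56
    bulk_conductivity: 1.0e-16
    surface_conductance: 2.0e-9
    table_conductivity: 1.6e-3

cells:
  keratinocyte:
    outer_dimensions_um: [5.97, 5.97, 11.95]
    membrane_thickness_nm: 7.0
    cytoplasm: {conductivity: 0.12, relative_permittivity: 50}
    membrane: {conductivity: 1.0e-6, relative_permittivity: 9.04}
  fibroblast:
    outer_dimensions_um: [70.0, 70.0, 7.0]
    membrane_thickness_nm: 7.0
    cytoplasm: {conductivity: 0.75, relative_permittivity: 75}
    membrane: {conductivity: 4.7e-3, relative_permittivity: 53}

geometry: {w1: 100, w2: 80, w3: 100, w4: 280, a1: 75, a2: 15, h1: 4, h2: 4, h3: 80}

release_grids:
  grid_1: {x: [30, 45, 130], y: [30, 30, 60]}   # left side: small beads / keratinocytes
  grid_2: {x: [150, 45, 270], y: [30, 30, 60]}  # right side: large beads / fibroblasts

fluid:
  viscosity_pa_s: 8.9e-4
  density_kg_m3: 997.0

densities:
  polystyrene_kg_m3: 1050.0
  cell_kg_m3: 1100.0

drive:
  v_left: 10.0
  v_right: -10.0
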