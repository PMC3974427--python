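# Legend for the 11 general qualitative shell characters scored for all
# Peninsular Malaysian Plectostoma species. Codes follow the published
# character-state legend; figure_ref points at the plate that illustrates
# the states.
characters:
  - character_id: apex
    name: Apex form
    figure_ref: Fig 4
    state_codes:
      1: distinctly convex
      2: moderately convex
      3: slightly convex
  - character_id: apical_spire
    name: Apical spire form
    figure_ref: Fig 5
    state_codes:
      1: oblong
      2: depressed
  - character_id: basal_spire
    name: Basal spire form
    figure_ref: Fig 6
    state_codes:
      1: conical
      2: ovoid
      3: ellipsoid
  - character_id: parietal_teeth
    name: Parietal constriction teeth
    figure_ref: Fig 7
    state_codes:
      1: two long lamella
      2: two knob-shaped teeth
      3: single knob-shaped tooth
      4: no tooth
  - character_id: basal_teeth
    name: Basal constriction teeth
    figure_ref: Fig 8
    state_codes:
      1: two knob-shaped teeth
      2: no tooth
  - character_id: tuba_form
    name: Tuba form
    figure_ref: Fig 9
    state_codes:
      1: tuba type 1
      2: tuba type 2
      3: tuba type 3
  - character_id: aperture_view
    name: Aperture view
    figure_ref: Fig 1
    state_codes:
      1: frontal view
      2: right lateral view
      3: back view
      4: left lateral view
  - character_id: peristome
    name: Peristome types
    figure_ref: Fig 11
    state_codes:
      1: simple peristome
      2: double peristome
  - character_id: spiral_lines
    name: Spiral lines
    figure_ref: Fig 12
    state_codes:
      1: thick and thin
      2: thin only
  - character_id: rib_shape
    name: Rib shape
    figure_ref: Fig 13
    state_codes:
      1: single-humped
      2: slightly curved
      3: straight
  - character_id: rib_thickness
    name: Rib thickness
    figure_ref: Fig 13
    state_codes:
      1: thick
      2: thin
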