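# Surface-protein multiplet-exclusion rules and cell-type annotation markers.
#
# A cell is flagged as a multiplet when, for any rule, ALL anchor markers are
# positive AND at least one marker in ANY forbidden group is positive.
# Forbidden groups encode lineage-incompatible co-expression: e.g. a CD19+
# cell that also carries a T-cell marker (CD3/CD4/CD8) or an innate marker
# (CD14/CD16/CD56) is a B-cell-containing multiplet, not a B cell.
multiplet_rules:
  - id: B_multiplet
    anchors: [CD19]
    forbidden:
      - [CD3, CD4, CD8]        # T cell markers
      - [CD14, CD16, CD56]     # innate cell markers
  - id: CD14_monocyte_multiplet
    anchors: [CD14]
    forbidden:
      - [CD3, CD8, CD28]       # T cell markers
      - [CD56]                 # NK marker
      - [CD19, CD20]           # B cell markers
  - id: NK_multiplet
    anchors: [CD56]
    forbidden:
      - [CD3, CD4, CD28]       # T cell markers
      - [CD14, CD11c]          # monocyte markers
      - [CD19, CD20]           # B cell markers
  - id: CD4_T_multiplet
    anchors: [CD3, CD4]
    forbidden:
      - [CD8]                  # CD8+ T
      - [CD56]                 # NK
      - [CD19, CD20]           # B cells
      - [CD14, CD16]           # monocytes / NK
  - id: CD8_T_multiplet
    anchors: [CD3, CD8]
    forbidden:
      - [CD4]                  # CD4+ T
      - [CD56]                 # NK
      - [CD19, CD20]           # B cells
      - [CD14, CD16]           # monocytes / NK

# Lineage annotation, applied in precedence order (first match wins).
annotation:
  precedence:
    - {cell_type: CD4_T, require_all: [CD3, CD4]}
    - {cell_type: CD8_T, require_all: [CD3, CD8]}
    - {cell_type: CD14_monocyte, require_any: [CD14]}
    - {cell_type: B, require_any: [CD19, CD20]}
    - {cell_type: NK, require_any: [CD56, CD16]}
  naive_marker: CD45RA
  memory_marker: CD45RO
  activation_markers: [CD69, CD25]
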