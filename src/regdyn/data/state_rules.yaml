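# Chromatin-state truth tables, versioned so the one genuinely rule-based
# (rather than model-based) step of the pipeline is auditable and can be
# overridden without code changes.
#
# Keys under `states` are bit strings over `marks` in the listed order:
# "101" over [H3K4me1, H3K27ac, H3K27me3] means K4me1 and K27me3 present,
# K27ac absent. A mark is "present" at an element when its peaks cover at
# least `min_overlap_frac` of the element length in that cell type.
#
# Defaults: acetylation without Polycomb = active; acetylation with
# H3K27me3 = mixed (bivalent-like); H3K4me1 alone = primed; H3K4me1 with
# H3K27me3 = poised; H3K27me3 alone = repressed; no mark = neutral.
# Promoters use H3K4me3 in place of H3K4me1 and have no primed state:
# H3K4me3 without H3K27me3 is active.
version: 1
enhancer:
  marks: [H3K4me1, H3K27ac, H3K27me3]
  states:
    "000": neutral
    "001": repressed
    "010": active
    "011": mixed
    "100": primed
    "101": poised
    "110": active
    "111": mixed
promoter:
  marks: [H3K4me3, H3K27ac, H3K27me3]
  states:
    "000": neutral
    "001": repressed
    "010": active
    "011": mixed
    "100": active
    "101": poised
    "110": active
    "111": mixed
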