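"""Segment and count cells in a synthetic phase-contrast field.

Builds a 512x512 field of 150 textured cells (10% placed as touching
pairs, half carrying a red reporter), runs the bandpass → Otsu →
watershed chain, and compares the counts against the generator's ground
truth.
"""

from fructolyze.imaging import SegmentationConfig, segment_frame
from fructolyze.synthetic import CellFieldSpec, generate_cell_images

spec = CellFieldSpec(n_cells=150, labeled_fraction=0.5, touching_fraction=0.10,
                     seed=7)
[field] = generate_cell_images(spec)

result = segment_frame(field.phase, field.red, SegmentationConfig())

print(f"true cells:      {len(field.truth)}")
print(f"counted objects: {result.count}")
print(f"true labeled:    {int(field.truth.labeled.sum())}")
print(f"flagged labeled: {result.labeled_count}")
print(f"median area:     {result.objects.area_px.median():.0f} px "
      f"(truth {field.truth.area_px.median():.0f} px)")
# A count within a few percent of truth and an exact labeled tally show
# the watershed is splitting touching pairs without fragmenting cells.
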