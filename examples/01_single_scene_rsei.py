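"""Single-scene RSEI: indicators -> static min-max -> sign-stabilized PC1.

Generates one synthetic October acquisition, computes the four ecological
indicators, and aggregates them into the classic single-scene remote-sensing
ecological index.  The printed class means show the October bias: winter
wheat is freshly sown (low NDVI) while deciduous forest is still leafy, so a
single October scene ranks cropland far below forest.
"""

from datetime import date

from ecoqi import LandscapeSpec, generate_series, rsei_single_scene
from ecoqi.indicators import compute_indicator_stack

spec = LandscapeSpec(rows=64, cols=64, seed=42, dates=(date(2018, 10, 15),))
scenes, lucc, truth = generate_series(spec)
scene = scenes[0]

stack = compute_indicator_stack(scene)
print(f"scene {scene.acquisition_date}, {scene.valid_mask.sum()} valid pixels")
for name in ("ndvi", "ndbsi", "wet", "lst"):
    values = stack.indicator(name).valid_values()
    print(f"  {name:6s} range [{values.min():8.3f}, {values.max():8.3f}]")

rsei = rsei_single_scene(scene, seed=0)
print("\nOctober RSEI class means (0 = worst, 1 = best):")
for cls in truth.quality_ordering:
    sel = (truth.class_map == cls) & rsei.mask
    print(f"  {cls:22s} {rsei.data[sel].mean():.3f}")
print("\nForest far outranks winter wheat here - an artefact of the single")
print("October date, not of the annual ecological quality (see example 02).")
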