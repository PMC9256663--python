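"""Candidate-frame selection on a synthetic flow-through stream.

Most frames of a flow-through recording are empty background; a moving
average over the surrounding 50 frames models the background, and frames
with a large connected foreground blob are selected for segmentation.
"""

from ichthyoflow import PixelScale, SelectionConfig, select_candidates
from ichthyoflow.synthetic import render_stream

stream, truth = render_stream(n_frames=200, n_objects=12, n_distractors=20, seed=3)
config = SelectionConfig(scale=PixelScale(0.012), window=50, threshold=25,
                         min_area_mm2=0.2)
candidates = select_candidates(stream, config)

selected = {c.index for c in candidates if c.selected}
true_set = set(truth.object_frames)
print(f"frames in stream      : {len(stream)}")
print(f"frames with an object : {sorted(true_set)}")
print(f"frames selected       : {sorted(selected)}")
print(f"recall                : {len(selected & true_set)}/{len(true_set)}")
print(f"false selections      : {len(selected - true_set)}")
# The 20 distractor blobs (bubbles, fibres) are below the 0.2 mm^2 minimum
# blob area and must not trigger a selection.
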