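"""Render one ground-truthed synthetic coculture field.

Builds a 4-channel (Hoechst / NeuO / IB4 / DRAQ7) field with the seven
object classes and prints the exact per-class ground truth the renderer
guarantees by construction.
"""

import gliascreen as gs

spec = gs.SceneSpec(seed=1)
stack, truth = gs.render_field(spec)

print(f"field size: {stack.shape}, channels: {list(stack.channels)}")
print(f"objects rendered: {truth.n_objects}")
for cls, n in truth.true_counts.items():
    print(f"  {cls:10s} {n:4d}")
print("Counts are exact: the label mask, class list and centroids are the")
print("ground truth every downstream stage is scored against.")
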