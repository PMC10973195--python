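"""Segment nuclei and score the result against ground truth.

Shows the declumping gap: on a field where 30% of neurons touch another
nucleus, the distance-transform watershed cuts split/merge errors well
below the plain connected-components variant.
"""

import gliascreen as gs

stack, truth = gs.render_field(gs.SceneSpec(seed=3, clump_fraction=0.3))

for declump in (True, False):
    mask = gs.segment_nuclei(stack["hoechst"], declump=declump)
    sc = gs.score_segmentation(mask, truth.label_mask, iou_match=0.5)
    name = "declump " if declump else "plain   "
    print(f"{name}: correct {sc.correct:3d}/{sc.n_truth}, "
          f"over {sc.over_segmented}, under {sc.under_segmented}, "
          f"missed {sc.missed}, spurious {sc.spurious}")
print("'correct' = one-to-one match at IoU >= 0.5; over/under = split/merged")
print("objects; the declumping variant should show far fewer of those.")
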