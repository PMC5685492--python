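"""Build the adaptive shape prior and inspect its certainty.

For every brain voxel the prior searches a small cube around the
corresponding atlas position, over all training subjects, for voxels whose
(equalized) intensity matches within +-tau, and turns the labels of the
matches into a probability vector.
"""

import numpy as np

import brainseg as bs
from brainseg.shape_prior import PriorSearchParams

spec = bs.adult_spec(grid_shape=(48, 48, 48), seed=2)
training = bs.generate_training_set(spec, 6)
test = bs.generate_test_subject(spec)

equalized = [
    bs.SubjectPair(bs.equalize_to_reference(s.grey, test.grey), s.labels)
    for s in training
]
prior = bs.build_adaptive_prior(
    test.grey, equalized, params=PriorSearchParams(tau=10)
)

brain = test.grey.values > 0
certainty = prior.probs[brain].max(axis=1)
agree = prior.argmax_labels()[brain] == test.labels.values[brain]
print(f"brain voxels: {brain.sum()}")
print(f"mean per-voxel max probability: {certainty.mean():.3f}")
print(f"prior argmax agreement with ground truth: {agree.mean():.4f}")
print("(the prior alone nearly classifies the phantom; ambiguity concentrates")
print(" at shell boundaries, which the intensity and spatial terms resolve)")
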