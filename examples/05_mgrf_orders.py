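"""Second-order vs higher-order MGRF on a low-contrast infant phantom.

The higher-order model (triple + quad cliques on top of the pairwise ones)
is a stronger spatial regularizer.  Whether it helps depends on how good the
initial map is: started from intensity alone (isointense GM/WM, no shape
prior) it repairs large speckle errors that the pairwise model cannot;
started from the adaptive shape prior's already-accurate map, its extra
smoothing instead erodes fine structure.  This script shows both regimes.
"""

import numpy as np

import brainseg as bs
from brainseg.lcdg import empirical_density, fit_lcdg, partition_classes
from brainseg.mgrf import enumerate_families, estimate_potentials
from brainseg.segmenter import icm_refine, initial_map
from brainseg.shape_prior import ShapePriorField

spec = bs.infant_spec(grid_shape=(48, 48, 48), seed=0)
training = bs.generate_training_set(spec, 8)
test = bs.generate_test_subject(spec)

print("full pipeline (adaptive shape prior):")
res = bs.compare_mgrf_orders(test.grey, training, bs.SegmenterParams())
for order in (2, 4):
    print(f"  order {order}: WM DSC {bs.dsc(res[order], test.labels, 3):.4f}")

print("intensity-only initialization (uniform prior):")
g = test.grey
probs = np.zeros((*g.shape, 4))
probs[..., 0] = 1.0
probs[g.values > 0] = [0.0, 1 / 3, 1 / 3, 1 / 3]
prior = ShapePriorField(probs, g.spacing, g.affine)
classes = partition_classes(fit_lcdg(empirical_density(g), K=4), 3)
m0 = initial_map(prior, classes, g)
print(f"  initial map WM DSC {bs.dsc(m0, test.labels, 3):.4f}")
for order in (2, 4):
    fams = enumerate_families(order)
    table = estimate_potentials(m0, fams)
    out = icm_refine(g, m0, prior, classes, table, fams)
    print(f"  order {order}: WM DSC {bs.dsc(out.labels, test.labels, 3):.4f}")
print("(the higher-order advantage appears when initialization is poor,")
print(" the regime low-contrast clinical scans actually occupy)")
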