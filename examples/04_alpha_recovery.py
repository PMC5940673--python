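"""Parameter recovery: feature gain tracks the generative sharpening strength.

Sweeps the sharpening parameter alpha over {0, 0.3, 0.6, 0.9} with common
random numbers (identical images, encoding weights and noise draws; only
the represented test features move toward the original), reusing the
decoders trained on the shared training runs.  The cohort-mean feature gain
should increase monotonically with alpha - the analysis recovers the
injected sharpening.
"""

import logging

from featuregain.studies import run_alpha_sweep, run_depth_study

logging.disable(logging.WARNING)

sweep = run_alpha_sweep(alphas=(0.0, 0.3, 0.6, 0.9), master_seed=5)
print("cohort-mean feature gain vs injected sharpening alpha:")
print(sweep.round(4).to_string(index=False))

depth = run_depth_study(master_seed=5, deep_alpha=0.6)
print("\ndeep-only sharpening (alpha = 0.6 on the deepest layer only):")
print(depth[["layer", "mean_gain"]].round(4).to_string(index=False))
print("\nthe gain concentrates in the deepest layer, localizing the "
      "injected effect in the hierarchy")
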