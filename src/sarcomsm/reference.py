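"""Published reference quantities from the CHARLS sarcopenia-transition study.

These are the estimates reported for the 2011/2013/2015 CHARLS analytic
sample of 2856 community-dwelling Chinese adults aged 60+, staged with the
AWGS-2019 algorithm.  They serve as inputs for desk-scale consistency checks
(matrix exponentials, sojourn times, table arithmetic) and as the "truth"
generator for synthetic-cohort recovery studies; the microdata themselves are
restricted and not redistributed here.

States: 1 = no sarcopenia, 2 = possible sarcopenia, 3 = sarcopenia, 4 = death.
"""

from __future__ import annotations

import numpy as np

from .msm import DEFAULT_STRUCTURE, build_intensity_matrix

# Estimated transition intensities (per year), off-diagonal entries
REFERENCE_INTENSITIES: dict[tuple[int, int], float] = {
    (1, 2): 0.176, (1, 3): 0.043, (1, 4): 0.013,
    (2, 1): 0.388, (2, 3): 0.028, (2, 4): 0.045,
    (3, 1): 0.199, (3, 2): 0.053, (3, 4): 0.089,
}


def reference_intensity_matrix() -> np.ndarray:
    """The published generator matrix (diagonals = negative row sums)."""
    return build_intensity_matrix(DEFAULT_STRUCTURE, REFERENCE_INTENSITIES)


# Observed transition counts between consecutive waves (origin -> destination)
REFERENCE_TRANSITION_COUNTS: dict[tuple[int, int], int] = {
    (1, 1): 2202, (1, 2): 584, (1, 3): 173, (1, 4): 103,
    (2, 1): 763, (2, 2): 859, (2, 3): 82, (2, 4): 136,
    (3, 1): 154, (3, 2): 53, (3, 3): 317, (3, 4): 88,
}

# Baseline staging of the analytic sample
BASELINE_STATE_COUNTS: dict[int, int] = {1: 1505, 2: 1019, 3: 332}
BASELINE_N = 2856
BASELINE_STATE_MIX = (0.527, 0.357, 0.116)

# Wave schedule: three biennial waves
REFERENCE_WAVES = (0.0, 2.0, 4.0)

# Baseline covariate distributions of the analytic sample
REFERENCE_COVARIATES: dict[str, tuple] = {
    "female": ("bernoulli", 0.484),
    "rural": ("bernoulli", 0.697),
    "age": ("normal", 67.6, 6.1),
    "bmi": ("normal", 22.7, 3.8),
    "cognition": ("normal", 12.6, 5.7),
}
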