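"""Compute CytAct and the IFN-gamma score from an expression matrix.

Generates synthetic log2 expression for 30 samples whose GZMA/PRF1 levels
track a known latent immune score, then checks that the computed CytAct
(mean of the two z-scored genes) recovers that score.
"""

import numpy as np
from scipy import stats as sps

from immunopet import cytact, gen_expression, ifng_score

u = np.random.default_rng(0).normal(size=30)  # ground-truth immune score
mat = gen_expression(u, noise_sd=0.15, corr_ifng=0.5, rng_seed=1)

cyt = cytact(mat)
ifng = ifng_score(mat)

print(f"samples                    : {mat.n_samples}")
print(f"CytAct cohort mean         : {cyt.mean():+.2e} (z-scores average to 0)")
print(f"Spearman(CytAct, true u)   : {sps.spearmanr(cyt, u).statistic:.3f}")
print(f"Spearman(CytAct, IFNG)     : {sps.spearmanr(cyt, ifng).statistic:.3f}")
# CytAct tracks the latent score almost perfectly at this noise level; its
# correlation with the 6-gene IFN-gamma score reflects the generator's
# corr_ifng target (0.5), mirroring how the two signatures co-vary in tumors.
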