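"""Explicit-rank truncation of the tubal SVD and its error identity.

All hat-domain singular values, from every frontal face, are pooled into
one global ranking; rank-q truncation keeps the q largest regardless of
which face they come from.  With an orthonormal mixing matrix the
truncation error obeys ‖A − A_q‖_F² = Σ_{h>q} σ̂_h², exactly as in the
matrix Eckart–Young theorem.
"""

import numpy as np

from tcam import (
    make_m_transform,
    planted_rank_tensor,
    ranking_vector,
    truncate_explicit_rank,
    tsvdm,
)

mt = make_m_transform(4, "dct2")
a = planted_rank_tensor(m=6, p=9, n=4, q=5, mt=mt, seed=2)
factors = tsvdm(a, mt)
rank = ranking_vector(factors.s_hat)

nonzero = int(np.sum(factors.s_hat > 1e-8 * factors.s_hat.max()))
print(f"planted explicit rank 5, recovered {nonzero} nonzero singular values")

print(" q   ||A - A_q||_F    sqrt(sum of dropped sigma^2)")
for q in (0, 1, 3, 5, 8):
    aq = truncate_explicit_rank(factors, q, rank.pairs()).reconstruct()
    err = np.linalg.norm(a - aq)
    ident = np.sqrt(np.sum(rank.sigma[q:] ** 2))
    print(f"{q:2d}   {err:12.6f}    {ident:12.6f}")
# At q = 5 (the planted rank) the error drops to ~1e-16: the truncation
# is lossless, and the two columns agree at every q.
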