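"""Randomised-response (permutation) validation of PLS calibrations.

A calibration fitted on a handful of samples can look excellent by chance.
The guard implemented here refits the entire pipeline -- preprocessing,
factor selection, leave-one-out CV -- on uniformly shuffled temperatures and
compares the observed cross-validated r^2 against that null distribution.
Models whose apparent skill is not clearly above the shuffled baseline are
flagged as spurious and refuse to predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .pls import loo_cv
from .spectra import SpectralMatrix

__all__ = ["PermutationResult", "permutation_null", "accept_model"]


@dataclass
class PermutationResult:
    observed_r2: float
    null_r2: list[float]
    p_value: float
    n_perm: int
    seed: int


def permutation_null(
    X,
    y,
    f_max: int = 4,
    n_perm: int = 199,
    seed: int = 0,
    window: int = 5,
    use_snv: bool = True,
    r2_mode: str = "pearson",
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation test of the cross-validated r^2.

    Each of the ``n_perm`` shuffles reruns the full honest pipeline
    (per-fold preprocessing refit, AIC factor selection, LOO CV) on the same
    spectra with temperatures in permuted order, so every null fit sees
    exactly the calibration temperatures as a multiset.  Shuffles are drawn
    with replacement over the permutation group (standard Monte-Carlo
    practice; the identity may recur at small n).  The p-value uses the
    add-one formula (1 + #{null >= observed}) / (n_perm + 1), which can never
    be exactly zero.

    With ``exhaustive=True`` (n <= 7 only) every one of the n! orders is
    evaluated instead, and p = #{null >= observed} / n!, where the identity
    order guarantees at least one count.
    """
    values = X.values if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, dtype=float)
    observed = loo_cv(values, y, f_max, window, use_snv, r2_mode).r2
    if exhaustive:
        n = len(y)
        if n > 7:
            raise ValidationError("exhaustive enumeration is limited to n <= 7")
        from itertools import permutations
        from math import factorial

        null = [
            loo_cv(values, np.asarray(order), f_max, window, use_snv, r2_mode).r2
            for order in permutations(y)
        ]
        p = float(np.sum(np.asarray(null) >= observed)) / factorial(n)
        return PermutationResult(float(observed), [float(v) for v in null], p, len(null), seed)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        null.append(loo_cv(values, y_perm, f_max, window, use_snv, r2_mode).r2)
    exceed = int(np.sum(np.asarray(null) >= observed))
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(float(observed), [float(v) for v in null], float(p), n_perm, seed)


def accept_model(perm: PermutationResult, alpha: float = 0.05):
    """Verdict on a calibration: accepted iff the permutation p-value < alpha."""
    ok = perm.p_value < alpha
    reason = (
        f"observed CV r2={perm.observed_r2:.4f}, permutation p={perm.p_value:.4f} "
        f"vs alpha={alpha:g} -> {'accepted' if ok else 'rejected (spurious)'}"
    )
    return ok, reason
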