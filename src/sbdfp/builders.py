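"""Statistical core: bit counting, the two-proportion Z-test, and the DFP /
SB-DFP condensation rules.

The classic database fingerprint (DFP) sets a bit when it occurs in at least
a fixed fraction (default 50%) of the molecules in a set.  The
statistical-based database fingerprint (SB-DFP) instead sets a bit only when
its "1"-frequency in the target set is *statistically* higher than in a
large reference collection, judged by a pooled one-sided two-proportion
Z-test at significance level ``alpha`` (default 0.01, i.e. 99% confidence).

The test statistic for one bit, with target frequency p_t over n_t molecules
and reference frequency p_r over n_r molecules, is

    z = (p_t - p_r) / sqrt( P (1 - P) (1/n_t + 1/n_r) )

where P = (n_t p_t + n_r p_r) / (n_t + n_r) is the pooled proportion, and
the one-sided p-value is 1 - Phi(z) under the alternative "target larger".
No multiple-testing correction is applied across bits: alpha is a tunable
operating point, selected in practice by downstream screening performance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core import (
    METHOD_DFP,
    METHOD_SBDFP,
    BitCountProfile,
    BitMatrix,
    DatabaseFingerprint,
    ZTestResult,
    check_same_scheme,
)

__all__ = [
    "count_bits",
    "two_proportion_ztest",
    "ztest_pvalues",
    "build_dfp",
    "build_sbdfp",
    "min_significant_count",
    "UNATTAINABLE",
]

#: sentinel returned by :func:`min_significant_count` when no count in
#: [0, n_t] reaches significance.
UNATTAINABLE = None


def count_bits(matrix: BitMatrix) -> BitCountProfile:
    """Per-bit "1"-counts of a fingerprint matrix.

    ``counts[j]`` is the number of molecules with bit ``j`` set and ``n_obs``
    is the number of molecules; the scheme tag is propagated.
    """
    if matrix.n_molecules < 1:
        raise ValueError("cannot profile an empty bit matrix: no observations")
    return BitCountProfile(
        counts=matrix.rows.sum(axis=0, dtype=np.int64),
        n_obs=matrix.n_molecules,
        scheme_tag=matrix.scheme_tag,
    )


def _validate_counts(count, n, side: str) -> None:
    count = np.asarray(count)
    if np.asarray(n).min() < 1:
        raise ValueError(f"{side}: number of observations must be >= 1")
    if (count < 0).any() or (count > n).any():
        raise ValueError(f"{side}: counts must lie in [0, n]")


def ztest_pvalues(
    counts_t, n_t: int, counts_r, n_r: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled one-sided two-proportion Z-test.

    Returns ``(z, p_one_sided)`` arrays, broadcasting over the count inputs.
    Degenerate bits where the pooled proportion is 0 or 1 (which forces
    p_t == p_r) get ``z = 0`` and ``p = 0.5``, the continuous limit of the
    equal-proportion case.
    """
    counts_t = np.asarray(counts_t, dtype=float)
    counts_r = np.asarray(counts_r, dtype=float)
    _validate_counts(counts_t, n_t, "target")
    _validate_counts(counts_r, n_r, "reference")
    p_t = counts_t / n_t
    p_r = counts_r / n_r
    pooled = (counts_t + counts_r) / (n_t + n_r)
    var = pooled * (1.0 - pooled) * (1.0 / n_t + 1.0 / n_r)
    safe = var > 0
    z = np.where(safe, (p_t - p_r) / np.sqrt(np.where(safe, var, 1.0)), 0.0)
    return z, norm.sf(z)


def two_proportion_ztest(
    count_t: int, n_t: int, count_r: int, n_r: int
) -> ZTestResult:
    """Pooled one-sided two-proportion Z-test for a single bit.

    Tests whether the target "1"-proportion ``count_t / n_t`` is higher than
    the reference proportion ``count_r / n_r`` (alternative: target larger).

    Examples
    --------
    >>> r = two_proportion_ztest(268, 350, 10892579, 15403690)
    >>> round(r.p_one_sided, 3)
    0.008
    """
    z, p = ztest_pvalues(count_t, n_t, count_r, n_r)
    return ZTestResult(
        z=float(z),
        p_one_sided=float(p),
        pooled_p=float((count_t + count_r) / (n_t + n_r)),
        p_t=count_t / n_t,
        p_r=count_r / n_r,
    )


def build_dfp(profile: BitCountProfile, threshold: float = 0.5) -> DatabaseFingerprint:
    """Classic database fingerprint: bit set iff present in at least
    ``threshold`` of the molecules (``counts[j]/n_obs >= threshold``; an
    exact tie sets the bit)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    bits = (profile.counts >= threshold * profile.n_obs).astype(np.uint8)
    return DatabaseFingerprint(
        bits=bits,
        method=METHOD_DFP,
        param=threshold,
        n_source=profile.n_obs,
        scheme_tag=profile.scheme_tag,
    )


def build_sbdfp(
    target_profile: BitCountProfile,
    reference_profile: BitCountProfile,
    alpha: float = 0.01,
) -> DatabaseFingerprint:
    """Statistical-based database fingerprint.

    Bit ``j`` is set iff the one-sided two-proportion Z-test of the target
    count against the reference count yields ``p < alpha`` (strict, matching
    the "p value < 0.01" operating point), which entails p_t > p_r.
    """
    check_same_scheme(target_profile, reference_profile)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    _, p = ztest_pvalues(
        target_profile.counts,
        target_profile.n_obs,
        reference_profile.counts,
        reference_profile.n_obs,
    )
    return DatabaseFingerprint(
        bits=(p < alpha).astype(np.uint8),
        method=METHOD_SBDFP,
        param=alpha,
        n_source=target_profile.n_obs,
        scheme_tag=target_profile.scheme_tag,
    )


def min_significant_count(
    n_t: int, count_r: int, n_r: int, alpha: float
) -> int | None:
    """Smallest target count reaching significance against the reference.

    Returns the smallest integer ``k`` in ``[0, n_t]`` such that
    ``two_proportion_ztest(k, n_t, count_r, n_r).p_one_sided < alpha``, or
    :data:`UNATTAINABLE` (``None``) when no count qualifies.  For the
    reference bit with 10,892,579 "1"s in 15,403,690 molecules and a target
    set of 350, the answer at alpha = 0.01 is 268.

    The p-value is non-increasing in the target count, so a binary search
    finds the boundary; the result is verified against the definitional
    boundary property and falls back to an exhaustive scan if numerical
    noise ever violates monotonicity.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    _validate_counts(np.asarray(count_r), n_r, "reference")
    if n_t < 1:
        raise ValueError("target set size must be >= 1")

    def pval(k: int) -> float:
        _, p = ztest_pvalues(k, n_t, count_r, n_r)
        return float(p)

    if not pval(n_t) < alpha:
        return UNATTAINABLE
    lo, hi = 0, n_t  # invariant: pval(hi) < alpha
    while lo < hi:
        mid = (lo + hi) // 2
        if pval(mid) < alpha:
            hi = mid
        else:
            lo = mid + 1
    k = hi
    # definitional boundary check; scan if the monotone assumption failed
    if pval(k) < alpha and (k == 0 or not pval(k - 1) < alpha):
        return k
    _, p = ztest_pvalues(np.arange(n_t + 1), n_t, count_r, n_r)
    hits = np.nonzero(p < alpha)[0]
    return int(hits[0]) if hits.size else UNATTAINABLE
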