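"""Permutation-based two-group comparison of perfusion parameters.

Two tests are provided, mirroring common neuroimaging practice:

* a whole-brain scalar test: difference of group means, with the null
  distribution built by relabelling subjects (equivalent to a permutation
  test of the group factor in a two-group linear model);
* a voxel-wise test: a pooled-variance two-sample t statistic per voxel,
  with uncorrected p-values from each voxel's permutation distribution and
  family-wise-error (FWE) corrected p-values from the permutation
  distribution of the maximal |t| over the mask.

When the number of distinct group labelings is no larger than the
requested permutation count the null is enumerated exactly (p is then a
rational with the enumeration size as denominator); otherwise labelings
are sampled Monte-Carlo with the add-one convention
p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_draws), which keeps p in
(0, 1].  All randomness derives from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np

from .errors import InputError, UndefinedSummaryError
from .metrics import PerfusionMaps

__all__ = [
    "PermutationResult",
    "VoxelwisePermutationResult",
    "whole_brain_mean",
    "permutation_test_scalar",
    "permutation_test_voxelwise",
]


@dataclass
class PermutationResult:
    """Observed statistic and permutation p-value of a scalar test."""

    statistic: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: Optional[int] = None


@dataclass
class VoxelwisePermutationResult:
    """Voxel-wise t map with uncorrected and max-statistic FWE p maps."""

    t_map: np.ndarray
    p_map: np.ndarray
    p_fwe_map: np.ndarray
    n_permutations: int
    exact: bool
    seed: Optional[int] = None


def whole_brain_mean(maps: PerfusionMaps, mask: Optional[np.ndarray] = None) -> dict:
    """Mean of each perfusion metric over valid (and optionally masked)
    voxels.

    Raises UndefinedSummaryError when no valid voxel remains.
    """
    sel = maps.valid.copy()
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != sel.shape:
            raise InputError("mask grid does not match maps")
        sel &= mask
    if not sel.any():
        raise UndefinedSummaryError("no valid voxels to average")
    return {name: float(vol[sel].mean()) for name, vol in maps.metric_dict().items()}


def _labelings(n_total: int, n_a: int, n_perm: int, seed: Optional[int]):
    """Yield (index-arrays for group A, n_draws, exact flag).

    Exact enumeration of all C(n, n_a) labelings when that count does not
    exceed n_perm, else n_perm Monte-Carlo draws.
    """
    total = comb(n_total, n_a)
    if total <= n_perm:
        idx = np.array(list(combinations(range(n_total), n_a)), dtype=int)
        return idx, total, True
    rng = np.random.default_rng(seed)
    # random labelings as the first n_a ranks of i.i.d. uniforms per row
    idx = np.argsort(rng.random((n_perm, n_total)), axis=1)[:, :n_a]
    return idx, n_perm, False


def permutation_test_scalar(
    a,
    b,
    n_perm: int = 100_000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Two-group permutation test on scalars; statistic = mean(a) - mean(b).

    With exact enumeration the observed labeling is one of the enumerated
    ones, so p = #{|T| >= |T_obs|} / n_labelings; Monte-Carlo sampling
    uses the add-one convention.  Degenerate inputs (identical groups)
    give p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InputError("need at least 2 subjects per group")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    obs = float(a.mean() - b.mean())

    idx, n_draws, exact = _labelings(n, na, n_perm, seed)
    sum_a = pooled[idx].sum(axis=1)
    total = pooled.sum()
    stats = sum_a / na - (total - sum_a) / (n - na)
    # tiny tolerance so exact mirror labelings are not lost to summation
    # round-off (keeps p invariant under subject reordering)
    count = int(np.sum(np.abs(stats) >= abs(obs) * (1.0 - 1e-12) - 1e-300))
    if exact:
        p = count / n_draws
    else:
        p = (1 + count) / (1 + n_draws)
    return PermutationResult(
        statistic=obs, p_value=float(p), n_permutations=n_draws, exact=exact, seed=seed
    )


def _t_from_sums(sa, sa2, sb, sb2, na, nb):
    """Pooled-variance two-sample t from per-group sums and sums of squares.

    Zero-variance, zero-difference voxels give t = 0; zero variance with a
    mean difference gives ±inf (both handled consistently downstream).
    """
    ma = sa / na
    mb = sb / nb
    ssa = sa2 - na * ma**2
    ssb = sb2 - nb * mb**2
    dof = na + nb - 2
    pooled = (ssa + ssb) / dof
    pooled = np.maximum(pooled, 0.0)
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t = np.where(denom == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t


def permutation_test_voxelwise(
    group_a,
    group_b,
    mask: np.ndarray,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    block: int = 256,
) -> VoxelwisePermutationResult:
    """Voxel-wise two-sample permutation test with max-statistic FWE control.

    Parameters
    ----------
    group_a, group_b : sequences of 3-D arrays (one map per subject)
    mask : 3-D boolean array selecting the voxels tested
    n_perm : permutation budget (exact enumeration if it covers all
        labelings)
    seed : integer seed for the Monte-Carlo path
    block : number of permutations processed per vectorised block

    Returns maps of t, uncorrected p and FWE-corrected p (NaN outside the
    mask), all deterministic given the seed.
    """
    a = np.stack([np.asarray(v, dtype=float) for v in group_a])
    b = np.stack([np.asarray(v, dtype=float) for v in group_b])
    if a.shape[1:] != b.shape[1:]:
        raise InputError("group maps are on different grids")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != a.shape[1:]:
        raise InputError("mask grid does not match maps")
    if not mask.any():
        raise InputError("empty mask")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InputError("need at least 2 subjects per group")

    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    X = np.concatenate([a[:, mask], b[:, mask]], axis=0)  # (n, V)
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite values inside the mask")
    X2 = X**2
    col_sum = X.sum(axis=0)
    col_sum2 = X2.sum(axis=0)

    obs_t = _t_from_sums(
        X[:na].sum(axis=0), X2[:na].sum(axis=0),
        X[na:].sum(axis=0), X2[na:].sum(axis=0), na, nb,
    )
    obs_abs = np.abs(obs_t)
    # threshold with a tiny tie tolerance (see permutation_test_scalar)
    obs_thr = np.where(
        np.isfinite(obs_abs), obs_abs * (1.0 - 1e-12) - 1e-300, obs_abs
    )

    idx, n_draws, exact = _labelings(n, na, n_perm, seed)
    ge_count = np.zeros(X.shape[1], dtype=np.int64)
    max_ge_count = np.zeros(X.shape[1], dtype=np.int64)
    for start in range(0, n_draws, block):
        sel = idx[start:start + block]  # (B, na)
        ind = np.zeros((sel.shape[0], n))
        np.put_along_axis(ind, sel, 1.0, axis=1)
        sa = ind @ X
        sa2 = ind @ X2
        t = _t_from_sums(sa, sa2, col_sum - sa, col_sum2 - sa2, na, nb)
        at = np.abs(t)
        ge_count += (at >= obs_thr).sum(axis=0)
        max_t = at.max(axis=1)  # (B,)
        max_ge_count += (max_t[:, None] >= obs_thr[None, :]).sum(axis=0)

    if exact:
        p_unc = ge_count / n_draws
        p_fwe = max_ge_count / n_draws
    else:
        p_unc = (1 + ge_count) / (1 + n_draws)
        p_fwe = (1 + max_ge_count) / (1 + n_draws)

    def to_map(vec, dtype=float):
        out = np.full(mask.shape, np.nan, dtype=dtype)
        out[mask] = vec
        return out

    return VoxelwisePermutationResult(
        t_map=to_map(obs_t),
        p_map=to_map(p_unc),
        p_fwe_map=to_map(p_fwe),
        n_permutations=n_draws,
        exact=exact,
        seed=seed,
    )
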