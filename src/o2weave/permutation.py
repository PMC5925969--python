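"""Permutation null distributions and influence selection for joint loadings.

The cross-block association is destroyed by permuting the sample rows of one
block (Y) while the other stays fixed; each block keeps its internal
covariance, so the resulting loading distribution is the null for "feature
contributes to the JOINT variation".  The full O2PLS fit is recomputed for
every permutation and the sign-fixed joint loadings of both blocks are pooled
per block and per joint component.  The empirical alpha/2 and 1 - alpha/2
quantiles of each pool become the lower/upper thresholds for that latent
variable, and a feature is flagged as influential when its observed loading
falls outside the interval on any joint component.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import OmicsBlock
from .o2pls import O2PLSConfig, O2PLSError, O2PLSModel, _fit_arrays

log = logging.getLogger(__name__)

__all__ = [
    "PermutationNull",
    "InfluenceSelection",
    "permutation_null",
    "select_influential",
]


@dataclasses.dataclass
class PermutationNull:
    """Null loading pools and quantile thresholds.

    ``pools_x`` has shape ``(n_joint, n_perm * p)`` (one pooled loading
    distribution per joint component of the X block), ``thresholds_x`` shape
    ``(n_joint, 2)`` with columns (lower, upper); likewise for Y.
    """

    n_perm: int
    alpha: float
    seed: int
    config: O2PLSConfig
    pools_x: np.ndarray
    pools_y: np.ndarray
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray

    def __post_init__(self) -> None:
        for thr in (self.thresholds_x, self.thresholds_y):
            if np.any(thr[:, 0] > thr[:, 1]):
                raise ValueError("lower threshold exceeds upper threshold")

    def with_alpha(self, alpha: float) -> "PermutationNull":
        """Re-derive thresholds from the stored pools at a different alpha."""
        if not 0 < alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        return PermutationNull(
            n_perm=self.n_perm,
            alpha=alpha,
            seed=self.seed,
            config=self.config,
            pools_x=self.pools_x,
            pools_y=self.pools_y,
            thresholds_x=_quantile_thresholds(self.pools_x, alpha),
            thresholds_y=_quantile_thresholds(self.pools_y, alpha),
        )


@dataclasses.dataclass
class InfluenceSelection:
    """Per feature x component records plus distinct-feature summary counts.

    ``records`` columns: block, feature_id, component, loading, flagged.
    ``summary`` maps block name to the number of distinct flagged features.
    """

    records: pd.DataFrame
    summary: dict[str, int]
    x_name: str
    y_name: str

    def flagged_features(self, block: str) -> list[str]:
        sub = self.records[(self.records["block"] == block) & self.records["flagged"]]
        return list(dict.fromkeys(sub["feature_id"]))

    def flag_matrix(self, which: str) -> np.ndarray:
        """Boolean (n_features x n_joint) flag matrix for block "x" or "y"."""
        name = self.x_name if which == "x" else self.y_name
        sub = self.records[self.records["block"] == name]
        pivot = sub.pivot(index="feature_id", columns="component", values="flagged")
        features = list(dict.fromkeys(sub["feature_id"]))
        return pivot.loc[features].to_numpy(dtype=bool)


def _quantile_thresholds(pools: np.ndarray, alpha: float) -> np.ndarray:
    """(lower, upper) = inclusive empirical alpha/2 and 1 - alpha/2 quantiles,
    linear interpolation between order statistics."""
    lo = np.quantile(pools, alpha / 2.0, axis=1, method="linear")
    hi = np.quantile(pools, 1.0 - alpha / 2.0, axis=1, method="linear")
    return np.column_stack([lo, hi])


def permutation_null(
    X: OmicsBlock | np.ndarray,
    Y: OmicsBlock | np.ndarray,
    config: O2PLSConfig,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    permutations=None,
) -> PermutationNull:
    """Build the permutation null for the joint loadings.

    For each of ``n_perm`` draws, the Y block's rows are permuted by a
    uniformly random permutation (sampled with replacement from the
    permutation group; X stays fixed), the full O2PLS model is refitted, and
    the sign-fixed joint loadings are pooled.  Inputs must already carry the
    same preprocessing as the observed fit.  Deterministic given ``seed``.

    ``permutations`` overrides the random draws with an explicit sequence of
    row-index arrays (for audit; its length replaces ``n_perm``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    x_arr = X.values if isinstance(X, OmicsBlock) else np.asarray(X, dtype=float)
    y_arr = Y.values if isinstance(Y, OmicsBlock) else np.asarray(Y, dtype=float)
    n, p = x_arr.shape
    q = y_arr.shape[1]
    a = config.n_joint
    if permutations is not None:
        permutations = [np.asarray(pi, dtype=int) for pi in permutations]
        n_perm = len(permutations)

    min_pool = min(p, q) * n_perm
    if min_pool * (alpha / 2.0) < 5:
        log.warning(
            "pool size %d gives fewer than 5 points beyond the alpha/2 quantile; "
            "thresholds will be noisy (increase n_perm)",
            min_pool,
        )

    rng = np.random.default_rng(seed)
    pools_x = np.empty((a, n_perm * p))
    pools_y = np.empty((a, n_perm * q))
    for b in range(n_perm):
        perm = permutations[b] if permutations is not None else rng.permutation(n)
        model = _fit_arrays(x_arr, y_arr[perm], config)
        pools_x[:, b * p : (b + 1) * p] = model.W.T
        pools_y[:, b * q : (b + 1) * q] = model.C.T
    return PermutationNull(
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        config=config,
        pools_x=pools_x,
        pools_y=pools_y,
        thresholds_x=_quantile_thresholds(pools_x, alpha),
        thresholds_y=_quantile_thresholds(pools_y, alpha),
    )


def _block_records(
    block_name: str,
    feature_ids: list[str],
    loadings: np.ndarray,
    thresholds: np.ndarray,
) -> pd.DataFrame:
    p, a = loadings.shape
    flagged = (loadings < thresholds[:, 0]) | (loadings > thresholds[:, 1])
    return pd.DataFrame(
        {
            "block": np.repeat(block_name, p * a),
            "feature_id": np.tile(feature_ids, a),
            "component": np.repeat(np.arange(1, a + 1), p),
            "loading": loadings.T.ravel(),
            "flagged": flagged.T.ravel(),
        }
    )


def select_influential(model: O2PLSModel, null: PermutationNull) -> InfluenceSelection:
    """Flag the most influential features of a fitted model.

    A feature is flagged when its observed loading on ANY joint component
    falls outside that component's (lower, upper) null interval; records are
    emitted for every feature x component pair, and the summary counts
    distinct flagged features per block.
    """
    if model.n_joint != null.thresholds_x.shape[0]:
        raise O2PLSError(
            f"model has {model.n_joint} joint components but the null has "
            f"{null.thresholds_x.shape[0]}"
        )
    if model.config != null.config:
        raise O2PLSError("model and null were built with different component configurations")
    x_ids = model.x_feature_ids or [f"x{j}" for j in range(model.W.shape[0])]
    y_ids = model.y_feature_ids or [f"y{j}" for j in range(model.C.shape[0])]
    rec_x = _block_records(model.x_name, x_ids, model.W, null.thresholds_x)
    rec_y = _block_records(model.y_name, y_ids, model.C, null.thresholds_y)
    records = pd.concat([rec_x, rec_y], ignore_index=True)
    summary = {
        model.x_name: int(rec_x[rec_x["flagged"]]["feature_id"].nunique()),
        model.y_name: int(rec_y[rec_y["flagged"]]["feature_id"].nunique()),
    }
    return InfluenceSelection(
        records=records, summary=summary, x_name=model.x_name, y_name=model.y_name
    )
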