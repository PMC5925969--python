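"""Block preprocessing for two-block integration.

Three steps, applied per block before fitting:

1. mean-center every feature (both blocks);
2. optionally scale every feature to unit variance (the metabolome block,
   where peak intensities live on wildly different scales);
3. rescale the whole block so its total sum of squares equals a common
   target (default 1), so neither block dominates the joint fit simply by
   having more features or larger units.

A fitted :class:`PreprocessRecipe` stores the means, standard deviations and
block scale factor so a run can be reproduced or serialized exactly.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .io import OmicsBlock

__all__ = [
    "PreprocessError",
    "PreprocessRecipe",
    "fit_preprocess",
    "apply_preprocess",
    "preprocess_block",
    "preprocess_pair",
    "log2_transform",
]

_SD_DDOF = 1  # sample standard deviation (n-1 denominator)


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class PreprocessRecipe:
    """Fitted preprocessing parameters for one block."""

    block_name: str
    feature_ids: list[str]
    center: bool
    uv_scale: bool
    ss_target: float
    means: np.ndarray
    sds: np.ndarray | None
    block_scale: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
            if np.any(self.sds <= 0):
                raise PreprocessError("fitted standard deviations must be positive")
        if len(self.feature_ids) != self.means.shape[0]:
            raise PreprocessError("means length does not match feature count")
        if self.block_scale <= 0:
            raise PreprocessError("block scale factor must be positive")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "block_name": self.block_name,
            "feature_ids": self.feature_ids,
            "center": self.center,
            "uv_scale": self.uv_scale,
            "ss_target": self.ss_target,
            "means": self.means.tolist(),
            "sds": None if self.sds is None else self.sds.tolist(),
            "block_scale": self.block_scale,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessRecipe":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            block_name=d["block_name"],
            feature_ids=d["feature_ids"],
            center=d["center"],
            uv_scale=d["uv_scale"],
            ss_target=d["ss_target"],
            means=np.array(d["means"], dtype=float),
            sds=None if d["sds"] is None else np.array(d["sds"], dtype=float),
            block_scale=d["block_scale"],
        )


def fit_preprocess(
    block: OmicsBlock,
    center: bool = True,
    uv_scale: bool = False,
    ss_target: float = 1.0,
) -> PreprocessRecipe:
    """Fit centering/scaling parameters on a raw block.

    Unit-variance scaling requires every feature to have nonzero variance;
    offending features are reported so the caller can drop them explicitly.
    A block that is all-zero after centering/scaling has no defined block
    scale and is rejected.
    """
    if ss_target <= 0:
        raise PreprocessError("ss_target must be positive")
    values = block.values
    means = values.mean(axis=0) if center else np.zeros(block.n_features)
    transformed = values - means
    sds = None
    if uv_scale:
        sds = values.std(axis=0, ddof=_SD_DDOF)
        dead = np.flatnonzero(sds <= 0)
        if dead.size:
            names = [block.feature_ids[j] for j in dead[:10]]
            raise PreprocessError(
                f"block {block.block_name!r}: {dead.size} zero-variance feature(s) "
                f"cannot be unit-variance scaled: {names}"
            )
        transformed = transformed / sds
    total_ss = float(np.sum(transformed**2))
    if total_ss <= 0:
        raise PreprocessError(
            f"block {block.block_name!r}: zero total sum of squares; block scale undefined"
        )
    block_scale = float(np.sqrt(ss_target / total_ss))
    return PreprocessRecipe(
        block_name=block.block_name,
        feature_ids=list(block.feature_ids),
        center=center,
        uv_scale=uv_scale,
        ss_target=ss_target,
        means=means,
        sds=sds,
        block_scale=block_scale,
    )


def apply_preprocess(block: OmicsBlock, recipe: PreprocessRecipe) -> OmicsBlock:
    """Apply a fitted recipe: ``(values - means) [/ sds] * block_scale``.

    The recipe must have been fitted on a block with identical feature ids.
    Applying a recipe to data it has already transformed is forbidden (the
    transform is not idempotent); a block whose features are already centered
    while the recipe stores materially nonzero means is rejected.
    """
    if list(block.feature_ids) != list(recipe.feature_ids):
        raise PreprocessError(
            f"feature ids of block {block.block_name!r} do not match recipe "
            f"({block.n_features} vs {len(recipe.feature_ids)} features)"
        )
    if recipe.center:
        scale_ref = np.abs(block.values).max()
        col_means = block.values.mean(axis=0)
        tol = 1e-10 * max(scale_ref, 1.0)
        if np.abs(recipe.means).max() > tol and np.abs(col_means).max() <= tol:
            raise PreprocessError(
                "input block appears already centered; applying a recipe twice is forbidden"
            )
    values = block.values - recipe.means
    if recipe.uv_scale:
        values = values / recipe.sds
    values = values * recipe.block_scale
    return block.copy_with(values)


def preprocess_block(
    block: OmicsBlock,
    center: bool = True,
    uv_scale: bool = False,
    ss_target: float = 1.0,
) -> tuple[OmicsBlock, PreprocessRecipe]:
    """Fit and apply in one step."""
    recipe = fit_preprocess(block, center=center, uv_scale=uv_scale, ss_target=ss_target)
    return apply_preprocess(block, recipe), recipe


def preprocess_pair(
    x: OmicsBlock,
    y: OmicsBlock,
    uv_scale_x: bool = False,
    uv_scale_y: bool = True,
    ss_target: float = 1.0,
) -> tuple[OmicsBlock, OmicsBlock, PreprocessRecipe, PreprocessRecipe]:
    """Standard two-block recipe: center both blocks, unit-variance scale the
    second (metabolome) block, then bring both to the same total sum of
    squares."""
    xt, rx = preprocess_block(x, center=True, uv_scale=uv_scale_x, ss_target=ss_target)
    yt, ry = preprocess_block(y, center=True, uv_scale=uv_scale_y, ss_target=ss_target)
    return xt, yt, rx, ry


def log2_transform(block: OmicsBlock, pseudocount: float = 1.0) -> OmicsBlock:
    """Optional ``log2(x + pseudocount)`` pre-transform for abundance matrices."""
    if np.any(block.values + pseudocount <= 0):
        raise PreprocessError("log2 transform undefined for values <= -pseudocount")
    return block.copy_with(np.log2(block.values + pseudocount))
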