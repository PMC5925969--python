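"""Synthetic paired-omics generators with known latent structure.

Every downstream stage of the pipeline is testable against these generators:

* :func:`generate_joint_pair` builds two blocks that share low-rank joint
  variation (one set of latent scores drives both blocks), carry
  block-specific orthogonal variation, and i.i.d. Gaussian noise, with the
  three variance components mixed at exactly the configured sums-of-squares
  fractions.  A chosen number of "planted" features per block is given at
  least three times the average joint-loading mass, so selector recall can be
  scored against ground truth.
* :func:`generate_null_pair` builds two independent Gaussian blocks with no
  cross-block association — the null case for calibrating the permutation
  selector.
* :func:`generate_peak_table` builds a two-group ion-intensity table with
  lognormal multiplicative noise and per-ion planted log2 fold changes for
  testing the differential-ion prefilter.

Defaults mirror the study scale the pipeline targets: a handful of samples
(three biological replicates per treatment) and tens-to-hundreds of features.
All randomness flows through an explicit mandatory seed; there is no hidden
global state.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .io import OmicsBlock
from .prefilter import PeakTable

__all__ = [
    "SynthConfigError",
    "SynthConfig",
    "SyntheticTruth",
    "generate_joint_pair",
    "generate_null_pair",
    "generate_peak_table",
    "write_pair",
]

_PLANT_MASS_RATIO = 3.0  # planted rows carry >= 3x the average loading mass


class SynthConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator configuration for one paired-block draw.

    ``var_joint_* / var_orth_* / var_noise_*`` are the sums-of-squares
    fractions of the three variance components per block; they must each lie
    in [0, 1] and sum to 1.  ``n_planted_*`` features per block receive
    boosted joint-loading rows.  ``seed`` is mandatory.
    """

    n_samples: int = 6
    p_features_x: int = 126
    q_features_y: int = 85
    n_joint: int = 3
    n_orth_x: int = 1
    n_orth_y: int = 1
    var_joint_x: float = 0.6
    var_orth_x: float = 0.2
    var_noise_x: float = 0.2
    var_joint_y: float = 0.6
    var_orth_y: float = 0.2
    var_noise_y: float = 0.2
    n_planted_x: int = 0
    n_planted_y: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise SynthConfigError("n_samples must be >= 2")
        if self.n_joint < 1:
            raise SynthConfigError("n_joint must be >= 1")
        if self.n_orth_x < 0 or self.n_orth_y < 0:
            raise SynthConfigError("orthogonal component counts must be >= 0")
        for label, fracs in (
            ("x", (self.var_joint_x, self.var_orth_x, self.var_noise_x)),
            ("y", (self.var_joint_y, self.var_orth_y, self.var_noise_y)),
        ):
            if any(f < 0 or f > 1 for f in fracs):
                raise SynthConfigError(f"variance fractions for block {label} must lie in [0, 1]")
            if abs(sum(fracs) - 1.0) > 1e-8:
                raise SynthConfigError(
                    f"variance fractions for block {label} sum to {sum(fracs)}, expected 1"
                )
        if self.n_joint + self.n_orth_x > min(self.n_samples - 1, self.p_features_x):
            raise SynthConfigError(
                "n_joint + n_orth_x exceeds min(n_samples - 1, p_features_x): "
                "requested rank is infeasible"
            )
        if self.n_joint + self.n_orth_y > min(self.n_samples - 1, self.q_features_y):
            raise SynthConfigError(
                "n_joint + n_orth_y exceeds min(n_samples - 1, q_features_y): "
                "requested rank is infeasible"
            )
        if self.n_joint + self.n_orth_x + self.n_orth_y > self.n_samples - 1:
            raise SynthConfigError(
                "n_joint + n_orth_x + n_orth_y must not exceed n_samples - 1: "
                "the block-specific score spaces cannot all be mutually orthogonal"
            )
        if self.n_planted_x > self.p_features_x or self.n_planted_y > self.q_features_y:
            raise SynthConfigError("planted feature counts cannot exceed feature counts")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of one draw: generating loadings (orthonormal columns),
    planted identifiers, the realized variance fractions of the emitted mix,
    and the seed."""

    joint_loadings_x: np.ndarray
    joint_loadings_y: np.ndarray
    orth_loadings_x: np.ndarray
    orth_loadings_y: np.ndarray
    planted_x: list[str]
    planted_y: list[str]
    variance_fractions_x: tuple[float, float, float]
    variance_fractions_y: tuple[float, float, float]
    seed: int


def _orthonormal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((rows, cols)))
    # fix the QR sign ambiguity so the draw is a well-defined function of rng
    return Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))


def _plant(W: np.ndarray, planted: np.ndarray, ratio: float = _PLANT_MASS_RATIO) -> np.ndarray:
    """Boost the planted rows of an orthonormal loading matrix, then
    re-orthonormalize by polar (symmetric) orthogonalization, which preserves
    relative row structure.  The boost is doubled until the planted rows hold
    at least ``ratio`` times the average per-feature loading mass."""
    if planted.size == 0:
        return W
    p, k = W.shape
    avg_mass = k / p
    target = ratio * avg_mass
    if planted.size * target > 0.9 * k:
        raise SynthConfigError(
            "planted features cannot all hold the required loading mass: "
            f"{planted.size} planted x target mass {target:.3g} exceeds the "
            f"joint rank budget {k}"
        )
    Wp = W.copy()
    Wp[planted] *= 2.0 * ratio
    for _ in range(100):
        u, _, vt = np.linalg.svd(Wp, full_matrices=False)
        Wp = u @ vt
        mass = (Wp[planted] ** 2).sum(axis=1)
        if mass.min() >= target:
            return Wp
        # boost only the rows still short of the target (with headroom)
        short = mass < target
        Wp[planted[short]] *= np.sqrt(1.5 * target / mass[short])[:, None]
    raise SynthConfigError(
        "could not give planted features the required loading mass; "
        "too many planted features for the joint rank"
    )


def _mix(
    parts: list[np.ndarray],
    fractions: tuple[float, float, float],
    total_ss: float,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Scale each component to exactly its target share of ``total_ss`` and sum."""
    out = np.zeros_like(parts[0])
    realized = []
    for part, frac in zip(parts, fractions):
        ss = float(np.sum(part**2))
        if frac > 0 and ss <= 0:
            raise SynthConfigError("a variance component with positive target fraction is zero")
        if frac > 0:
            out += part * np.sqrt(frac * total_ss / ss)
        realized.append(frac)
    return out, tuple(realized)


def generate_joint_pair(config: SynthConfig) -> tuple[OmicsBlock, OmicsBlock, SyntheticTruth]:
    """Draw one paired-block dataset with planted joint/orthogonal structure.

    The joint latent scores are drawn once and shared by both blocks; each
    block's orthogonal scores are drawn independently and residualized
    against the joint scores, so the joint and orthogonal parts are exactly
    Frobenius-orthogonal and the configured variance split is realized from
    sums of squares, not in expectation.  Deterministic given the seed.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n, p, q, k = c.n_samples, c.p_features_x, c.q_features_y, c.n_joint

    T = rng.standard_normal((n, k))
    T -= T.mean(axis=0)

    def orth_scores(n_orth: int, base: np.ndarray) -> np.ndarray:
        S = rng.standard_normal((n, n_orth))
        S -= S.mean(axis=0)
        # residualize so the block-specific structure is empirically
        # orthogonal to the joint scores (and, for the second block, to the
        # first block's orthogonal scores: "unique to each dataset" means no
        # accidental cross-block correlation either)
        coef, *_ = np.linalg.lstsq(base, S, rcond=None)
        return S - base @ coef

    To_x = orth_scores(c.n_orth_x, T)
    To_y = orth_scores(c.n_orth_y, np.column_stack([T, To_x]))

    W = _orthonormal(rng, p, k)
    C = _orthonormal(rng, q, k)
    planted_x_idx = np.sort(rng.choice(p, size=c.n_planted_x, replace=False))
    planted_y_idx = np.sort(rng.choice(q, size=c.n_planted_y, replace=False))
    W = _plant(W, planted_x_idx)
    C = _plant(C, planted_y_idx)
    P_x = _orthonormal(rng, p, c.n_orth_x) if c.n_orth_x else np.zeros((p, 0))
    P_y = _orthonormal(rng, q, c.n_orth_y) if c.n_orth_y else np.zeros((q, 0))

    noise_x = rng.standard_normal((n, p))
    noise_y = rng.standard_normal((n, q))

    X, fracs_x = _mix(
        [T @ W.T, To_x @ P_x.T if c.n_orth_x else np.zeros((n, p)), noise_x],
        (c.var_joint_x, c.var_orth_x, c.var_noise_x),
        total_ss=float(n * p),
    )
    Y, fracs_y = _mix(
        [T @ C.T, To_y @ P_y.T if c.n_orth_y else np.zeros((n, q)), noise_y],
        (c.var_joint_y, c.var_orth_y, c.var_noise_y),
        total_ss=float(n * q),
    )

    sample_ids = [f"S{i + 1}" for i in range(n)]
    x_ids = [f"TX{j + 1:05d}" for j in range(p)]
    y_ids = [f"MZ{j + 1:05d}" for j in range(q)]
    x_block = OmicsBlock("transcriptome", sample_ids, x_ids, X)
    y_block = OmicsBlock("metabolome", sample_ids, y_ids, Y)
    truth = SyntheticTruth(
        joint_loadings_x=W,
        joint_loadings_y=C,
        orth_loadings_x=P_x,
        orth_loadings_y=P_y,
        planted_x=[x_ids[j] for j in planted_x_idx],
        planted_y=[y_ids[j] for j in planted_y_idx],
        variance_fractions_x=fracs_x,
        variance_fractions_y=fracs_y,
        seed=c.seed,
    )
    return x_block, y_block, truth


def generate_null_pair(
    n_samples: int, p: int, q: int, seed: int
) -> tuple[OmicsBlock, OmicsBlock]:
    """Two independent standard-Gaussian blocks over shared samples: no
    cross-block association exists by construction."""
    if n_samples < 2 or p < 2 or q < 2:
        raise SynthConfigError("all sizes must be >= 2")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    X = rng.standard_normal((n_samples, p))
    Y = rng.standard_normal((n_samples, q))
    x_block = OmicsBlock("transcriptome", sample_ids, [f"TX{j + 1:05d}" for j in range(p)], X)
    y_block = OmicsBlock("metabolome", sample_ids, [f"MZ{j + 1:05d}" for j in range(q)], Y)
    return x_block, y_block


def generate_peak_table(
    n_ions: int,
    n_per_group: int,
    effect_log2fc,
    base_intensity: float = 1000.0,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[PeakTable, np.ndarray]:
    """Two-group ion-intensity table with lognormal multiplicative noise.

    Treated-group mean intensity per ion is ``base_intensity * 2**effect``;
    the lognormal noise is mean-preserving, so with ``noise_cv = 0`` the
    group-mean ratio equals ``2**effect`` exactly.  Returns the table and the
    truth flags marking ions with ``|effect_log2fc| >= 1``.
    """
    if n_per_group < 2:
        raise SynthConfigError("n_per_group must be >= 2")
    if base_intensity <= 0:
        raise SynthConfigError("base_intensity must be positive")
    if noise_cv < 0:
        raise SynthConfigError("noise_cv must be non-negative")
    effects = np.broadcast_to(np.asarray(effect_log2fc, dtype=float), (n_ions,)).copy()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    means = np.column_stack(
        [
            np.repeat(base_intensity, n_per_group * n_ions).reshape(n_ions, n_per_group),
            (base_intensity * 2.0**effects)[:, None] * np.ones((n_ions, n_per_group)),
        ]
    )
    z = rng.standard_normal(means.shape)
    intensities = means * np.exp(sigma * z - 0.5 * sigma**2)
    sample_ids = [f"C{i + 1}" for i in range(n_per_group)] + [
        f"T{i + 1}" for i in range(n_per_group)
    ]
    groups = ["control"] * n_per_group + ["treated"] * n_per_group
    peaks = PeakTable(
        ion_ids=[f"ion{j + 1:04d}" for j in range(n_ions)],
        sample_ids=sample_ids,
        intensities=intensities,
        groups=groups,
    )
    return peaks, np.abs(effects) >= 1.0


def write_pair(
    x_block: OmicsBlock,
    y_block: OmicsBlock,
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the two blocks as TSV and the truth as a JSON sidecar."""
    from .io import write_block

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "x": write_block(x_block, out_dir / "x_block.tsv"),
        "y": write_block(y_block, out_dir / "y_block.tsv"),
    }
    payload = {
        "planted_x": truth.planted_x,
        "planted_y": truth.planted_y,
        "variance_fractions_x": list(truth.variance_fractions_x),
        "variance_fractions_y": list(truth.variance_fractions_y),
        "seed": truth.seed,
        "joint_loadings_x": truth.joint_loadings_x.tolist(),
        "joint_loadings_y": truth.joint_loadings_y.tolist(),
    }
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths
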