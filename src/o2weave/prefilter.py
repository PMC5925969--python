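"""Metabolomics differential-ion prefilter, feature subsetting and signature
comparison.

The prefilter reproduces the standard untargeted-metabolomics screen that
feeds the integration: an ion is called differentially accumulated between a
control and a treated group when its one-way ANOVA p-value is at most
``p_threshold`` (default 0.05) AND the magnitude of its log2 fold change is at
least ``lfc_threshold`` (default 1).  Both thresholds are inclusive and the
rule is conjunctive.  With exactly two groups the one-way ANOVA is
algebraically identical to the pooled-variance two-sample t test.

Transcript differential expression is never recomputed here: the significant
gene list produced by a dedicated count-based DE analysis is ingested as a
plain feature-list file and applied with :func:`subset_significant`.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError, OmicsBlock

log = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "read_peak_table",
    "peak_table_to_block",
    "differential_ions",
    "anova_pvalues",
    "subset_significant",
    "intersect_signatures",
]


@dataclasses.dataclass
class PeakTable:
    """Grouped ion-intensity table: ions in rows, samples in columns.

    ``groups`` assigns one treatment label per sample.  ``ion_modes`` is an
    optional per-ion ionization-mode annotation (``positive`` / ``negative`` /
    ``both``); it is carried through, never interpreted.
    """

    ion_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    groups: list[str]
    ion_modes: list[str] | None = None

    def __post_init__(self) -> None:
        self.ion_ids = [str(i) for i in self.ion_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.ion_ids), len(self.sample_ids)):
            raise FormatError("intensity matrix shape does not match ion/sample ids")
        if len(set(self.ion_ids)) != len(self.ion_ids):
            raise FormatError("duplicate ion ids")
        if len(self.groups) != len(self.sample_ids):
            raise FormatError("one group label per sample required")
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("peak table contains non-finite intensities")
        if np.any(self.intensities < 0):
            raise FormatError("peak intensities must be non-negative")
        if self.ion_modes is not None and len(self.ion_modes) != len(self.ion_ids):
            raise FormatError("one ionization mode per ion required")

    def group_columns(self, group: str) -> np.ndarray:
        idx = np.array([j for j, g in enumerate(self.groups) if g == group], dtype=int)
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.ion_ids, columns=self.sample_ids)


def read_peak_table(path, design, sep: str | None = None) -> PeakTable:
    """Read an ions-in-rows intensity TSV/CSV and attach group labels.

    ``design`` is a :class:`~o2weave.io.DesignTable`; every sample column must
    be present in it.
    """
    from .io import read_block

    block = read_block(path, orientation="features_in_rows", block_name="peaks", sep=sep)
    # read_block canonicalises to samples-in-rows; ions are its features
    missing = [s for s in block.sample_ids if s not in design.groups]
    if missing:
        raise FormatError(f"samples without a group assignment: {missing[:10]}")
    return PeakTable(
        ion_ids=list(block.feature_ids),
        sample_ids=list(block.sample_ids),
        intensities=block.values.T,
        groups=[design.groups[s] for s in block.sample_ids],
    )


def peak_table_to_block(peaks: PeakTable, block_name: str = "metabolome") -> OmicsBlock:
    """View a peak table as a samples-by-ions block for integration."""
    return OmicsBlock(block_name, list(peaks.sample_ids), list(peaks.ion_ids), peaks.intensities.T)


def _anova_f_p(group_values: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA across groups, per row of each array.

    Degenerate rows (zero within-group variance) get p = 0 when the group
    means differ and p = 1 when they do not, the limit of the F test as the
    within-group variance vanishes.
    """
    k = len(group_values)
    counts = np.array([g.shape[1] for g in group_values])
    n = int(counts.sum())
    grand = np.hstack(group_values)
    grand_mean = grand.mean(axis=1)
    means = np.column_stack([g.mean(axis=1) for g in group_values])
    ssb = ((means - grand_mean[:, None]) ** 2 * counts[None, :]).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for j, g in enumerate(group_values):
        ssw += ((g - means[:, [j]]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = np.where(ssw > 0, stats.f.sf(F, dfb, dfw), np.where(ssb > 0, 0.0, 1.0))
    F = np.where(ssw > 0, F, np.where(ssb > 0, np.inf, 0.0))
    return F, p


def anova_pvalues(peaks: PeakTable, groups: Sequence[str]) -> np.ndarray:
    """One-way ANOVA p-value per ion across the named groups (2 or more)."""
    arrays = []
    for g in groups:
        cols = peaks.group_columns(g)
        if cols.size < 2:
            raise FormatError(f"group {g!r} has {cols.size} samples; at least 2 required")
        arrays.append(peaks.intensities[:, cols])
    _, p = _anova_f_p(arrays)
    return p


def differential_ions(
    peaks: PeakTable,
    control: str,
    treated: str,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Call differentially accumulated ions between two treatment groups.

    Returns one row per ion with columns ``ion_id``, ``p_value``, ``log2fc``
    (treated over control) and ``selected``.  Selection requires BOTH
    ``p_value <= p_threshold`` and ``|log2fc| >= lfc_threshold``.

    Zero intensities are floored at half the smallest positive intensity in
    the table before group means enter the fold change, so the log is always
    defined; an ion that is all-zero in both groups gets p = 1, log2fc = 0
    and is never selected.
    """
    ctrl_cols = peaks.group_columns(control)
    trt_cols = peaks.group_columns(treated)
    for name, cols in ((control, ctrl_cols), (treated, trt_cols)):
        if cols.size < 2:
            raise FormatError(f"group {name!r} has {cols.size} samples; at least 2 required")
    ctrl = peaks.intensities[:, ctrl_cols]
    trt = peaks.intensities[:, trt_cols]

    _, p = _anova_f_p([ctrl, trt])

    positive = peaks.intensities[peaks.intensities > 0]
    floor = 0.5 * positive.min() if positive.size else 1.0
    ctrl_mean = np.maximum(ctrl.mean(axis=1), floor)
    trt_mean = np.maximum(trt.mean(axis=1), floor)
    log2fc = np.log2(trt_mean / ctrl_mean)

    all_zero = (ctrl.sum(axis=1) == 0) & (trt.sum(axis=1) == 0)
    if all_zero.any():
        log.warning("%d ion(s) are all-zero in both groups; forced to p=1, log2fc=0", all_zero.sum())
        p = np.where(all_zero, 1.0, p)
        log2fc = np.where(all_zero, 0.0, log2fc)

    selected = (p <= p_threshold) & (np.abs(log2fc) >= lfc_threshold) & ~all_zero
    return pd.DataFrame(
        {
            "ion_id": peaks.ion_ids,
            "p_value": p,
            "log2fc": log2fc,
            "selected": selected,
        }
    )


def subset_significant(
    block: OmicsBlock,
    keep: Sequence[str],
    allow_missing: bool = False,
) -> OmicsBlock:
    """Restrict a block to the features named in ``keep``.

    The block's original column order is preserved and the sample axis is
    untouched.  Identifiers absent from the block are an error unless
    ``allow_missing`` (then counted and logged).  An empty result cannot be
    integrated and is always an error.
    """
    keep_set = set(keep)
    if not keep_set:
        raise FormatError("empty keep list: an empty block cannot be integrated")
    present = set(block.feature_ids)
    unknown = [k for k in keep if k not in present]
    if unknown:
        if allow_missing:
            log.warning(
                "%d of %d keep identifiers absent from block %r",
                len(unknown), len(keep), block.block_name,
            )
        else:
            raise FormatError(
                f"{len(unknown)} keep identifier(s) absent from block "
                f"{block.block_name!r}: {unknown[:10]}"
            )
    cols = [j for j, f in enumerate(block.feature_ids) if f in keep_set]
    if not cols:
        raise FormatError("no keep identifiers present in the block")
    return OmicsBlock(
        block.block_name,
        list(block.sample_ids),
        [block.feature_ids[j] for j in cols],
        block.values[:, cols],
    )


def intersect_signatures(
    list_a: Sequence[str],
    list_b: Sequence[str],
) -> tuple[list[str], list[str], list[str]]:
    """Partition two feature signatures into (shared, only_a, only_b).

    ``shared`` preserves the order of ``list_a``; the "only" lists preserve
    their own list's order.  This is the set arithmetic behind a two-way Venn
    comparison of treatment signatures.
    """
    set_a, set_b = set(list_a), set(list_b)
    shared = [f for f in list_a if f in set_b]
    only_a = [f for f in list_a if f not in set_b]
    only_b = [f for f in list_b if f not in set_a]
    return shared, only_a, only_b
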