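"""Reading and writing of omics feature tables, design tables, feature lists
and fitted-model result tables.

The canonical in-memory container is :class:`OmicsBlock`: one numeric
samples-by-features matrix with unique identifiers on both axes.  Files may be
stored with either orientation; the orientation is always declared by the
caller, never guessed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "OmicsBlock",
    "DesignTable",
    "read_block",
    "write_block",
    "read_feature_list",
    "read_design_table",
    "write_results",
    "write_manifest",
    "read_manifest",
]


class FormatError(ValueError):
    """A delimited input file violates the expected table contract."""


# Strings treated as missing values when they appear in a numeric cell.
_MISSING_TOKENS = {"", "NA", "N/A", "NAN", "NaN", "nan", "na", "NULL", "null", "None"}


@dataclasses.dataclass
class OmicsBlock:
    """One omics data matrix: rows are samples, columns are features.

    Parameters
    ----------
    block_name
        Label for the block (e.g. ``"transcriptome"``).
    sample_ids, feature_ids
        Ordered unique identifiers for the two axes.
    values
        Numeric matrix of shape ``(n_samples, n_features)``; every entry must
        be finite.  Abundance units are arbitrary.
    """

    block_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError(f"block {self.block_name!r}: values must be 2-D")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise FormatError(
                f"block {self.block_name!r}: {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.feature_ids):
            raise FormatError(
                f"block {self.block_name!r}: {p} columns but {len(self.feature_ids)} feature ids"
            )
        for axis_name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(
                    f"block {self.block_name!r}: duplicate {axis_name} ids: {dupes[:5]}"
                )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"block {self.block_name!r}: non-finite value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def copy_with(self, values: np.ndarray) -> "OmicsBlock":
        """Same identifiers, new matrix."""
        return OmicsBlock(self.block_name, list(self.sample_ids), list(self.feature_ids), values)


@dataclasses.dataclass
class DesignTable:
    """Maps each sample identifier to a treatment group label."""

    groups: dict[str, str]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def require_group(self, group: str, min_samples: int = 2) -> list[str]:
        samples = self.samples_in(group)
        if len(samples) < min_samples:
            raise FormatError(
                f"group {group!r} has {len(samples)} samples; at least {min_samples} required"
            )
        return samples


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_block(
    path: str | Path,
    orientation: str = "samples_in_rows",
    block_name: str | None = None,
    sep: str | None = None,
) -> OmicsBlock:
    """Read a delimited feature table into canonical samples-in-rows form.

    The first column must hold row identifiers and the header row column
    identifiers.  ``orientation`` declares how the file is laid out
    (``"samples_in_rows"`` or ``"features_in_rows"``); features-in-rows input
    is transposed on read.  The delimiter is auto-detected between tab and
    comma from the header unless ``sep`` is given.

    Missing or non-numeric cells are hard errors reporting the offending
    row/column pair — imputation is deliberately out of scope.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _detect_sep(path, sep)
    # pandas silently renames duplicate header names, so check the raw header
    with open(path) as fh:
        header_cells = fh.readline().rstrip("\r\n").split(sep)[1:]
    if len(set(header_cells)) != len(header_cells):
        dupes = sorted({c for c in header_cells if header_cells.count(c) > 1})
        raise FormatError(f"{path}: duplicate column ids: {dupes[:5]}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row ids: {dupes[:5]}")

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col]
        bad = pd.to_numeric(cells, errors="coerce").isna()
        if bad.any():
            row_id = cells.index[bad.to_numpy().argmax()]
            cell = cells.loc[row_id]
            kind = "missing value" if cell.strip() in _MISSING_TOKENS else f"non-numeric cell {cell!r}"
            raise FormatError(f"{path}: {kind} at row {row_id!r}, column {col!r}")
        # numpy's parser is correctly rounded; pd.to_numeric's fast path is not
        values[:, j] = cells.to_numpy().astype(np.float64)

    name = block_name if block_name is not None else path.stem
    if orientation == "features_in_rows":
        return OmicsBlock(name, list(raw.columns), list(raw.index), values.T)
    return OmicsBlock(name, list(raw.index), list(raw.columns), values)


def write_block(
    block: OmicsBlock,
    path: str | Path,
    orientation: str = "samples_in_rows",
    sep: str = "\t",
) -> Path:
    """Write a block as delimited text with full round-trip float precision."""
    path = Path(path)
    frame = block.to_frame()
    if orientation == "features_in_rows":
        frame = frame.T
        frame.index.name = "feature_id"
    elif orientation == "samples_in_rows":
        frame.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly
    frame.to_csv(path, sep=sep, float_format="%.17g")
    return path


def read_feature_list(path: str | Path, column: str | None = None, sep: str = "\t") -> list[str]:
    """Read an ordered feature-identifier list.

    Default format is one identifier per line; with ``column`` set, the file
    is read as a delimited table and that column is used.  Order is preserved;
    duplicates are dropped with a logged warning.  An empty list is an error.
    """
    path = Path(path)
    if column is not None:
        frame = pd.read_csv(path, sep=sep)
        if column not in frame.columns:
            raise FormatError(f"{path}: no column named {column!r}")
        entries = [str(v).strip() for v in frame[column]]
    else:
        with open(path) as fh:
            entries = [line.strip() for line in fh]
    entries = [e for e in entries if e and not e.startswith("#")]
    seen: dict[str, None] = {}
    n_dupes = 0
    for e in entries:
        if e in seen:
            n_dupes += 1
        else:
            seen[e] = None
    if n_dupes:
        log.warning("%s: dropped %d duplicate identifiers", path, n_dupes)
    if not seen:
        raise FormatError(f"{path}: feature list is empty")
    return list(seen)


def read_design_table(path: str | Path, sep: str | None = None) -> DesignTable:
    """Read a two-column sample-to-group table (header row required)."""
    path = Path(path)
    sep = _detect_sep(path, sep)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample_id, group)")
    samples = frame.iloc[:, 0].tolist()
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample ids in design table")
    return DesignTable(dict(zip(samples, frame.iloc[:, 1].tolist())))


# ---------------------------------------------------------------------------
# result writing


def _loading_frame(
    block_name: str,
    feature_ids: Sequence[str],
    loadings: np.ndarray,
    flags: np.ndarray | None,
) -> pd.DataFrame:
    """Long-format loading table: one row per feature x joint component."""
    p, a = loadings.shape
    rows = []
    for k in range(a):
        for j in range(p):
            rows.append(
                {
                    "block": block_name,
                    "component": k + 1,
                    "feature_id": feature_ids[j],
                    "loading": loadings[j, k],
                    "flagged": bool(flags[j, k]) if flags is not None else False,
                }
            )
    frame = pd.DataFrame(rows, columns=["block", "component", "feature_id", "loading", "flagged"])
    # deterministic order: block, component, |loading| descending, feature id
    frame["_abs"] = frame["loading"].abs()
    frame = frame.sort_values(
        by=["block", "component", "_abs", "feature_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop(columns="_abs")
    return frame.reset_index(drop=True)


def write_results(
    model,
    stats,
    out_dir: str | Path,
    selection=None,
    null=None,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write loading, variance and threshold tables plus a run manifest.

    ``model`` is a fitted :class:`~o2weave.o2pls.O2PLSModel`, ``stats`` its
    :class:`~o2weave.o2pls.VarianceStats`; ``selection`` and ``null`` (from the
    permutation stage) are optional.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    flags_x = flags_y = None
    if selection is not None:
        flags_x = selection.flag_matrix("x")
        flags_y = selection.flag_matrix("y")
    frames = [
        _loading_frame(model.x_name, model.x_feature_ids, model.W, flags_x),
        _loading_frame(model.y_name, model.y_feature_ids, model.C, flags_y),
    ]
    loading_path = out_dir / "loadings.tsv"
    pd.concat(frames, ignore_index=True).to_csv(loading_path, sep="\t", index=False, float_format="%.17g")
    written["loadings"] = loading_path

    stats_path = out_dir / "variance_stats.tsv"
    pd.DataFrame([dataclasses.asdict(stats)]).to_csv(stats_path, sep="\t", index=False)
    written["variance_stats"] = stats_path

    if null is not None:
        rows = []
        for block_name, thr in ((model.x_name, null.thresholds_x), (model.y_name, null.thresholds_y)):
            for k in range(thr.shape[0]):
                rows.append(
                    {
                        "block": block_name,
                        "component": k + 1,
                        "lower": thr[k, 0],
                        "upper": thr[k, 1],
                    }
                )
        thr_path = out_dir / "thresholds.tsv"
        pd.DataFrame(rows).to_csv(thr_path, sep="\t", index=False)
        written["thresholds"] = thr_path

    if selection is not None:
        rec_path = out_dir / "influence_records.tsv"
        selection.records.to_csv(rec_path, sep="\t", index=False)
        written["records"] = rec_path
        sel_path = out_dir / "selected_features.tsv"
        flagged = selection.records[selection.records["flagged"]]
        flagged.to_csv(sel_path, sep="\t", index=False)
        written["selection"] = sel_path
        summary_path = out_dir / "selection_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(selection.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["selection_summary"] = summary_path

    if manifest is not None:
        written["manifest"] = write_manifest(manifest, out_dir / "manifest.json")
    return written


def write_manifest(manifest: Mapping, path: str | Path) -> Path:
    """Write a JSON run manifest (config, seed, package versions)."""
    import scipy

    from . import __version__

    path = Path(path)
    payload = dict(manifest)
    payload.setdefault(
        "versions",
        {
            "o2weave": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
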