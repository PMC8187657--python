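"""Chromatin-trace containers and preprocessing.

A chromosome-tracing experiment (ORCA and relatives) reports, per cell, the
3D coordinate of each of ``B`` sequential genomic barcodes (here B=52,
~6 kb steps). Absolute coordinates depend on the microscope viewing angle,
so the rotation/translation-invariant representation used throughout the
package is the ``B x B`` matrix of all pairwise Euclidean distances.

This module reads tabular trace files, imputes missing barcodes by linear
interpolation along the chain, converts traces to distance matrices,
z-standardizes them against training-set statistics, and produces
label-stratified train/validation/test splits.

Barcode indices are 1-based in files, configs and reports (matching the
"monomer 20", "monomer 40" convention) and 0-based in all in-memory arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.model_selection import train_test_split

#: Sentinel for an unobserved barcode coordinate (any non-finite value in a
#: trace's coordinate array means MISSING).
MISSING = np.nan

DEFAULT_N_BARCODES = 52

SPLIT_CODES = {"train": 0, "val": 1, "test": 2}
SPLIT_NAMES = {v: k for k, v in SPLIT_CODES.items()}


class TraceError(ValueError):
    """Raised for malformed or degenerate trace data."""


@dataclass
class PolymerTrace:
    """Ordered 3D coordinates of one cell's barcodes (nm); NaN rows = missing."""

    cell_id: object
    coords: np.ndarray  # (B, 3) float, NaN where missing
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TraceError(f"trace {self.cell_id}: coords must be (B, 3)")
        if self.n_observed < 2:
            raise TraceError(
                f"trace {self.cell_id}: fewer than 2 observed barcodes"
            )

    @property
    def n_barcodes(self) -> int:
        return self.coords.shape[0]

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.coords).all(axis=1)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    @property
    def is_complete(self) -> bool:
        return bool(self.observed_mask.all())


@dataclass
class DistanceMatrix:
    """Symmetric B x B pairwise-distance map; nm if raw, unitless if standardized."""

    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise TraceError("distance matrix must be square")

    @property
    def n_barcodes(self) -> int:
        return self.values.shape[0]


@dataclass
class NormStats:
    """Per-entry training-set mean/std used for z-standardization.

    ``std`` is floored at ``epsilon`` so degenerate entries (notably the
    all-zero diagonal of raw distance matrices) never divide by zero. With
    ``mode="mean_ratio"`` the alternative normalization — dividing each entry
    by the training mean — is applied instead of the z-score.
    """

    mean: np.ndarray
    std: np.ndarray
    epsilon: float = 1e-6
    mode: str = "zscore"  # or "mean_ratio"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape:
            raise TraceError("norm stats mean/std shape mismatch")
        if self.epsilon <= 0:
            raise TraceError("epsilon must be positive")
        if np.any(self.std < self.epsilon):
            raise TraceError("std entries below epsilon floor")
        if self.mode not in ("zscore", "mean_ratio"):
            raise TraceError(f"unknown normalization mode {self.mode!r}")


@dataclass
class QCReport:
    """Bookkeeping from trace-file ingestion."""

    n_cells: int = 0
    n_rejected: int = 0
    rejected_ids: list = field(default_factory=list)
    n_missing_barcodes: int = 0


@dataclass
class LabeledDataset:
    """Distance matrices + binary labels + split tags + normalization stats.

    ``matrices`` are stored raw (nm); ``standardized_matrices`` applies the
    fitted ``norm_stats`` on demand. ``split`` holds integer codes
    (0=train, 1=val, 2=test).
    """

    matrices: np.ndarray  # (N, B, B) raw nm
    labels: np.ndarray  # (N,) 0/1
    split: np.ndarray  # (N,) int8 codes
    norm_stats: NormStats | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.split = np.asarray(self.split, dtype=np.int8)
        n = len(self.matrices)
        if not (len(self.labels) == len(self.split) == n):
            raise TraceError("matrices/labels/split length mismatch")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def on_fraction(self) -> float:
        return float(self.labels.mean())

    def indices(self, split: str) -> np.ndarray:
        return np.nonzero(self.split == SPLIT_CODES[split])[0]

    def standardized_matrices(self, split: str | None = None) -> np.ndarray:
        if self.norm_stats is None:
            raise TraceError("dataset has no fitted norm_stats")
        idx = slice(None) if split is None else self.indices(split)
        return _apply_stats(self.matrices[idx], self.norm_stats)

    def split_labels(self, split: str) -> np.ndarray:
        return self.labels[self.indices(split)]

    def replace(self, **kwargs) -> "LabeledDataset":
        return dataclasses.replace(self, **kwargs)

    # --- persistence -----------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_group("matrices")["values"] = self.matrices
            f.create_group("labels")["values"] = self.labels
            f.create_group("splits")["codes"] = self.split
            if self.norm_stats is not None:
                g = f.create_group("norm_stats")
                g["mean"] = self.norm_stats.mean
                g["std"] = self.norm_stats.std
                g.attrs["epsilon"] = self.norm_stats.epsilon
                g.attrs["mode"] = self.norm_stats.mode

    @classmethod
    def from_hdf5(cls, path) -> "LabeledDataset":
        with h5py.File(path, "r") as f:
            norm = None
            if "norm_stats" in f:
                g = f["norm_stats"]
                norm = NormStats(
                    mean=g["mean"][...],
                    std=g["std"][...],
                    epsilon=float(g.attrs["epsilon"]),
                    mode=str(g.attrs["mode"]),
                )
            return cls(
                matrices=f["matrices/values"][...],
                labels=f["labels/values"][...],
                split=f["splits/codes"][...],
                norm_stats=norm,
            )


# ---------------------------------------------------------------------------
# Reading tabular traces
# ---------------------------------------------------------------------------

DEFAULT_FORMAT = {
    "cell_id": "cell_id",
    "barcode": "barcode",
    "x": "x",
    "y": "y",
    "z": "z",
}


def read_trace_table(
    path,
    format_spec: dict | None = None,
    n_barcodes: int = DEFAULT_N_BARCODES,
    label_columns: Sequence[str] = (),
    label_threshold: float = 0.0,
    sep: str | None = None,
):
    """Read a delimited trace table into traces plus per-cell binary labels.

    One row per (cell, barcode) with 1-based barcode indices and x/y/z in nm.
    Rows absent or non-finite become MISSING barcodes. Label columns are
    constant per cell and binarized as ``value > label_threshold`` (already
    0/1 columns pass through unchanged). Cells with fewer than two observed
    barcodes are rejected and counted in the QC report.

    Returns ``(traces, labels_frame, qc_report)`` where ``labels_frame`` is a
    DataFrame indexed by cell id.
    """
    spec = dict(DEFAULT_FORMAT)
    if format_spec:
        spec.update(format_spec)
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # pragma: no cover - passthrough with context
        raise TraceError(f"failed to parse {path}: {exc}") from exc

    required = [spec["cell_id"], spec["barcode"], spec["x"], spec["y"], spec["z"]]
    for col in required + list(label_columns):
        if col not in df.columns:
            raise TraceError(f"{path}: missing required column {col!r}")

    bc = pd.to_numeric(df[spec["barcode"]], errors="coerce")
    bad = ~np.isfinite(bc) | (bc < 1) | (bc > n_barcodes) | (bc != np.round(bc))
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header + 1-based
        raise TraceError(f"{path}: malformed barcode index at line {line}")
    df = df.assign(_bc=bc.astype(int) - 1)

    traces: list[PolymerTrace] = []
    qc = QCReport()
    label_rows = {}
    for cell_id, grp in df.groupby(spec["cell_id"], sort=False):
        coords = np.full((n_barcodes, 3), MISSING)
        xyz = grp[[spec["x"], spec["y"], spec["z"]]].apply(
            pd.to_numeric, errors="coerce"
        ).to_numpy(dtype=float)
        ok = np.isfinite(xyz).all(axis=1)
        coords[grp["_bc"].to_numpy()[ok]] = xyz[ok]
        qc.n_missing_barcodes += n_barcodes - int(
            np.isfinite(coords).all(axis=1).sum()
        )
        if np.isfinite(coords).all(axis=1).sum() < 2:
            qc.n_rejected += 1
            qc.rejected_ids.append(cell_id)
            continue
        traces.append(PolymerTrace(cell_id=cell_id, coords=coords))
        if label_columns:
            row = {}
            for col in label_columns:
                vals = pd.to_numeric(grp[col], errors="coerce")
                row[col] = int(float(vals.iloc[0]) > label_threshold)
            label_rows[cell_id] = row
    qc.n_cells = len(traces)
    labels = pd.DataFrame.from_dict(label_rows, orient="index") if label_columns else (
        pd.DataFrame(index=[t.cell_id for t in traces])
    )
    return traces, labels, qc


def write_trace_table(traces: Iterable[PolymerTrace], path, sep: str = ",") -> None:
    """Export traces to the CSV dialect read by :func:`read_trace_table`.

    Missing barcodes are simply omitted (the round-trip restores them as
    MISSING).
    """
    rows = []
    for t in traces:
        obs = t.observed_mask
        for b in np.nonzero(obs)[0]:
            x, y, z = t.coords[b]
            rows.append((t.cell_id, b + 1, x, y, z))
    pd.DataFrame(rows, columns=["cell_id", "barcode", "x", "y", "z"]).to_csv(
        path, index=False, sep=sep
    )


# ---------------------------------------------------------------------------
# Imputation and distances
# ---------------------------------------------------------------------------

def interpolate_missing(trace: PolymerTrace, end_policy: str = "copy") -> PolymerTrace:
    """Fill MISSING barcodes by linear interpolation between observed neighbors.

    Interior gaps get the linear interpolant at their fractional position
    along the chain; runs of missing barcodes at either chain end copy the
    nearest observed barcode (``end_policy="copy"``, the default) or raise
    (``end_policy="reject"``). Idempotent on complete traces.
    """
    if trace.n_observed < 2:
        raise TraceError(f"trace {trace.cell_id}: need >=2 observed barcodes")
    if trace.is_complete:
        return trace
    obs = np.nonzero(trace.observed_mask)[0]
    if end_policy == "reject" and (obs[0] != 0 or obs[-1] != trace.n_barcodes - 1):
        raise TraceError(f"trace {trace.cell_id}: missing end barcodes")
    idx = np.arange(trace.n_barcodes)
    coords = np.empty_like(trace.coords)
    for d in range(3):
        # np.interp clamps outside the observed range = copy nearest observed
        coords[:, d] = np.interp(idx, obs, trace.coords[obs, d])
    return PolymerTrace(cell_id=trace.cell_id, coords=coords, meta=dict(trace.meta))


def trace_to_distance_matrix(trace: PolymerTrace) -> DistanceMatrix:
    """All-pairs Euclidean distances of a complete trace (raw, nm)."""
    if not trace.is_complete:
        raise TraceError(
            f"trace {trace.cell_id}: has missing barcodes; interpolate first"
        )
    return DistanceMatrix(values=squareform(pdist(trace.coords)), standardized=False)


def traces_to_matrices(traces: Sequence[PolymerTrace]) -> np.ndarray:
    """Stack complete traces into an (N, B, B) raw distance array."""
    return np.stack([trace_to_distance_matrix(t).values for t in traces])


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def fit_normalizer(
    train_matrices: np.ndarray | Sequence[DistanceMatrix],
    epsilon: float = 1e-6,
    mode: str = "zscore",
) -> NormStats:
    """Per-entry mean and std over the training matrices, std floored at epsilon."""
    arr = _as_array(train_matrices)
    if len(arr) < 2:
        raise TraceError("need >=2 training matrices to fit a normalizer")
    mean = arr.mean(axis=0)
    std = np.maximum(arr.std(axis=0, ddof=0), epsilon)
    return NormStats(mean=mean, std=std, epsilon=epsilon, mode=mode)


def _apply_stats(arr: np.ndarray, stats: NormStats) -> np.ndarray:
    if arr.shape[-2:] != stats.mean.shape:
        raise TraceError("matrix shape does not match norm stats")
    if stats.mode == "mean_ratio":
        return arr / np.maximum(stats.mean, stats.epsilon)
    return (arr - stats.mean) / stats.std


def apply_normalizer(
    matrix: DistanceMatrix | np.ndarray, stats: NormStats
) -> DistanceMatrix:
    """Standardize one raw matrix: entrywise (x - mean) / std (z-score mode)."""
    values = matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(matrix)
    return DistanceMatrix(values=_apply_stats(values, stats), standardized=True)


def invert_normalizer(
    matrix: DistanceMatrix | np.ndarray, stats: NormStats
) -> DistanceMatrix:
    """Algebraic inverse of :func:`apply_normalizer` (round-trip check support)."""
    values = matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(matrix)
    if stats.mode == "mean_ratio":
        raw = values * np.maximum(stats.mean, stats.epsilon)
    else:
        raw = values * stats.std + stats.mean
    return DistanceMatrix(values=raw, standardized=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> np.ndarray:
    """Label-stratified train/val/test assignment (codes 0/1/2).

    Fractions must sum to 1; the ON fraction of every split matches the
    global ON fraction within rounding. Deterministic for a fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise TraceError(f"split fractions must sum to 1, got {fractions}")
    labels = np.asarray(labels)
    n = len(labels)
    idx = np.arange(n)
    f_train, f_val, f_test = fractions
    train_idx, rest_idx = train_test_split(
        idx,
        train_size=f_train,
        stratify=labels,
        random_state=seed,
    )
    rel_val = f_val / (f_val + f_test)
    val_idx, test_idx = train_test_split(
        rest_idx,
        train_size=rel_val,
        stratify=labels[rest_idx],
        random_state=seed + 1,
    )
    codes = np.empty(n, dtype=np.int8)
    codes[train_idx] = SPLIT_CODES["train"]
    codes[val_idx] = SPLIT_CODES["val"]
    codes[test_idx] = SPLIT_CODES["test"]
    return codes


def build_dataset(
    matrices: np.ndarray,
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    epsilon: float = 1e-6,
    norm_mode: str = "zscore",
    meta: dict | None = None,
) -> LabeledDataset:
    """Assemble a model-ready dataset: split, then fit norm stats on train only."""
    split = stratified_split(np.asarray(labels), fractions, seed)
    ds = LabeledDataset(
        matrices=matrices,
        labels=labels,
        split=split,
        norm_stats=None,
        meta=meta or {},
    )
    stats = fit_normalizer(ds.matrices[ds.indices("train")], epsilon, norm_mode)
    return ds.replace(norm_stats=stats)


def _as_array(matrices) -> np.ndarray:
    if isinstance(matrices, np.ndarray):
        return matrices
    return np.stack(
        [m.values if isinstance(m, DistanceMatrix) else np.asarray(m) for m in matrices]
    )
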