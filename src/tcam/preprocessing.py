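"""Assemble long-format 'omics records into tensors and normalize them.

The entry point is :func:`assemble_tensor`, which pivots a tidy long
table (subject, time, feature, value) into a fully sampled
subjects × features × timepoints tensor with sorted, deterministic
labels.  Normalization front-ends cover the three schemes commonly
paired with longitudinal tensor factorization:

* **DFB** — deviation from a subject's own baseline timepoint(s);
* **LFB** — log-fold change relative to the subject's baseline, with a
  symmetric pseudocount;
* **rclr** — robust centered log-ratio per sample, where zeros are
  masked out of the geometric mean and stay zero.

Every transform appends a record to ``normalization_log``, and
:func:`replay_log` re-applies a log to raw data bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TensorDataset",
    "read_long_csv",
    "read_wide_tsv_dir",
    "assemble_tensor",
    "impute_missing",
    "normalize_dfb",
    "normalize_lfb",
    "normalize_rclr",
    "filter_features",
    "replay_log",
    "to_long_frame",
]

LONG_COLUMNS = ("subject", "time", "feature", "value")


@dataclass
class TensorDataset:
    """An order-3 tensor plus axis labels and a normalization audit log."""

    tensor: np.ndarray
    subject_labels: list[str]
    feature_labels: list[str]
    timepoint_labels: list[str]
    normalization_log: list[dict] = field(default_factory=list)
    missing_mask: np.ndarray | None = None  # m×n, True = whole sample absent

    def __post_init__(self) -> None:
        m, p, n = self.tensor.shape
        if (len(self.subject_labels), len(self.feature_labels),
                len(self.timepoint_labels)) != (m, p, n):
            raise ValueError("axis label lengths do not match tensor shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape

    def _with(self, tensor: np.ndarray, log_entry: dict, **kw) -> "TensorDataset":
        return replace(
            self,
            tensor=tensor,
            normalization_log=self.normalization_log + [log_entry],
            **kw,
        )


def read_long_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy long table with header subject,time,feature,value."""
    df = pd.read_csv(path, dtype={"subject": str, "time": str, "feature": str})
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long table is missing columns: {sorted(missing)}")
    return df[list(LONG_COLUMNS)]


def read_wide_tsv_dir(directory: str | Path) -> pd.DataFrame:
    """Read a directory of per-timepoint wide TSVs (features × subjects).

    Each file ``<timepoint>.tsv`` has feature ids in the first column and
    one column per subject; the stem is the timepoint label.  Returns the
    equivalent tidy long table.
    """
    directory = Path(directory)
    frames = []
    for f in sorted(directory.glob("*.tsv")):
        wide = pd.read_csv(f, sep="\t", index_col=0)
        long = wide.reset_index(names="feature").melt(
            id_vars="feature", var_name="subject", value_name="value"
        )
        long["time"] = f.stem
        frames.append(long[list(LONG_COLUMNS)])
    if not frames:
        raise ValueError(f"no .tsv files found in {directory}")
    return pd.concat(frames, ignore_index=True)


def assemble_tensor(
    table: pd.DataFrame,
    timepoint_order: Sequence[str],
    mode: str = "strict",
    fill_value: float = 0.0,
) -> TensorDataset:
    """Pivot a tidy long table into a fully sampled tensor.

    Subjects and features are sorted lexicographically for determinism;
    timepoints follow ``timepoint_order``.  Features absent from an
    otherwise present (subject, timepoint) sample are set to
    ``fill_value`` (0 for count data).  A whole (subject, timepoint)
    sample with no records at all is an error in ``strict`` mode; in
    ``impute`` mode it is recorded in ``missing_mask`` and left NaN for
    :func:`impute_missing`.
    """
    if mode not in ("strict", "impute"):
        raise ValueError(f"mode must be 'strict' or 'impute', got {mode!r}")
    if len(table) == 0:
        raise ValueError("the long table has no records")
    table = table.copy()
    table["subject"] = table["subject"].astype(str)
    table["time"] = table["time"].astype(str)
    table["feature"] = table["feature"].astype(str)
    timepoint_order = [str(t) for t in timepoint_order]
    extra_times = set(table["time"]) - set(timepoint_order)
    if extra_times:
        raise ValueError(
            f"timepoint_order does not cover timepoints {sorted(extra_times)}"
        )

    dup = table.duplicated(subset=["subject", "time", "feature"])
    if dup.any():
        offenders = table.loc[dup, ["subject", "time", "feature"]].iloc[:5]
        raise ValueError(
            "duplicate (subject, time, feature) keys, e.g.:\n"
            f"{offenders.to_string(index=False)}"
        )

    subjects = sorted(table["subject"].unique())
    features = sorted(table["feature"].unique())
    times = timepoint_order
    m, p, n = len(subjects), len(features), len(times)

    s_idx = {s: i for i, s in enumerate(subjects)}
    f_idx = {f: j for j, f in enumerate(features)}
    t_idx = {t: k for k, t in enumerate(times)}

    present = np.zeros((m, n), dtype=bool)
    si = table["subject"].map(s_idx).to_numpy()
    ti = table["time"].map(t_idx).to_numpy()
    fi = table["feature"].map(f_idx).to_numpy()
    present[si, ti] = True

    missing_mask = ~present
    if mode == "strict" and missing_mask.any():
        offenders = [
            f"({subjects[i]}, {times[k]})"
            for i, k in zip(*np.nonzero(missing_mask))
        ]
        raise ValueError(
            "missing (subject, timepoint) samples in strict mode: "
            + ", ".join(offenders)
        )

    tensor = np.full((m, p, n), fill_value, dtype=float)
    tensor[si, fi, ti] = table["value"].to_numpy(dtype=float)
    if mode == "impute" and missing_mask.any():
        for i, k in zip(*np.nonzero(missing_mask)):
            tensor[i, :, k] = np.nan
    return TensorDataset(
        tensor=tensor,
        subject_labels=subjects,
        feature_labels=features,
        timepoint_labels=times,
        normalization_log=[],
        missing_mask=missing_mask if missing_mask.any() else None,
    )


def impute_missing(
    ds: TensorDataset,
    missing_mask: np.ndarray | None = None,
    method: str = "linear",
) -> TensorDataset:
    """Fill whole missing (subject, timepoint) samples.

    ``zeros`` writes 0; ``locf`` carries the last observed timepoint
    forward (and the first observed backward at the start); ``linear``
    interpolates each (subject, feature) tube across time between
    observed samples, clamping at the edges.
    """
    if method not in ("zeros", "locf", "linear"):
        raise ValueError(f"unknown imputation method {method!r}")
    if missing_mask is None:
        missing_mask = ds.missing_mask
    if missing_mask is None or not np.any(missing_mask):
        return ds._with(ds.tensor.copy(), {"op": "impute", "params": {"method": method}},
                        missing_mask=None)
    missing_mask = np.asarray(missing_mask, dtype=bool)
    m, p, n = ds.tensor.shape
    out = ds.tensor.copy()
    for i in range(m):
        miss = missing_mask[i]
        if not miss.any():
            continue
        obs = np.nonzero(~miss)[0]
        if obs.size == 0:
            raise ValueError(
                f"subject {ds.subject_labels[i]!r} has no observed timepoints"
            )
        gap = np.nonzero(miss)[0]
        if method == "zeros":
            out[i, :, gap] = 0.0
        elif method == "locf":
            for k in gap:
                earlier = obs[obs < k]
                src = earlier[-1] if earlier.size else obs[0]
                out[i, :, k] = out[i, :, src]
        else:  # linear, per tube; np.interp clamps at the edges
            for j in range(p):
                out[i, j, gap] = np.interp(gap, obs, out[i, j, obs])
    return ds._with(
        out,
        {"op": "impute", "params": {"method": method,
                                    "mask": missing_mask.tolist()}},
        missing_mask=None,
    )


def _baseline_indices(ds: TensorDataset, baseline: Sequence[str]) -> np.ndarray:
    baseline = [str(b) for b in baseline]
    missing = set(baseline) - set(ds.timepoint_labels)
    if missing:
        raise ValueError(f"baseline timepoints not in dataset: {sorted(missing)}")
    return np.array([ds.timepoint_labels.index(b) for b in baseline])


def normalize_dfb(ds: TensorDataset, baseline: Sequence[str]) -> TensorDataset:
    """Deviation from baseline: subtract each subject's own baseline level.

    Multiple baseline timepoints are aggregated by their arithmetic mean
    per (subject, feature) before subtraction, so baseline slices become
    (approximately) zero and are retained in the tensor.
    """
    idx = _baseline_indices(ds, baseline)
    base = ds.tensor[:, :, idx].mean(axis=2, keepdims=True)
    return ds._with(
        ds.tensor - base, {"op": "dfb", "params": {"baseline": [str(b) for b in baseline]}}
    )


def normalize_lfb(
    ds: TensorDataset,
    baseline: Sequence[str],
    pseudocount: float = 1.0,
    log_base: float = 2.0,
) -> TensorDataset:
    """Log-fold change from baseline: log_b((x_t + c) / (x_base + c)).

    The pseudocount c enters both numerator and denominator, so a value
    equal to its baseline maps to 0 regardless of c; baseline timepoints
    map to exactly 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(ds.tensor < 0):
        raise ValueError("LFB requires non-negative values (counts/abundances)")
    idx = _baseline_indices(ds, baseline)
    base = ds.tensor[:, :, idx].mean(axis=2, keepdims=True)
    out = (np.log(ds.tensor + pseudocount) - np.log(base + pseudocount)) / np.log(log_base)
    return ds._with(
        out,
        {"op": "lfb", "params": {"baseline": [str(b) for b in baseline],
                                 "pseudocount": pseudocount,
                                 "log_base": log_base}},
    )


def normalize_rclr(ds: TensorDataset) -> TensorDataset:
    """Robust centered log-ratio, per sample (one subject × timepoint vector).

    Each nonzero entry becomes ln(x) minus the mean ln over that sample's
    nonzero entries; zeros are excluded from the geometric mean and
    remain zero (the matched-mask convention for sparse compositions).
    """
    x = ds.tensor
    if np.any(x < 0):
        raise ValueError("rclr requires non-negative values")
    nz = x > 0
    counts = nz.sum(axis=1, keepdims=True)  # nonzero features per sample
    if np.any(counts == 0):
        bad = np.argwhere(counts[:, 0, :] == 0)
        i, k = bad[0]
        raise ValueError(
            f"sample ({ds.subject_labels[i]}, {ds.timepoint_labels[k]}) "
            "has all-zero features; rclr is undefined"
        )
    logx = np.where(nz, np.log(x, where=nz, out=np.zeros_like(x)), 0.0)
    gmean_log = logx.sum(axis=1, keepdims=True) / counts
    out = np.where(nz, logx - gmean_log, 0.0)
    return ds._with(out, {"op": "rclr", "params": {}})


def filter_features(
    ds: TensorDataset, min_prevalence: float = 0.0, min_mean_value: float = 0.0
) -> TensorDataset:
    """Keep features by nonzero prevalence and overall mean value."""
    x = ds.tensor
    prevalence = (x != 0).mean(axis=(0, 2))
    mean_value = x.mean(axis=(0, 2))
    keep = (prevalence >= min_prevalence) & (mean_value >= min_mean_value)
    if not keep.any():
        raise ValueError("feature filter removed every feature")
    return replace(
        ds,
        tensor=x[:, keep, :],
        feature_labels=[f for f, k in zip(ds.feature_labels, keep) if k],
        normalization_log=ds.normalization_log
        + [{"op": "filter_features",
            "params": {"min_prevalence": min_prevalence,
                       "min_mean_value": min_mean_value}}],
    )


_REPLAY = {
    "dfb": lambda ds, p: normalize_dfb(ds, p["baseline"]),
    "lfb": lambda ds, p: normalize_lfb(ds, p["baseline"], p["pseudocount"], p["log_base"]),
    "rclr": lambda ds, p: normalize_rclr(ds),
    "filter_features": lambda ds, p: filter_features(
        ds, p["min_prevalence"], p["min_mean_value"]),
    "impute": lambda ds, p: impute_missing(
        ds, np.array(p["mask"], dtype=bool) if "mask" in p else None, p["method"]),
}


def replay_log(raw: TensorDataset, log: Sequence[dict]) -> TensorDataset:
    """Re-apply a normalization log to raw data; reproduces outputs bitwise."""
    ds = raw
    for entry in log:
        op = entry["op"]
        if op not in _REPLAY:
            raise ValueError(f"unknown normalization op {op!r}")
        ds = _REPLAY[op](ds, entry.get("params", {}))
    return ds


def to_long_frame(ds: TensorDataset) -> pd.DataFrame:
    """Export back to the tidy long format (round-trips through assemble)."""
    m, p, n = ds.tensor.shape
    si, fi, ti = np.meshgrid(np.arange(m), np.arange(p), np.arange(n),
                             indexing="ij")
    return pd.DataFrame(
        {
            "subject": np.array(ds.subject_labels)[si.ravel()],
            "time": np.array(ds.timepoint_labels)[ti.ravel()],
            "feature": np.array(ds.feature_labels)[fi.ravel()],
            "value": ds.tensor.ravel(),
        }
    )
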