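"""Raw expression matrices to per-instance differential profiles.

Two platform paths are supported:

* array path: quantile normalization, per-gene batch-mean centering, then
  subtraction of the averaged vehicle (DMSO) controls of the same batch and
  cell line from each treatment sample;
* L1000-style path: per-gene robust z-scores (median/MAD) across the samples
  of each plate grouping.

Matrices are pandas DataFrames with genes as rows and samples as columns;
sample metadata is a DataFrame with one row per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency constant: scaled MAD estimates a Gaussian sd


@dataclass
class TreatmentProfile:
    """Per-gene differential vector for one treatment sample."""

    instance_id: str
    perturbagen: str
    dose: float
    cell_line: str
    replicate_index: int
    values: pd.Series  # indexed by gene ID; treatment-to-control log2 diff or robust z
    batch: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"profile {self.instance_id} contains non-finite values")


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene IDs in matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in matrix")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("matrix contains non-finite values")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common distribution of per-rank means.

    Each column's values are replaced, in their original rank order, by the
    mean across columns of the column-sorted values. Tied values within a
    column receive the mean of the rank means their tie run spans, so the
    operation is well defined and idempotent in the presence of ties.
    """
    _check_matrix(matrix)
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: single-column matrix returned unchanged")
        return matrix.copy()

    values = matrix.to_numpy(dtype=float)
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # runs of tied values share the mean of the rank means they span
        run_starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        run_ends = np.r_[run_starts[1:], len(col)]
        cum = np.r_[0.0, np.cumsum(rank_means)]
        run_means = (cum[run_ends] - cum[run_starts]) / (run_ends - run_starts)
        normalized = np.repeat(run_means, run_ends - run_starts)
        out[order, j] = normalized
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def batch_correct(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Center each batch's per-gene mean onto the gene's grand mean.

    Within-batch contrasts are untouched; the per-gene grand mean is preserved
    exactly. Single-sample batches are corrected like any other but flagged in
    the log, since their shift absorbs sample noise.
    """
    _check_matrix(matrix)
    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    batches = meta.loc[matrix.columns, "batch"]
    if batches.isna().any():
        raise ValueError("every sample needs a batch label")

    grand_mean = matrix.mean(axis=1)
    out = matrix.copy()
    for batch, sample_ids in batches.groupby(batches).groups.items():
        cols = list(sample_ids)
        if len(cols) == 1:
            logger.warning("batch_correct: batch %r has a single sample; shift applied anyway", batch)
        shift = grand_mean - matrix[cols].mean(axis=1)
        out[cols] = matrix[cols].add(shift, axis=0)
    return out


def treatment_to_control(matrix: pd.DataFrame, metadata: pd.DataFrame) -> list[TreatmentProfile]:
    """Subtract the averaged vehicle controls of each (batch, cell line) stratum.

    Every treatment sample yields one profile: its log2 values minus the mean
    of all vehicle samples sharing its batch and cell line. Vehicle samples
    yield no profiles.
    """
    _check_matrix(matrix)
    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    meta = meta.loc[matrix.columns]

    control_means: dict[tuple, pd.Series] = {}
    for (batch, cell_line), sub in meta[meta["is_vehicle"]].groupby(["batch", "cell_line"]):
        control_means[(batch, cell_line)] = matrix[list(sub.index)].mean(axis=1)

    profiles: list[TreatmentProfile] = []
    replicate_counter: dict[tuple, int] = {}
    for sample_id, row in meta[~meta["is_vehicle"]].iterrows():
        stratum = (row["batch"], row["cell_line"])
        if stratum not in control_means:
            raise ValueError(
                f"treatment sample {sample_id!r} has no vehicle control in stratum "
                f"(batch={row['batch']!r}, cell_line={row['cell_line']!r})"
            )
        key = (row["perturbagen"], row["dose"], row["cell_line"])
        idx = replicate_counter.get(key, 0)
        replicate_counter[key] = idx + 1
        profiles.append(
            TreatmentProfile(
                instance_id=str(sample_id),
                perturbagen=str(row["perturbagen"]),
                dose=float(row["dose"]),
                cell_line=str(row["cell_line"]),
                batch=str(row["batch"]),
                replicate_index=idx,
                values=matrix[sample_id] - control_means[stratum],
            )
        )
    return profiles


def profiles_from_matrix(matrix: pd.DataFrame, metadata: pd.DataFrame) -> list[TreatmentProfile]:
    """Wrap each non-vehicle column of a differential matrix as a TreatmentProfile.

    Used on the L1000-style path, where robust z-scores are already
    differential values and need no control subtraction.
    """
    _check_matrix(matrix)
    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    profiles: list[TreatmentProfile] = []
    replicate_counter: dict[tuple, int] = {}
    for sample_id, row in meta.loc[matrix.columns][~meta.loc[matrix.columns, "is_vehicle"]].iterrows():
        key = (row["perturbagen"], row["dose"], row["cell_line"])
        idx = replicate_counter.get(key, 0)
        replicate_counter[key] = idx + 1
        profiles.append(
            TreatmentProfile(
                instance_id=str(sample_id),
                perturbagen=str(row["perturbagen"]),
                dose=float(row["dose"]),
                cell_line=str(row["cell_line"]),
                batch=str(row.get("batch", "")),
                replicate_index=idx,
                values=matrix[sample_id],
            )
        )
    return profiles


def robust_zscore(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    plate_col: str = "plate",
) -> pd.DataFrame:
    """Per-gene robust z-scores: (value - median) / (MAD * 1.4826), per plate group.

    The median and MAD are taken across the samples of each plate grouping
    (from ``metadata[plate_col]`` when present, else the whole matrix is one
    group). Genes with zero MAD in a group get z = 0 and a log warning.
    """
    _check_matrix(matrix)
    if metadata is not None and plate_col in metadata.columns:
        plates = metadata.set_index("sample_id").loc[matrix.columns, plate_col]
    else:
        plates = pd.Series("plate0", index=matrix.columns)

    out = matrix.astype(float).copy()
    for plate, sample_ids in plates.groupby(plates).groups.items():
        cols = list(sample_ids)
        if len(cols) < 3:
            raise ValueError(f"plate grouping {plate!r} has {len(cols)} samples; >= 3 required")
        block = matrix[cols].to_numpy(dtype=float)
        med = np.median(block, axis=1, keepdims=True)
        mad = np.median(np.abs(block - med), axis=1, keepdims=True)
        zero_mad = mad[:, 0] == 0
        if zero_mad.any():
            logger.warning(
                "robust_zscore: %d gene(s) with zero MAD in plate %r set to z=0",
                int(zero_mad.sum()), plate,
            )
        scale = np.where(mad == 0, np.inf, mad * MAD_SCALE)
        out[cols] = (block - med) / scale
    return out
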