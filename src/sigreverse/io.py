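"""Readers and writers for the package's plain-text interchange formats.

Expression matrices travel as TSV with gene IDs in the first column and one
column per sample; sample metadata as TSV with one row per sample; animal
observations as CSV; ground-truth bookkeeping as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

METADATA_COLUMNS = ["sample_id", "perturbagen", "dose", "cell_line", "batch", "is_vehicle"]
ANIMAL_COLUMNS = ["animal_id", "group", "day", "weight_pct_change", "stool_category", "blood_category"]


def gene_labels(n_genes: int) -> list[str]:
    """Zero-padded synthetic gene identifiers ``g00000`` ... shared across modules."""
    width = max(5, len(str(n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="gene_id")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes[:5]}")
    if matrix.columns.duplicated().any():
        raise ValueError(f"duplicate sample IDs in {path}")
    if not matrix.map(lambda v: pd.notna(v)).all().all():
        raise ValueError(f"non-finite or missing values in {path}")
    return matrix


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False, columns=[c for c in METADATA_COLUMNS if c in metadata.columns] + [c for c in metadata.columns if c not in METADATA_COLUMNS])


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    metadata = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata {path} is missing columns {missing}")
    metadata["is_vehicle"] = metadata["is_vehicle"].astype(bool)
    return metadata


def write_animal_csv(observations: pd.DataFrame, path: str | Path) -> None:
    observations.to_csv(path, index=False)


def read_animal_csv(path: str | Path) -> pd.DataFrame:
    observations = pd.read_csv(path)
    missing = [c for c in ANIMAL_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"animal table {path} is missing columns {missing}")
    return observations


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
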