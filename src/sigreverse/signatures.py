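"""Disease signatures: top up/down-regulated genes of a disease-vs-normal cohort.

A signature is the pair of ordered gene lists -- by default the 250 most
up-regulated and 250 most down-regulated genes by fold change (difference of
group means on the log2 scale) between disease and normal samples. Cohorts
with fewer than 3 samples in either group are rejected.

Signatures serialize to a GMT-compatible two-record file (``<id>_UP`` and
``<id>_DN`` lines) with a JSON sidecar carrying tissue/disease/species
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CohortDesign:
    """Which samples of a cohort matrix are disease vs normal."""

    disease_sample_ids: tuple[str, ...]
    normal_sample_ids: tuple[str, ...]
    tissue: str = ""
    disease: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.disease_sample_ids or not self.normal_sample_ids:
            raise ValueError("both sample lists must be nonempty")
        if set(self.disease_sample_ids) & set(self.normal_sample_ids):
            raise ValueError("disease and normal sample lists must be disjoint")


@dataclass(frozen=True)
class DiseaseSignature:
    """Ordered up/down gene lists with provenance metadata.

    ``up_genes`` is ordered most up-regulated first, ``down_genes`` most
    down-regulated first; the two lists are disjoint and each has exactly
    ``size_per_direction`` entries.
    """

    signature_id: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    size_per_direction: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.up_genes) != self.size_per_direction or len(self.down_genes) != self.size_per_direction:
            raise ValueError(
                f"signature {self.signature_id!r}: each direction needs exactly "
                f"{self.size_per_direction} genes"
            )
        if len(set(self.up_genes)) != len(self.up_genes):
            raise ValueError(f"signature {self.signature_id!r}: duplicate gene in up list")
        if len(set(self.down_genes)) != len(self.down_genes):
            raise ValueError(f"signature {self.signature_id!r}: duplicate gene in down list")
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError(f"signature {self.signature_id!r}: up and down lists overlap")


def fold_changes(matrix: pd.DataFrame, design: CohortDesign) -> pd.Series:
    """Per-gene disease-minus-normal difference of group means (log2 scale)."""
    missing = [s for s in (*design.disease_sample_ids, *design.normal_sample_ids)
               if s not in matrix.columns]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing[:5]}")
    disease_mean = matrix[list(design.disease_sample_ids)].mean(axis=1)
    normal_mean = matrix[list(design.normal_sample_ids)].mean(axis=1)
    return disease_mean - normal_mean


def build_signature(
    matrix: pd.DataFrame,
    design: CohortDesign,
    signature_id: str = "signature",
    size_per_direction: int = 250,
    min_per_group: int = 3,
) -> DiseaseSignature:
    """Build a disease signature from a cohort matrix.

    Genes are ranked by fold change (difference of log2 group means); the top
    ``size_per_direction`` in each direction form the up and down lists. Ties
    are broken by lexicographic gene ID for determinism. Cohorts with fewer
    than ``min_per_group`` samples in either group are rejected.
    """
    if len(design.disease_sample_ids) < min_per_group:
        raise ValueError(
            f"disease group has {len(design.disease_sample_ids)} samples; "
            f"at least {min_per_group} disease samples are required"
        )
    if len(design.normal_sample_ids) < min_per_group:
        raise ValueError(
            f"normal group has {len(design.normal_sample_ids)} samples; "
            f"at least {min_per_group} normal samples are required"
        )
    n_genes = matrix.shape[0]
    if n_genes < 2 * size_per_direction:
        raise ValueError(
            f"matrix has {n_genes} genes; >= {2 * size_per_direction} required for "
            f"{size_per_direction} genes per direction"
        )

    fc = fold_changes(matrix, design)
    gene_ids = fc.index.to_numpy(dtype=object)
    values = fc.to_numpy(dtype=float)
    # lexsort: last key is primary; ties in fold change break by gene ID
    up = tuple(gene_ids[np.lexsort((gene_ids, -values))][:size_per_direction])
    # the down list draws from the remaining genes so ties straddling both
    # cuts can never put one gene in both directions
    keep = ~np.isin(gene_ids, up)
    down_ids, down_values = gene_ids[keep], values[keep]
    down = tuple(down_ids[np.lexsort((down_ids, down_values))][:size_per_direction])

    return DiseaseSignature(
        signature_id=signature_id,
        up_genes=up,
        down_genes=down,
        size_per_direction=size_per_direction,
        metadata={"tissue": design.tissue, "disease": design.disease,
                  "species": design.species, "source": "cohort fold change"},
    )


def write_signature(signature: DiseaseSignature, path: str | Path) -> None:
    """Write a signature as a two-record GMT file plus a JSON metadata sidecar."""
    path = Path(path)
    desc = signature.metadata.get("source", "")
    lines = [
        "\t".join([f"{signature.signature_id}_UP", desc, *signature.up_genes]),
        "\t".join([f"{signature.signature_id}_DN", desc, *signature.down_genes]),
    ]
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "signature_id": signature.signature_id,
        "size_per_direction": signature.size_per_direction,
        "metadata": signature.metadata,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_signature(path: str | Path) -> DiseaseSignature:
    """Read a signature written by :func:`write_signature`; validates invariants."""
    path = Path(path)
    records: dict[str, tuple[str, ...]] = {}
    sig_id = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT record (need id, description, genes)")
        name, _desc, *genes = fields
        if name.endswith("_UP"):
            base, direction = name[:-3], "up"
        elif name.endswith("_DN"):
            base, direction = name[:-3], "down"
        else:
            raise ValueError(f"{path}:{lineno}: record name {name!r} must end in _UP or _DN")
        if sig_id is None:
            sig_id = base
        elif base != sig_id:
            raise ValueError(f"{path}:{lineno}: mixed signature IDs {sig_id!r} and {base!r}")
        if direction in records:
            raise ValueError(f"{path}:{lineno}: duplicate {direction} record")
        records[direction] = tuple(genes)
    if sig_id is None or set(records) != {"up", "down"}:
        raise ValueError(f"{path}: expected exactly one _UP and one _DN record")

    sidecar_path = Path(str(path) + ".json")
    metadata: dict = {}
    size = len(records["up"])
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        metadata = sidecar.get("metadata", {})
        size = sidecar.get("size_per_direction", size)
    return DiseaseSignature(
        signature_id=sig_id,
        up_genes=records["up"],
        down_genes=records["down"],
        size_per_direction=size,
        metadata=metadata,
    )
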