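"""Synthetic data with known ground truth for every pipeline input.

Three generators cover the three kinds of input the pipeline consumes:

* :func:`generate_disease_cohort` -- a disease/normal expression cohort with an
  embedded per-gene effect vector (the truth a signature should recover);
* :func:`generate_compound_experiment` -- a compound-treatment experiment with
  vehicle controls, batch structure and, for selected compounds, a treatment
  effect that is a scaled copy of a registered disease effect (negative scale
  = a reverser, the ground truth connectivity scoring should recover);
* :func:`generate_animal_study` -- per-animal daily colitis observations whose
  implied Disease Activity Index follows requested group trajectories.

All randomness flows through :class:`numpy.random.Generator` seeded from the
config, so identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sigreverse.io import METADATA_COLUMNS, gene_labels
from sigreverse.signatures import CohortDesign

BASELINE_MEAN = 7.0  # log2 intensity center of simulated baselines
BASELINE_SD = 1.0

# representative percent weight change for each weight-loss score band
_WEIGHT_REPRESENTATIVE = {0: 0.0, 1: -3.0, 2: -7.5, 3: -12.5, 4: -18.0}
_STOOL_LEVELS = ["normal", "loose", "diarrhea"]
_BLOOD_LEVELS = ["none", "visible", "rectal"]


@dataclass(frozen=True)
class SimConfig:
    """Shape and noise parameters of a simulated compound screen.

    noise_sd and batch_sd are on the log2-intensity scale. The defaults mirror
    the screening design the pipeline targets: triplicate treatment instances
    with vehicle (DMSO) controls in every batch/cell-line stratum.
    """

    n_genes: int = 2000
    n_compounds: int = 20
    n_batches: int = 2
    cell_lines: tuple[str, ...] = ("MCF7",)
    replicates_per_instance: int = 3
    controls_per_batch: int = 3
    noise_sd: float = 0.2
    batch_sd: float = 0.5
    dose: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 500:
            raise ValueError("n_genes must be >= 500 (signature construction needs >= 2 x 250 genes)")
        for name in ("n_compounds", "n_batches", "replicates_per_instance", "controls_per_batch"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not self.cell_lines:
            raise ValueError("cell_lines must be nonempty")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ValueError("noise_sd and batch_sd must be nonnegative")


@dataclass(frozen=True)
class EmbeddedEffect:
    """Ground-truth treatment effect: ``strength`` x a registered disease effect.

    strength < 0 embeds a reverser; affected_gene_fraction subsamples which
    genes of the disease effect the compound actually moves.
    """

    target_signature_id: str
    strength: float
    affected_gene_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.affected_gene_fraction <= 1.0):
            raise ValueError("affected_gene_fraction must be in (0, 1]")


@dataclass
class DiseaseCohort:
    """A simulated disease/normal cohort plus its ground-truth effect vector."""

    cohort_id: str
    matrix: pd.DataFrame  # genes x samples, log2 intensities
    design: CohortDesign
    effect: pd.Series  # true disease-minus-normal mean difference per gene

    @property
    def groups(self) -> pd.Series:
        labels = {s: "disease" for s in self.design.disease_sample_ids}
        labels.update({s: "normal" for s in self.design.normal_sample_ids})
        return pd.Series(labels, name="group")


def generate_disease_cohort(
    n_genes: int,
    n_disease: int,
    n_normal: int,
    effect_sd: float = 1.0,
    affected_fraction: float = 0.25,
    noise_sd: float = 0.3,
    seed: int = 0,
    cohort_id: str = "cohort",
    tissue: str = "",
    disease: str = "",
    species: str = "",
) -> DiseaseCohort:
    """Simulate a disease-vs-normal log2 expression cohort.

    A random ``round(affected_fraction * n_genes)`` subset of genes carries a
    zero-centered Gaussian effect (sd ``effect_sd``, random sign by symmetry)
    added to the disease group; all samples get i.i.d. Gaussian noise with sd
    ``noise_sd``. The returned effect vector is the exact expected
    disease-minus-normal group-mean difference.
    """
    if n_disease < 1 or n_normal < 1:
        raise ValueError("n_disease and n_normal must be positive counts")
    if n_genes < 500:
        raise ValueError("n_genes must be >= 500")
    if not (0.0 <= affected_fraction <= 1.0):
        raise ValueError("affected_fraction must be in [0, 1]")
    if effect_sd < 0 or noise_sd < 0:
        raise ValueError("effect_sd and noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    genes = gene_labels(n_genes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)

    n_affected = int(round(affected_fraction * n_genes))
    effect = np.zeros(n_genes)
    affected = rng.choice(n_genes, size=n_affected, replace=False)
    effect[affected] = rng.normal(0.0, effect_sd, size=n_affected)

    disease_ids = [f"{cohort_id}_dis_{i:02d}" for i in range(n_disease)]
    normal_ids = [f"{cohort_id}_nrm_{i:02d}" for i in range(n_normal)]
    values = np.empty((n_genes, n_disease + n_normal))
    for j in range(n_disease):
        values[:, j] = baseline + effect + rng.normal(0.0, noise_sd, size=n_genes)
    for j in range(n_normal):
        values[:, n_disease + j] = baseline + rng.normal(0.0, noise_sd, size=n_genes)

    matrix = pd.DataFrame(values, index=genes, columns=disease_ids + normal_ids)
    design = CohortDesign(
        disease_sample_ids=tuple(disease_ids),
        normal_sample_ids=tuple(normal_ids),
        tissue=tissue,
        disease=disease,
        species=species,
    )
    return DiseaseCohort(
        cohort_id=cohort_id,
        matrix=matrix,
        design=design,
        effect=pd.Series(effect, index=genes, name="effect"),
    )


def generate_compound_experiment(
    config: SimConfig,
    effects: Sequence[EmbeddedEffect] = (),
    disease_effects: Mapping[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a compound-treatment expression experiment with vehicle controls.

    Compound ``i`` carries ``effects[i]`` when present (remaining compounds are
    nulls). Each referenced ``target_signature_id`` must appear in
    ``disease_effects`` (typically ``{cohort.cohort_id: cohort.effect}`` from
    :func:`generate_disease_cohort`) with a gene index matching ``n_genes``.

    Returns ``(matrix, metadata, truth)``: a genes x samples log2 matrix, a
    metadata table with one row per sample (perturbagen, dose, cell line,
    batch, vehicle flag), and a truth dict recording each compound's target,
    strength and affected genes.
    """
    disease_effects = dict(disease_effects or {})
    if len(effects) > config.n_compounds:
        raise ValueError("more embedded effects than compounds")
    genes = None
    for eff in effects:
        if eff.target_signature_id not in disease_effects:
            known = sorted(disease_effects)
            raise KeyError(
                f"effect targets unknown signature {eff.target_signature_id!r}; registered: {known}"
            )
        vec = disease_effects[eff.target_signature_id]
        if len(vec) != config.n_genes:
            raise ValueError(
                f"disease effect {eff.target_signature_id!r} has {len(vec)} genes, "
                f"config expects {config.n_genes}"
            )
        if genes is None:
            genes = list(vec.index)
        elif list(vec.index) != genes:
            raise ValueError("registered disease effects have inconsistent gene indices")
    if genes is None:
        genes = gene_labels(config.n_genes)

    rng = np.random.default_rng(config.seed)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    batches = [f"batch{b}" for b in range(config.n_batches)]
    batch_offsets = {b: rng.normal(0.0, config.batch_sd, size=config.n_genes) for b in batches}

    strata = [(b, cl) for b in batches for cl in config.cell_lines]
    compounds = [f"cmpd_{i:03d}" for i in range(config.n_compounds)]

    truth: dict = {"compounds": {}, "seed": config.seed}
    columns: list[str] = []
    meta_rows: list[dict] = []
    data: list[np.ndarray] = []

    # vehicle controls: controls_per_batch per (batch, cell line) stratum
    for batch, cell_line in strata:
        for k in range(config.controls_per_batch):
            sid = f"veh_{batch}_{cell_line}_{k:02d}"
            columns.append(sid)
            meta_rows.append(
                dict(sample_id=sid, perturbagen="DMSO", dose=0.0, cell_line=cell_line,
                     batch=batch, is_vehicle=True)
            )
            data.append(baseline + batch_offsets[batch]
                        + rng.normal(0.0, config.noise_sd, size=config.n_genes))

    for i, compound in enumerate(compounds):
        batch, cell_line = strata[i % len(strata)]
        effect_vec = np.zeros(config.n_genes)
        record = {"target": None, "strength": 0.0, "affected_genes": [],
                  "batch": batch, "cell_line": cell_line}
        if i < len(effects):
            eff = effects[i]
            d = disease_effects[eff.target_signature_id].to_numpy(dtype=float)
            n_aff = int(round(eff.affected_gene_fraction * config.n_genes))
            affected = np.sort(rng.choice(config.n_genes, size=n_aff, replace=False))
            effect_vec[affected] = eff.strength * d[affected]
            record = {"target": eff.target_signature_id, "strength": eff.strength,
                      "affected_genes": [genes[a] for a in affected],
                      "batch": batch, "cell_line": cell_line}
        truth["compounds"][compound] = record
        for r in range(config.replicates_per_instance):
            sid = f"{compound}_{batch}_{cell_line}_r{r}"
            columns.append(sid)
            meta_rows.append(
                dict(sample_id=sid, perturbagen=compound, dose=config.dose,
                     cell_line=cell_line, batch=batch, is_vehicle=False)
            )
            data.append(baseline + batch_offsets[batch] + effect_vec
                        + rng.normal(0.0, config.noise_sd, size=config.n_genes))

    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    return matrix, metadata, truth


def _latent_to_observation(lam: float) -> tuple[float, str, str]:
    """Map a latent severity in [0, 4] to co-varying DAI components."""
    weight_score = int(np.clip(np.floor(lam + 0.5), 0, 4))
    weight_pct = _WEIGHT_REPRESENTATIVE[weight_score]
    cat_idx = 0 if lam < 1.0 else (1 if lam < 3.0 else 2)
    return weight_pct, _STOOL_LEVELS[cat_idx], _BLOOD_LEVELS[cat_idx]


def generate_animal_study(
    group_sizes: Mapping[str, int],
    dai_trajectories: Mapping[str, Sequence[float]],
    dispersion: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-animal daily colitis observations.

    Each group follows its requested mean-DAI trajectory on a common day grid
    (day 0 is the first entry). A latent severity per animal-day -- the
    trajectory value scaled by a mean-one lognormal factor combining an
    animal random effect (log-sd ``dispersion``) and day-level noise (log-sd
    ``dispersion / 2``), clipped to [0, 4] -- is thresholded into the
    weight-loss, stool and blood components so the three scores co-vary as
    they do biologically. The multiplicative form keeps disease-free days
    exactly at zero severity; ``dispersion = 0`` makes all animals in a group
    identical.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    missing = [g for g in group_sizes if g not in dai_trajectories]
    if missing:
        raise ValueError(f"groups without DAI trajectories: {missing}")
    lengths = {len(dai_trajectories[g]) for g in group_sizes}
    if lengths == {0}:
        raise ValueError("empty day grid: trajectories have no days")
    if len(lengths) != 1:
        raise ValueError("trajectories must share a common day grid")
    n_days = lengths.pop()
    if n_days == 0:
        raise ValueError("empty day grid: trajectories have no days")

    rng = np.random.default_rng(seed)
    rows = []
    for group in group_sizes:
        traj = np.asarray(dai_trajectories[group], dtype=float)
        if np.any(traj < 0) or np.any(traj > 4):
            raise ValueError(f"DAI trajectory for group {group!r} leaves [0, 4]")
        sigma2 = dispersion**2 + (dispersion / 2.0) ** 2
        for a in range(group_sizes[group]):
            animal_id = f"{group}_{a:02d}"
            animal_re = rng.normal(0.0, dispersion) if dispersion > 0 else 0.0
            for day in range(n_days):
                eps = rng.normal(0.0, dispersion / 2.0) if dispersion > 0 else 0.0
                # mean-one lognormal severity factor; zero trajectory stays zero
                factor = math.exp(animal_re + eps - sigma2 / 2.0)
                lam = float(np.clip(traj[day] * factor, 0.0, 4.0))
                weight_pct, stool, blood = _latent_to_observation(lam)
                rows.append(dict(animal_id=animal_id, group=group, day=day,
                                 weight_pct_change=weight_pct,
                                 stool_category=stool, blood_category=blood))
    return pd.DataFrame(rows)
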