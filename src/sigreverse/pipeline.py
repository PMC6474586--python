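"""Stage orchestration: simulate -> process -> signatures -> score -> report.

Each stage reads and writes the plain-text formats of :mod:`sigreverse.io`,
records nothing hidden, and never mutates its inputs; :func:`run_pipeline`
chains them and writes a manifest with every parameter, the seed, and a
SHA-256 checksum of every output so a rerun with the same config is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from sigreverse import io as srio
from sigreverse.preclinical import auc_by_animal, score_animal_table, summarize_groups
from sigreverse.processing import (
    TreatmentProfile,
    batch_correct,
    profiles_from_matrix,
    quantile_normalize,
    robust_zscore,
    treatment_to_control,
)
from sigreverse.scoring import build_hit_table, score_screen
from sigreverse.signatures import CohortDesign, build_signature, read_signature, write_signature
from sigreverse.simulate import (
    EmbeddedEffect,
    SimConfig,
    generate_animal_study,
    generate_compound_experiment,
    generate_disease_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "screen": {
        "n_genes": 1000,
        "n_compounds": 8,
        "n_batches": 2,
        "cell_lines": ["MCF7"],
        "replicates_per_instance": 3,
        "controls_per_batch": 3,
        "noise_sd": 0.2,
        "batch_sd": 0.5,
        "dose": 10.0,
        "effects": [
            {"target": "uc_epithelium", "strength": -1.0, "affected_gene_fraction": 1.0},
        ],
    },
    "cohorts": [
        {
            "id": "uc_epithelium",
            "n_disease": 6,
            "n_normal": 11,
            "effect_sd": 1.0,
            "affected_fraction": 0.25,
            "noise_sd": 0.3,
            "tissue": "colon epithelium",
            "disease": "ulcerative colitis",
            "species": "human",
        }
    ],
    "signature": {"size_per_direction": 250, "min_per_group": 3},
    "scoring": {"n_permutations": 10000, "platform": "array"},
    "animal_study": {
        "dispersion": 0.3,
        "groups": {"sham": 6, "DSS": 12, "CsA": 6, "EPHX2i": 6},
        "trajectories": {
            "sham": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            "DSS": [0, 0, 0, 0, 0, 0.5, 1.5, 2.5, 3.0, 2.5],
            "CsA": [0, 0, 0, 0, 0, 0.3, 0.9, 1.5, 1.8, 1.5],
            "EPHX2i": [0, 0, 0, 0, 0, 0.2, 0.5, 0.9, 1.1, 0.9],
        },
    },
    "report": {"top_k": 10},
}


# config keys whose values are self-contained collections: an override
# replaces them wholesale instead of deep-merging with the demo defaults
_REPLACE_KEYS = {"cohorts", "effects", "groups", "trajectories"}


def _merge(defaults: dict, overrides: dict) -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        if key not in _REPLACE_KEYS and isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(overrides: dict | None = None) -> dict:
    """Apply user overrides onto the demo defaults."""
    return _merge(DEFAULT_CONFIG, overrides or {})


def sha256_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def simulate_stage(config: dict, out_dir: Path) -> dict[str, Path]:
    """Generate every pipeline input; writes matrices, metadata, truth, animals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    outputs: dict[str, Path] = {}

    cohorts = {}
    for i, spec in enumerate(config["cohorts"]):
        cohort = generate_disease_cohort(
            n_genes=int(config["screen"]["n_genes"]),
            n_disease=int(spec["n_disease"]),
            n_normal=int(spec["n_normal"]),
            effect_sd=float(spec.get("effect_sd", 1.0)),
            affected_fraction=float(spec.get("affected_fraction", 0.25)),
            noise_sd=float(spec.get("noise_sd", 0.3)),
            seed=seed + 1 + i,
            cohort_id=str(spec["id"]),
            tissue=str(spec.get("tissue", "")),
            disease=str(spec.get("disease", "")),
            species=str(spec.get("species", "")),
        )
        cohorts[cohort.cohort_id] = cohort
        matrix_path = out_dir / f"cohort_{cohort.cohort_id}_matrix.tsv"
        srio.write_expression_tsv(cohort.matrix, matrix_path)
        groups_path = out_dir / f"cohort_{cohort.cohort_id}_groups.tsv"
        cohort.groups.rename_axis("sample_id").reset_index().to_csv(groups_path, sep="\t", index=False)
        outputs[f"cohort_{cohort.cohort_id}_matrix"] = matrix_path
        outputs[f"cohort_{cohort.cohort_id}_groups"] = groups_path

    screen_cfg = config["screen"]
    sim = SimConfig(
        n_genes=int(screen_cfg["n_genes"]),
        n_compounds=int(screen_cfg["n_compounds"]),
        n_batches=int(screen_cfg["n_batches"]),
        cell_lines=tuple(screen_cfg["cell_lines"]),
        replicates_per_instance=int(screen_cfg["replicates_per_instance"]),
        controls_per_batch=int(screen_cfg["controls_per_batch"]),
        noise_sd=float(screen_cfg["noise_sd"]),
        batch_sd=float(screen_cfg["batch_sd"]),
        dose=float(screen_cfg.get("dose", 10.0)),
        seed=seed,
    )
    effects = [
        EmbeddedEffect(
            target_signature_id=str(e["target"]),
            strength=float(e["strength"]),
            affected_gene_fraction=float(e.get("affected_gene_fraction", 1.0)),
        )
        for e in screen_cfg.get("effects", [])
    ]
    matrix, metadata, truth = generate_compound_experiment(
        sim, effects, {cid: c.effect for cid, c in cohorts.items()}
    )
    outputs["compound_matrix"] = out_dir / "compound_matrix.tsv"
    srio.write_expression_tsv(matrix, outputs["compound_matrix"])
    outputs["compound_metadata"] = out_dir / "compound_metadata.tsv"
    srio.write_metadata_tsv(metadata, outputs["compound_metadata"])
    outputs["truth"] = out_dir / "truth.json"
    srio.write_json(truth, outputs["truth"])

    animal_cfg = config["animal_study"]
    animals = generate_animal_study(
        group_sizes={k: int(v) for k, v in animal_cfg["groups"].items()},
        dai_trajectories=animal_cfg["trajectories"],
        dispersion=float(animal_cfg.get("dispersion", 0.3)),
        seed=seed + 101,
    )
    outputs["animals"] = out_dir / "animals.csv"
    srio.write_animal_csv(animals, outputs["animals"])
    return outputs


def process_stage(
    matrix_path: Path,
    metadata_path: Path,
    out_dir: Path,
    platform: str = "array",
) -> dict[str, Path]:
    """Raw matrix to per-instance differential profiles for the chosen platform."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = srio.read_expression_tsv(matrix_path)
    metadata = srio.read_metadata_tsv(metadata_path)

    if platform == "array":
        normalized = quantile_normalize(matrix)
        corrected = batch_correct(normalized, metadata)
        profiles = treatment_to_control(corrected, metadata)
    elif platform == "l1000":
        zscores = robust_zscore(matrix, metadata)
        profiles = profiles_from_matrix(zscores, metadata)
    else:
        raise ValueError(f"unknown platform {platform!r}; expected 'array' or 'l1000'")

    values = pd.concat({p.instance_id: p.values for p in profiles}, axis=1)
    values.columns = [p.instance_id for p in profiles]
    profile_meta = pd.DataFrame(
        [dict(sample_id=p.instance_id, perturbagen=p.perturbagen, dose=p.dose,
              cell_line=p.cell_line, batch=p.batch, is_vehicle=False,
              replicate_index=p.replicate_index)
         for p in profiles]
    )
    outputs = {
        "profiles": out_dir / "profiles.tsv",
        "profile_metadata": out_dir / "profile_metadata.tsv",
    }
    srio.write_expression_tsv(values, outputs["profiles"])
    profile_meta.to_csv(outputs["profile_metadata"], sep="\t", index=False)
    return outputs


def read_profiles(profiles_path: Path, profile_metadata_path: Path) -> list[TreatmentProfile]:
    values = srio.read_expression_tsv(profiles_path)
    meta = pd.read_csv(profile_metadata_path, sep="\t").set_index("sample_id")
    profiles = []
    for sid in values.columns:
        if sid not in meta.index:
            raise ValueError(f"profile {sid!r} missing from metadata")
        row = meta.loc[sid]
        profiles.append(TreatmentProfile(
            instance_id=str(sid), perturbagen=str(row["perturbagen"]),
            dose=float(row["dose"]), cell_line=str(row["cell_line"]),
            batch=str(row.get("batch", "")),
            replicate_index=int(row.get("replicate_index", 0)),
            values=values[sid],
        ))
    return profiles


def signatures_stage(
    matrix_path: Path,
    groups_path: Path,
    out_dir: Path,
    signature_id: str,
    size_per_direction: int = 250,
    min_per_group: int = 3,
    tissue: str = "",
    disease: str = "",
    species: str = "",
) -> dict[str, Path]:
    """Build one signature from a cohort matrix + group labels; writes GMT."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = srio.read_expression_tsv(matrix_path)
    groups = pd.read_csv(groups_path, sep="\t").set_index("sample_id")["group"]
    design = CohortDesign(
        disease_sample_ids=tuple(groups.index[groups == "disease"]),
        normal_sample_ids=tuple(groups.index[groups == "normal"]),
        tissue=tissue, disease=disease, species=species,
    )
    signature = build_signature(
        matrix, design, signature_id=signature_id,
        size_per_direction=size_per_direction, min_per_group=min_per_group,
    )
    path = out_dir / f"{signature_id}.gmt"
    write_signature(signature, path)
    return {f"signature_{signature_id}": path, f"signature_{signature_id}_meta": Path(str(path) + ".json")}


def score_stage(
    profiles_path: Path,
    profile_metadata_path: Path,
    signature_paths: list[Path],
    out_path: Path,
    n_permutations: int = 10000,
    seed: int = 0,
    platform: str = "",
) -> dict[str, Path]:
    """Score all instances against all signatures; writes the sorted hit table."""
    profiles = read_profiles(profiles_path, profile_metadata_path)
    signatures = [read_signature(p) for p in signature_paths]
    results = score_screen(
        profiles, signatures, n_permutations=n_permutations, seed=seed, platform=platform
    )
    table = build_hit_table(results, {s.signature_id: s.metadata for s in signatures})
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, sep="\t", index=False)
    return {"hit_table": out_path}


def preclinical_stage(observations_path: Path, out_dir: Path) -> dict[str, Path]:
    """Score animal observations: per-animal DAI and AUC, per-group summaries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    observations = srio.read_animal_csv(observations_path)
    scored = score_animal_table(observations)
    aucs = auc_by_animal(scored)
    group_dai = summarize_groups(scored, "dai", "group")
    group_auc = summarize_groups(aucs, "dai_auc", "group")
    outputs = {
        "dai_per_animal": out_dir / "dai_per_animal.csv",
        "auc_per_animal": out_dir / "auc_per_animal.csv",
        "dai_group_summary": out_dir / "dai_group_summary.csv",
        "auc_group_summary": out_dir / "auc_group_summary.csv",
    }
    scored.to_csv(outputs["dai_per_animal"], index=False)
    aucs.to_csv(outputs["auc_per_animal"], index=False)
    group_dai.to_csv(outputs["dai_group_summary"], index=False)
    group_auc.to_csv(outputs["auc_group_summary"], index=False)
    return outputs


def render_report(
    hit_table: pd.DataFrame,
    preclinical_summaries: dict[str, pd.DataFrame] | None = None,
    top_k: int = 10,
) -> str:
    """Human-readable markdown summary: top reversers plus preclinical tables."""
    lines = ["# Screen report", "", "## Top signature reversers", ""]
    if hit_table.empty:
        lines.append("No hits: the hit table is empty.")
    else:
        top = hit_table.head(top_k)
        lines.append("| instance | signature | mean CMAP score | p-value | specificity |")
        lines.append("|---|---|---|---|---|")
        for row in top.itertuples(index=False):
            lines.append(
                f"| {row.instance_id} | {row.signature_name} | {row.mean_cmap_score:.4f} "
                f"| {row.p_value:.3g} | {row.specificity:.3f} |"
            )
    for name, table in (preclinical_summaries or {}).items():
        lines += ["", f"## Preclinical: {name}", ""]
        lines.append("| " + " | ".join(str(c) for c in table.columns) + " |")
        lines.append("|" + "---|" * len(table.columns))
        for row in table.itertuples(index=False):
            cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
            lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def run_pipeline(config: dict, out_dir: Path) -> dict:
    """Full run: simulate, process, build signatures, score, preclinical, report.

    Returns the manifest (also written to ``manifest.json``): config, seed and
    SHA-256 checksums of every artifact.
    """
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    logger.info("stage: simulate")
    outputs.update(simulate_stage(config, out_dir / "simulated"))

    logger.info("stage: process (platform=%s)", config["scoring"]["platform"])
    outputs.update(process_stage(
        outputs["compound_matrix"], outputs["compound_metadata"],
        out_dir / "processed", platform=config["scoring"]["platform"],
    ))

    logger.info("stage: signatures")
    signature_paths = []
    for spec in config["cohorts"]:
        cid = str(spec["id"])
        stage_out = signatures_stage(
            outputs[f"cohort_{cid}_matrix"], outputs[f"cohort_{cid}_groups"],
            out_dir / "signatures", signature_id=cid,
            size_per_direction=int(config["signature"]["size_per_direction"]),
            min_per_group=int(config["signature"]["min_per_group"]),
            tissue=str(spec.get("tissue", "")), disease=str(spec.get("disease", "")),
            species=str(spec.get("species", "")),
        )
        outputs.update(stage_out)
        signature_paths.append(stage_out[f"signature_{cid}"])

    logger.info("stage: score")
    outputs.update(score_stage(
        outputs["profiles"], outputs["profile_metadata"], signature_paths,
        out_dir / "hits.tsv",
        n_permutations=int(config["scoring"]["n_permutations"]),
        seed=int(config["seed"]),
        platform=str(config["scoring"]["platform"]),
    ))

    logger.info("stage: preclinical")
    outputs.update(preclinical_stage(outputs["animals"], out_dir / "preclinical"))

    logger.info("stage: report")
    hit_table = pd.read_csv(outputs["hit_table"], sep="\t")
    summaries = {
        "DAI by group": pd.read_csv(outputs["dai_group_summary"]),
        "DAI AUC by group": pd.read_csv(outputs["auc_group_summary"]),
    }
    report = render_report(hit_table, summaries, top_k=int(config["report"]["top_k"]))
    report_path = out_dir / "report.md"
    report_path.write_text(report)
    outputs["report"] = report_path

    manifest = {
        "config": config,
        "seed": int(config["seed"]),
        "outputs": {name: str(path) for name, path in outputs.items()},
        "checksums": {name: sha256_file(path) for name, path in sorted(outputs.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
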