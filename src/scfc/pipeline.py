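"""End-to-end orchestration: simulate -> features -> harmonize -> stats.

Stages communicate only via files (manifest CSV, tab-delimited matrices,
feature CSVs), so each stage can be run, tested and replaced independently.
All outputs are plain text; a run log records the configuration, seed and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import scfc
from scfc.matrices import ConnectivityMatrix, read_matrix, write_matrix
from scfc.subnetworks import canonical_subnetworks
from scfc.features import build_feature_table, read_feature_table, write_feature_table
from scfc.harmonize import combat_fit_transform, harmonization_report
from scfc.simulate import (
    GROUPS,
    SITES,
    CohortConfig,
    generate_cohort,
    inject_site_effects,
    records_to_manifest,
)
from scfc import stats as gstats

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "group", "site", "age", "sex", "swan_hyper", "swan_inatt", "sc_path", "fc_path",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and subject context."""


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    out_dir: str = "scfc_out"
    manifest: str | None = None          # defaults to <out_dir>/manifest.csv
    matrix_dir: str | None = None        # defaults to <out_dir>/matrices
    t_points: int = 200
    fdr_q: float = 0.05
    zero_mode: str = "exclude"           # coupling zero-fiber handling
    include_group_covariate: bool = True  # group dummies in the ComBat design
    combat_tol: float = 1e-4
    posthoc_method: str = "tukey"
    seed: int = 0
    subnetwork_file: str | None = None   # override canonical definitions
    inject_site_effects: bool = False    # add configured site effects to features
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError(f"fdr_q must be in (0,1), got {self.fdr_q}")
        if self.manifest is None:
            self.manifest = str(Path(self.out_dir) / "manifest.csv")
        if self.matrix_dir is None:
            self.matrix_dir = str(Path(self.out_dir) / "matrices")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        if "n_per_group" in cohort_raw:
            cohort_raw["n_per_group"] = {
                k: int(v) for k, v in cohort_raw["n_per_group"].items()
            }
        for key in ("site_shift", "site_scale"):
            if key in cohort_raw:
                cohort_raw[key] = {int(k): float(v) for k, v in cohort_raw[key].items()}
        cfg = cls(**raw, cohort=CohortConfig(**cohort_raw))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cohort"]["age_range"] = list(data["cohort"]["age_range"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _subnets(config: PipelineConfig, node_labels: list[str]):
    return canonical_subnetworks(path=config.subnetwork_file, node_labels=node_labels)


def run_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Write a synthetic cohort (manifest, matrices, ground-truth sidecar)."""
    out = Path(config.out_dir)
    mat_dir = Path(config.matrix_dir)
    mat_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    records, matrices = generate_cohort(cohort_cfg)
    for rec in records:
        sc, fc = matrices[rec.subject_id]
        rec.sc_path = str(mat_dir / f"{rec.subject_id}_sc.tsv")
        rec.fc_path = str(mat_dir / f"{rec.subject_id}_fc.tsv")
        write_matrix(sc, rec.sc_path)
        write_matrix(fc, rec.fc_path)
    manifest = records_to_manifest(records)
    manifest.to_csv(config.manifest)
    truth = {
        "coupling_alpha": cohort_cfg.coupling_alpha,
        "edge_density": cohort_cfg.edge_density,
        "beta_hyper": cohort_cfg.beta_hyper,
        "rho_inatt_hyper": cohort_cfg.rho_inatt_hyper,
        "site_shift": cohort_cfg.site_shift,
        "site_scale": cohort_cfg.site_scale,
        "seed": cohort_cfg.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    logger.info("simulated %d subjects into %s", len(records), out)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, index_col="subject_id")
    return manifest


def load_cohort_matrices(
    manifest: pd.DataFrame,
) -> dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]]:
    matrices = {}
    missing = []
    for sid, row in manifest.iterrows():
        try:
            sc = read_matrix(row["sc_path"], modality="SC")
            fc = read_matrix(row["fc_path"], modality="FC")
        except FileNotFoundError:
            missing.append(sid)
            continue
        matrices[sid] = (sc, fc)
    if missing:
        raise PipelineError(f"stage features: missing matrix files for {missing}")
    return matrices


def validate_inputs(manifest_path: str | Path, matrix_dir: str | Path | None = None) -> list[str]:
    """Check manifest vocabulary and matrix files; return finding strings."""
    findings: list[str] = []
    try:
        manifest = load_manifest(manifest_path)
    except Exception as exc:  # unreadable manifest is a single finding
        return [f"manifest unreadable: {exc}"]
    for col in MANIFEST_COLUMNS:
        if col not in manifest.columns:
            findings.append(f"manifest missing column {col!r}")
    if "group" in manifest.columns:
        bad = sorted(set(manifest["group"]) - set(GROUPS))
        if bad:
            findings.append(f"unknown group label(s) {bad}")
    if "site" in manifest.columns:
        bad = sorted(set(manifest["site"].astype(int)) - set(SITES))
        if bad:
            findings.append(f"unknown site label(s) {bad}")
    n_expected = None
    for sid, row in manifest.iterrows():
        for kind, col in (("SC", "sc_path"), ("FC", "fc_path")):
            if col not in manifest.columns:
                continue
            path = Path(row[col])
            if not path.exists():
                findings.append(f"{sid}: missing {kind} file {path}")
                continue
            values = np.loadtxt(path, delimiter="\t", ndmin=2)
            if values.ndim != 2 or values.shape[0] != values.shape[1]:
                findings.append(f"{sid}: {kind} matrix not square {values.shape}")
                continue
            if n_expected is None:
                n_expected = values.shape[0]
            elif values.shape[0] != n_expected:
                findings.append(
                    f"{sid}: {kind} matrix is {values.shape[0]}x{values.shape[0]}, "
                    f"expected {n_expected}"
                )
            asym = np.max(np.abs(values - values.T))
            if asym > 1e-6:
                findings.append(f"{sid}: {kind} matrix asymmetric (max |a-aT| = {asym:g})")
            if kind == "SC" and (values < 0).any():
                findings.append(f"{sid}: SC matrix has negative entries")
    return findings


def run_features(config: PipelineConfig) -> pd.DataFrame:
    """Extract the raw feature table (and optionally inject site effects)."""
    manifest = load_manifest(config.manifest)
    matrices = load_cohort_matrices(manifest)
    labels = next(iter(matrices.values()))[0].node_labels
    subnets = _subnets(config, labels)
    table = build_feature_table(
        matrices, subnets, t_points=config.t_points, q=config.fdr_q,
        zero_mode=config.zero_mode,
    )
    if table.isna().any().any():
        bad = table.columns[table.isna().any(axis=0)].tolist()
        logger.warning("undefined couplings for subjects: %s", bad)
    if config.inject_site_effects:
        table = inject_site_effects(table, manifest["site"], config.cohort)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(
        table, out / "features_raw.csv",
        meta={
            "t_points": config.t_points,
            "fdr_q": config.fdr_q,
            "zero_mode": config.zero_mode,
            "site_effects_injected": config.inject_site_effects,
        },
    )
    return table


def _combat_covariates(manifest: pd.DataFrame, include_group: bool) -> pd.DataFrame:
    covs = pd.DataFrame(index=manifest.index)
    covs["age"] = manifest["age"].astype(float)
    covs["sex_male"] = (manifest["sex"] == "male").astype(float)
    if include_group:
        for g in GROUPS[1:]:
            covs[f"group_{g}"] = (manifest["group"] == g).astype(float)
    return covs


def run_harmonize(config: PipelineConfig) -> pd.DataFrame:
    """ComBat-harmonize the raw feature table across sites."""
    out = Path(config.out_dir)
    table, meta = read_feature_table(out / "features_raw.csv")
    table = table.dropna(axis=1)
    manifest = load_manifest(config.manifest).loc[table.columns]
    covs = _combat_covariates(manifest, config.include_group_covariate)
    harmonized, model = combat_fit_transform(
        table, manifest["site"], covs, tol=config.combat_tol
    )
    write_feature_table(
        harmonized, out / "features_harmonized.csv",
        meta={**meta, "combat_covariates": ",".join(model.covariate_names)},
    )
    harmonization_report(model).to_csv(out / "combat_report.csv", index=False)
    return harmonized


def _table2_report(
    features: pd.DataFrame, manifest: pd.DataFrame, posthoc_method: str
) -> pd.DataFrame:
    """Per-feature ANCOVA with group means/SEMs and pairwise adjusted p."""
    covs = np.column_stack(
        [manifest["age"].to_numpy(float), (manifest["sex"] == "male").to_numpy(float)]
    )
    rows = []
    for feat, values in features.iterrows():
        y = values.to_numpy(float)
        res = gstats.ancova_group_test(
            y, manifest["group"].to_numpy(), covs[:, 0], covs[:, 1]
        )
        row = {"feature": feat, "F": res.statistic, "p": res.p,
               "df_num": res.df[0], "df_den": res.df[1]}
        for g in GROUPS:
            row[f"mean_{g}"] = res.group_means.get(g, np.nan)
            row[f"sem_{g}"] = res.group_sems.get(g, np.nan)
        posthoc = gstats.pairwise_posthoc(
            y, manifest["group"].to_numpy(), covariates=covs, method=posthoc_method
        )
        for pr in posthoc:
            g1, g2 = pr.extra["pair"]
            row[f"p_{g1}_vs_{g2}"] = pr.adjusted_p if pr.adjusted_p is not None else pr.p
        rows.append(row)
    return pd.DataFrame(rows)


def run_stats(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Group, edgewise and behavior statistics on harmonized features."""
    out = Path(config.out_dir)
    features, _ = read_feature_table(out / "features_harmonized.csv")
    manifest = load_manifest(config.manifest).loc[features.columns]

    table2 = _table2_report(features, manifest, config.posthoc_method)
    table2.to_csv(out / "group_report.csv", index=False)

    matrices = load_cohort_matrices(manifest)
    by_group = {g: [sid for sid in features.columns if manifest.loc[sid, "group"] == g]
                for g in GROUPS}
    contrasts = {}
    pairs = [("ADHD-I", "TDC"), ("ADHD-C", "TDC"), ("ADHD-C", "ADHD-I")]
    for g1, g2 in pairs:
        for modality, transform, pos in (("sc", "log1p_sc", 0), ("fc", "fc_z", 1)):
            res = gstats.edgewise_group_contrast(
                [matrices[s][pos] for s in by_group[g1]],
                [matrices[s][pos] for s in by_group[g2]],
                edge_transform=transform,
                q=config.fdr_q,
            )
            name = f"edgewise_{modality}_{g1}_vs_{g2}".replace("-", "")
            res["edges"].to_csv(out / f"{name}.csv", index=False)
            contrasts[name] = res["edges"]

    behavior = gstats.behavior_coupling_analysis(
        features.loc["coupling__DMN"], manifest
    )
    inatt_hyper_rows = []
    for g in GROUPS:
        sub = manifest[manifest["group"] == g]
        res = gstats.pearson_corr_test(sub["swan_hyper"], sub["swan_inatt"])
        inatt_hyper_rows.append(
            {"group": g, "n": len(sub), "r": res.statistic, "p": res.p}
        )
    behavior_corr = pd.concat(
        [behavior["correlations"],
         pd.DataFrame(inatt_hyper_rows).assign(score="inatt_vs_hyper")],
        ignore_index=True,
    )
    behavior_corr.to_csv(out / "behavior_correlations.csv", index=False)
    behavior["differences"].to_csv(out / "behavior_correlation_differences.csv", index=False)
    return {
        "group_report": table2,
        "behavior_correlations": behavior_corr,
        "behavior_differences": behavior["differences"],
        **contrasts,
    }


def run_all(config: PipelineConfig, simulate: bool = True) -> dict[str, pd.DataFrame]:
    """Run every stage in order and write a run log.

    With ``simulate=False`` the manifest and matrices must already exist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[tuple[str, object]] = []
    if simulate:
        stages.append(("simulate", run_simulate))
    stages += [("features", run_features), ("harmonize", run_harmonize), ("stats", run_stats)]
    results: dict[str, pd.DataFrame] = {}
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            res = fn(config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        if name == "stats":
            results = res  # type: ignore[assignment]
    log_lines = [
        f"scfc version: {scfc.__version__}",
        f"numpy version: {np.__version__}",
        f"pandas version: {pd.__version__}",
        f"seed: {config.seed}",
        f"t_points: {config.t_points}",
        f"fdr_q: {config.fdr_q}",
        f"coupling zero_mode: {config.zero_mode}",
        f"posthoc method: {config.posthoc_method}",
        f"site effects injected: {config.inject_site_effects}",
        f"config: {json.dumps(dataclasses.asdict(config), default=str)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results


def analyze_cohort(
    cohort_cfg: CohortConfig,
    q: float = 0.05,
    include_group_covariate: bool = True,
    inject_sites: bool = True,
) -> dict:
    """Generate a cohort and run features -> harmonize -> ANCOVA in memory.

    Convenience wrapper over the same stage functions the file-based
    pipeline uses; returns the manifest, raw and harmonized feature tables,
    and the per-feature ANCOVA report.
    """
    records, matrices = generate_cohort(cohort_cfg)
    manifest = records_to_manifest(records)
    labels = next(iter(matrices.values()))[0].node_labels
    subnets = canonical_subnetworks(node_labels=labels)
    table = build_feature_table(
        matrices, subnets, t_points=cohort_cfg.t_points, q=q
    )
    if inject_sites:
        table = inject_site_effects(table, manifest["site"], cohort_cfg)
    clean = table.dropna(axis=1)
    covs = _combat_covariates(manifest.loc[clean.columns], include_group_covariate)
    harmonized, model = combat_fit_transform(clean, manifest.loc[clean.columns, "site"], covs)
    report = _table2_report(harmonized, manifest.loc[harmonized.columns], "tukey")
    return {
        "manifest": manifest,
        "features_raw": table,
        "features": harmonized,
        "combat_model": model,
        "group_report": report.set_index("feature"),
    }


def manifest_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
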