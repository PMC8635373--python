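"""Synthetic cohort generator.

Emulates the statistical structure of a two-site pediatric cohort with three
diagnostic groups (typically developing children, ADHD inattentive type,
ADHD combined type) and paired structural/functional connectomes:

* SC — symmetric integer fiber-count matrices: an Erdos-Renyi edge pattern
  at a group-specific density with log-normal counts on edges.
* FC — Fisher-z of the sample correlation matrix of ``t_points`` draws from
  a multivariate normal whose target covariance mixes identity with a
  correlation matrix derived from that subject's log fiber counts;
  the mixing weight ``coupling_alpha`` controls how strongly functional
  connectivity follows anatomy.
* Behavior — hyperactivity scores with a group-specific slope on the
  subject's measured DMN coupling, and inattention scores with a
  group-specific target correlation to hyperactivity.
* Site structure — Bernoulli site assignment, with optional additive and
  multiplicative site effects injected into downstream feature tables.

Group-level defaults follow the published cohort: group sizes 56/75/70,
male fractions 0.36/0.72/0.80, hyperactivity means -0.9/0.2/1.2 and
inattention means -0.8/1.2/1.4 (TDC / ADHD-I / ADHD-C), lower structural
density in ADHD groups, and the strongest structure-function coupling in the
combined type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from scfc.matrices import ConnectivityMatrix

GROUPS = ("TDC", "ADHD-I", "ADHD-C")
SITES = (1, 2)


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


def _default_labels(n: int) -> list[str]:
    from scfc.subnetworks import aal90_labels

    if n == 90:
        return aal90_labels()
    return [f"n{i + 1:03d}" for i in range(n)]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort.

    Per-group maps must contain exactly the labels TDC, ADHD-I, ADHD-C.
    ``coupling_alpha`` in [0, 1] mixes identity (0, FC independent of SC)
    with the SC-derived correlation target (1, maximal coupling).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"TDC": 56, "ADHD-I": 75, "ADHD-C": 70}
    )
    n_nodes: int = 90
    edge_density: dict[str, float] = field(
        default_factory=lambda: {"TDC": 0.30, "ADHD-I": 0.25, "ADHD-C": 0.22}
    )
    fiber_logmean: float = 4.0
    fiber_logsd: float = 1.2
    coupling_alpha: dict[str, float] = field(
        default_factory=lambda: {"TDC": 0.43, "ADHD-I": 0.36, "ADHD-C": 0.53}
    )
    t_points: int = 200
    site_prob: float = 0.5
    site_shift: dict[int, float] = field(default_factory=lambda: {1: 0.0, 2: 0.05})
    site_scale: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 1.0})
    swan_hyper_mean: dict[str, float] = field(
        default_factory=lambda: {"TDC": -0.9, "ADHD-I": 0.2, "ADHD-C": 1.2}
    )
    swan_inatt_mean: dict[str, float] = field(
        default_factory=lambda: {"TDC": -0.8, "ADHD-I": 1.2, "ADHD-C": 1.4}
    )
    swan_sd: float = 1.0
    beta_hyper: dict[str, float] = field(
        default_factory=lambda: {"TDC": 0.0, "ADHD-I": -0.3, "ADHD-C": 0.0}
    )
    rho_inatt_hyper: dict[str, float] = field(
        default_factory=lambda: {"TDC": 0.30, "ADHD-I": 0.25, "ADHD-C": 0.62}
    )
    age_range: tuple[float, float] = (6.0, 17.0)
    sex_prob: dict[str, float] = field(
        default_factory=lambda: {"TDC": 0.357, "ADHD-I": 0.72, "ADHD-C": 0.80}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_per_group",
            "edge_density",
            "coupling_alpha",
            "swan_hyper_mean",
            "swan_inatt_mean",
            "beta_hyper",
            "rho_inatt_hyper",
            "sex_prob",
        ):
            mapping = getattr(self, name)
            if set(mapping) != set(GROUPS):
                raise ConfigurationError(
                    f"{name} must have exactly the group labels {GROUPS}, "
                    f"got {sorted(mapping)}"
                )
        for g, a in self.coupling_alpha.items():
            if not 0.0 <= a <= 1.0:
                raise ConfigurationError(f"coupling_alpha[{g}]={a} outside [0, 1]")
        for g, d in self.edge_density.items():
            if not 0.0 <= d <= 1.0:
                raise ConfigurationError(f"edge_density[{g}]={d} outside [0, 1]")
        if self.t_points < 10:
            raise ConfigurationError(f"t_points must be >= 10, got {self.t_points}")
        if set(self.site_shift) != set(SITES) or set(self.site_scale) != set(SITES):
            raise ConfigurationError(f"site maps must have exactly the sites {SITES}")
        if not self.age_range[0] < self.age_range[1] or self.age_range[0] <= 0:
            raise ConfigurationError(f"bad age_range {self.age_range}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectRecord:
    """One subject's demographics, behavior and matrix references."""

    subject_id: str
    group: str
    site: int
    age: float
    sex: str
    swan_hyper: float
    swan_inatt: float
    sc_path: str = ""
    fc_path: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.site not in SITES:
            raise ConfigurationError(f"unknown site {self.site!r}")
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.age <= 0:
            raise ConfigurationError(f"age must be positive, got {self.age}")


def generate_sc_matrix(
    config: CohortConfig, rng: np.random.Generator, group: str
) -> ConnectivityMatrix:
    """Erdos-Renyi edge pattern with log-normal integer fiber counts.

    Counts on present edges are ``round(exp(N(fiber_logmean, fiber_logsd)))``
    clipped below at 1 so that every sampled edge survives the one-fiber
    threshold.
    """
    n = config.n_nodes
    density = config.edge_density[group]
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    counts = np.round(np.exp(rng.normal(config.fiber_logmean, config.fiber_logsd, len(iu[0]))))
    counts = np.maximum(counts, 1.0) * present
    mat = np.zeros((n, n))
    mat[iu] = counts
    mat += mat.T
    return ConnectivityMatrix(
        values=mat, node_labels=_default_labels(n), modality="SC"
    )


def nearest_correlation(c: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result re-standardized
    to unit diagonal.  Deterministic.
    """
    w, v = np.linalg.eigh(0.5 * (c + c.T))
    c_pd = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(c_pd))
    c_pd = c_pd / np.outer(d, d)
    np.fill_diagonal(c_pd, 1.0)
    return 0.5 * (c_pd + c_pd.T)


def _sc_correlation_target(sc_values: np.ndarray) -> np.ndarray:
    """Standardized log(1+SC) as a correlation-like matrix, PD-projected."""
    logw = np.log1p(sc_values)
    peak = logw.max()
    c = logw / peak if peak > 0 else np.zeros_like(logw)
    np.fill_diagonal(c, 1.0)
    return nearest_correlation(c)


def generate_fc_matrix(
    sc: ConnectivityMatrix,
    alpha: float,
    t_points: int,
    rng: np.random.Generator,
) -> ConnectivityMatrix:
    """Fisher-z FC from finite-length time series with SC-matched structure.

    The target covariance is ``(1 - alpha) I + alpha C`` with ``C`` the
    PD-projected standardized log(1+SC) matrix; ``t_points`` independent
    multivariate-normal vectors are drawn and the Fisher-z of their sample
    correlation matrix returned (zero diagonal).  Edgewise SC-FC coupling is
    monotone non-decreasing in ``alpha`` in expectation.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    n = sc.n_nodes
    target = (1.0 - alpha) * np.eye(n) + alpha * _sc_correlation_target(sc.values)
    w, v = np.linalg.eigh(target)
    root = v * np.sqrt(np.maximum(w, 0.0))
    ts = rng.standard_normal((t_points, n)) @ root.T
    corr = np.corrcoef(ts, rowvar=False)
    corr = np.clip(corr, -0.999999, 0.999999)
    z = np.arctanh(corr)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=0.5 * (z + z.T), node_labels=list(sc.node_labels), modality="FC"
    )


def generate_behavior(
    coupling_dmn: np.ndarray,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Hyperactivity and inattention scores for one group's subjects.

    Hyperactivity is the group mean plus ``beta_hyper`` times the
    standardized DMN coupling plus noise scaled so the total SD stays near
    ``swan_sd``; inattention is built to correlate with hyperactivity at the
    group's ``rho_inatt_hyper`` target.
    """
    coupling_dmn = np.asarray(coupling_dmn, dtype=float)
    if not np.all(np.isfinite(coupling_dmn)):
        raise ValueError("coupling values must be finite")
    m = len(coupling_dmn)
    beta = config.beta_hyper[group]
    rho = config.rho_inatt_hyper[group]
    sd_c = coupling_dmn.std()
    z_c = (coupling_dmn - coupling_dmn.mean()) / sd_c if sd_c > 0 else np.zeros(m)
    noise_frac = np.sqrt(max(0.0, 1.0 - min(beta**2, 1.0)))
    z_h = beta * z_c + noise_frac * rng.standard_normal(m)
    hyper = config.swan_hyper_mean[group] + config.swan_sd * z_h
    sd_h = z_h.std()
    z_h_std = (z_h - z_h.mean()) / sd_h if sd_h > 0 else np.zeros(m)
    z_i = rho * z_h_std + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(m)
    inatt = config.swan_inatt_mean[group] + config.swan_sd * z_i
    return hyper, inatt


def inject_site_effects(
    features: pd.DataFrame, sites: pd.Series, config: CohortConfig
) -> pd.DataFrame:
    """Apply ``site_scale * value + site_shift`` per subject column.

    Returns a new table; the input is untouched.
    """
    sites = sites.reindex(features.columns)
    unknown = sorted(set(sites.dropna().astype(int)) - set(SITES))
    if unknown or sites.isna().any():
        raise ConfigurationError(f"unknown or missing site labels: {unknown}")
    scale = sites.astype(int).map(config.site_scale).to_numpy(float)
    shift = sites.astype(int).map(config.site_shift).to_numpy(float)
    return features * scale + shift


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]]]:
    """Generate the full cohort: records plus per-subject (SC, FC) pairs.

    Deterministic given ``config.seed``.  Behavior scores are driven by each
    subject's measured whole-DMN coupling so that the configured
    brain-behavior slopes refer to the quantity the analysis later measures.
    """
    from scfc.coupling import sc_fc_coupling
    from scfc.subnetworks import canonical_subnetworks

    rng = np.random.default_rng(config.seed)
    labels = _default_labels(config.n_nodes)
    subnets = canonical_subnetworks(node_labels=labels)
    dmn = subnets["DMN"] if config.n_nodes == 90 else subnets["whole_brain"]

    records: list[SubjectRecord] = []
    matrices: dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]] = {}
    counter = 0
    for group in GROUPS:
        m = config.n_per_group[group]
        group_ids: list[str] = []
        couplings = np.empty(m)
        for k in range(m):
            counter += 1
            sid = f"sub-{counter:04d}"
            sc = generate_sc_matrix(config, rng, group)
            fc = generate_fc_matrix(
                sc, config.coupling_alpha[group], config.t_points, rng
            )
            matrices[sid] = (sc, fc)
            res = sc_fc_coupling(sc, fc, dmn, sid)
            couplings[k] = res.rho if res.defined else 0.0
            group_ids.append(sid)
        hyper, inatt = generate_behavior(couplings, group, config, rng)
        sites = np.where(rng.random(m) < config.site_prob, SITES[1], SITES[0])
        ages = rng.uniform(*config.age_range, m)
        sexes = np.where(rng.random(m) < config.sex_prob[group], "male", "female")
        for k, sid in enumerate(group_ids):
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    site=int(sites[k]),
                    age=float(np.round(ages[k], 1)),
                    sex=str(sexes[k]),
                    swan_hyper=float(np.round(hyper[k], 4)),
                    swan_inatt=float(np.round(inatt[k], 4)),
                )
            )
    return records, matrices


def records_to_manifest(records: list[SubjectRecord]) -> pd.DataFrame:
    """Subject records as the manifest DataFrame (indexed by subject id)."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df.set_index("subject_id")
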