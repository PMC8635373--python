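"""Feature extraction: the features x subjects table.

For every subject and every subnetwork (DMN, ECN, SAN, whole_brain) three
features are computed: global efficiency of the thresholded structural
graph, global efficiency of the FDR-thresholded functional graph, and the
SC-FC coupling.  Rows are named ``<metric>__<subnetwork>`` (e.g.
``Eglob_SC__DMN``), columns are subject ids.

The table travels as CSV with a ``#``-prefixed metadata header block
recording the thresholding parameters.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from scfc.matrices import ConnectivityMatrix
from scfc.graph import threshold_structural, threshold_functional, extract_subnetwork, global_efficiency
from scfc.coupling import sc_fc_coupling
from scfc.subnetworks import SubnetworkDefinition

logger = logging.getLogger(__name__)

METRICS = ("Eglob_SC", "Eglob_FC", "coupling")


def feature_rows(subnets: dict[str, SubnetworkDefinition]) -> list[str]:
    return [f"{m}__{s}" for m in METRICS for s in subnets]


def subject_features(
    sc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    subnets: dict[str, SubnetworkDefinition],
    t_points: int,
    q: float = 0.05,
    zero_mode: str = "exclude",
    subject_id: str = "",
) -> dict[str, float]:
    """All 3 x n_subnetworks features for a single subject."""
    sc_graph = threshold_structural(sc)
    fc_graph = threshold_functional(fc, t_points=t_points, q=q)
    out: dict[str, float] = {}
    for name, subnet in subnets.items():
        out[f"Eglob_SC__{name}"] = global_efficiency(extract_subnetwork(sc_graph, subnet))
        out[f"Eglob_FC__{name}"] = global_efficiency(extract_subnetwork(fc_graph, subnet))
        res = sc_fc_coupling(sc, fc, subnet, subject_id, zero_mode)
        out[f"coupling__{name}"] = res.rho if res.defined else np.nan
    return out


def build_feature_table(
    matrices: dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]],
    subnets: dict[str, SubnetworkDefinition],
    t_points: int,
    q: float = 0.05,
    zero_mode: str = "exclude",
) -> pd.DataFrame:
    """Features x subjects table for a cohort.

    ``matrices`` maps subject id to its ``(sc, fc)`` pair.  Deterministic;
    logs progress every 50 subjects.
    """
    columns: dict[str, dict[str, float]] = {}
    for i, (sid, (sc, fc)) in enumerate(matrices.items()):
        columns[sid] = subject_features(
            sc, fc, subnets, t_points=t_points, q=q, zero_mode=zero_mode, subject_id=sid
        )
        if (i + 1) % 50 == 0:
            logger.info("feature extraction: %d/%d subjects", i + 1, len(matrices))
    table = pd.DataFrame(columns).reindex(feature_rows(subnets))
    table.index.name = "feature"
    return table


def write_feature_table(
    table: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """Write the table as CSV preceded by ``# key: value`` metadata lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh)


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a feature CSV, returning the table and its metadata block."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, index_col=0)
    return table, meta
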