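"""Connectivity matrix container and plain-text I/O.

Matrices are square, symmetric, zero-diagonal.  Structural connectivity (SC)
holds non-negative streamline counts from probabilistic tractography;
functional connectivity (FC) holds Fisher-z transformed correlations between
regional resting-state time series.  On disk a matrix is tab-delimited text
(one row per node, no header) with node labels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SYMMETRY_TOL = 1e-10


class DataError(ValueError):
    """Raised when an input matrix violates the container invariants."""


@dataclass
class ConnectivityMatrix:
    """A symmetric N x N connectivity matrix with ordered node labels.

    Parameters
    ----------
    values
        Square array.  SC: fiber counts >= 0; FC: Fisher-z values.
    node_labels
        Region names, one per row/column (AAL-90 convention for real data).
    modality
        ``"SC"`` or ``"FC"``.
    """

    values: np.ndarray
    node_labels: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DataError(f"matrix must be square, got shape {self.values.shape}")
        n = self.values.shape[0]
        if len(self.node_labels) != n:
            raise DataError(
                f"{len(self.node_labels)} node labels for a {n}x{n} matrix"
            )
        if self.modality not in ("SC", "FC"):
            raise DataError(f"modality must be 'SC' or 'FC', got {self.modality!r}")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            # raw probabilistic tractography is asymmetric; a region pair has a
            # single undirected count, so average then round half-up for SC
            self.values = 0.5 * (self.values + self.values.T)
            if self.modality == "SC":
                self.values = np.floor(self.values + 0.5)
        np.fill_diagonal(self.values, 0.0)
        if self.modality == "SC" and np.any(self.values < 0):
            raise DataError("SC matrix contains negative fiber counts")
        if not np.all(np.isfinite(self.values)):
            raise DataError("matrix contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle values in row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    """Write a matrix as tab-delimited text plus a ``.labels.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, mat.values, fmt="%.10g", delimiter="\t")
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    sidecar.write_text(
        json.dumps({"node_labels": mat.node_labels, "modality": mat.modality})
    )


def read_matrix(
    path: str | Path,
    modality: str | None = None,
    node_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Read a tab-delimited matrix, taking labels/modality from the sidecar.

    Explicit ``modality`` / ``node_labels`` arguments override the sidecar;
    if neither is available, labels default to ``n001..nNNN``.
    """
    path = Path(path)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        node_labels = node_labels or meta.get("node_labels")
        modality = modality or meta.get("modality")
    if node_labels is None:
        node_labels = [f"n{i + 1:03d}" for i in range(values.shape[0])]
    if modality is None:
        raise DataError(f"modality for {path} not given and no sidecar found")
    return ConnectivityMatrix(values=values, node_labels=node_labels, modality=modality)
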