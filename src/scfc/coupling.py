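"""Per-subject SC-FC coupling.

Coupling is the Spearman rank correlation between log-transformed fiber
counts and the corresponding Fisher-z functional connectivity values over
the strict upper triangle of a subnetwork, one value per subject and
subnetwork.  High coupling means the functional organization closely adheres
to the anatomical backbone.

Zero-fiber pairs have no defined log and are excluded by default
(``zero_mode="exclude"``); ``zero_mode="log1p"`` instead keeps every pair and
correlates log(1 + SC) with FC.  Because Spearman is invariant to strictly
monotone transforms, feeding FC as Fisher-z values rather than raw
correlations cannot change the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from scfc.matrices import ConnectivityMatrix
from scfc.graph import extract_subnetwork
from scfc.subnetworks import SubnetworkDefinition

MIN_EDGES = 3


@dataclass
class CouplingResult:
    """Spearman SC-FC coupling for one subject and subnetwork.

    ``rho`` is ``None`` when fewer than 3 usable edge pairs remain; an
    undefined coupling propagates as missing, never silently as zero.
    """

    subject_id: str
    subnetwork: str
    rho: float | None
    n_edges: int

    @property
    def defined(self) -> bool:
        return self.rho is not None


def sc_fc_coupling(
    sc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    subnet: SubnetworkDefinition,
    subject_id: str = "",
    zero_mode: str = "exclude",
) -> CouplingResult:
    """Spearman correlation of log fiber counts vs FC within a subnetwork.

    Both matrices are restricted to the subnetwork, vectorized over the
    strict upper triangle, and rank-correlated with average ranks for ties.
    """
    if sc.node_labels != fc.node_labels:
        raise ValueError("SC and FC node labels differ")
    if zero_mode not in ("exclude", "log1p"):
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    sc_sub = extract_subnetwork(sc, subnet)
    fc_sub = extract_subnetwork(fc, subnet)
    x = sc_sub.upper_triangle()
    y = fc_sub.upper_triangle()
    if zero_mode == "exclude":
        keep = x > 0
        x, y = np.log(x[keep]), y[keep]
    else:
        x = np.log1p(x)
    n_edges = int(x.size)
    if n_edges < MIN_EDGES or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CouplingResult(subject_id, subnet.name, None, n_edges)
    rho = stats.spearmanr(x, y).statistic
    return CouplingResult(subject_id, subnet.name, float(rho), n_edges)


def coupling_profile(
    matrices: dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]],
    subnets: dict[str, SubnetworkDefinition],
    zero_mode: str = "exclude",
) -> list[CouplingResult]:
    """One :class:`CouplingResult` per subject x subnetwork.

    ``matrices`` maps subject id to its ``(sc, fc)`` pair; order of results
    follows the mapping's iteration order, subnetworks in definition order.
    """
    out: list[CouplingResult] = []
    for sid, (sc, fc) in matrices.items():
        for subnet in subnets.values():
            out.append(sc_fc_coupling(sc, fc, subnet, sid, zero_mode))
    return out
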