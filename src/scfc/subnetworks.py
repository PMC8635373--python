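"""Canonical intrinsic-network node sets on the AAL-90 parcellation.

The default mode (DMN), executive control (ECN) and salience (SAN) networks
are each defined as a fixed set of 12 AAL regions (6 bilateral pairs):

* DMN — superior frontal gyrus (medial), middle temporal gyrus, superior
  frontal gyrus (dorsolateral), anterior cingulate cortex, precuneus,
  angular gyrus.
* ECN — superior frontal gyrus (dorsolateral), middle frontal gyrus,
  inferior frontal gyrus (triangular part), inferior parietal gyrus,
  caudate, inferior temporal gyrus.
* SAN — middle cingulate cortex, supplementary motor area, inferior frontal
  gyrus (pars orbitalis), superior frontal gyrus (medial), insula, caudate.

The shipped region-name mapping follows standard AAL-90 naming and can be
overridden by a user-supplied JSON file of the same shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

_RESOURCE = "subnetworks.json"


class UnknownRegionError(KeyError):
    """A subnetwork region name that does not resolve to any node label."""


@dataclass(frozen=True)
class SubnetworkDefinition:
    """A named subset of network nodes (e.g. the 12-region DMN)."""

    name: str
    regions: tuple[str, ...]

    def indices(self, node_labels: list[str]) -> list[int]:
        """Positions of this subnetwork's regions within ``node_labels``."""
        lookup = {lab: i for i, lab in enumerate(node_labels)}
        missing = [r for r in self.regions if r not in lookup]
        if missing:
            raise UnknownRegionError(
                f"subnetwork {self.name!r}: unknown region(s) {missing}"
            )
        return [lookup[r] for r in self.regions]


def _load_resource(path: str | Path | None = None) -> dict:
    if path is not None:
        return json.loads(Path(path).read_text())
    with resources.files("scfc.resources").joinpath(_RESOURCE).open() as fh:
        return json.load(fh)


def aal90_labels(path: str | Path | None = None) -> list[str]:
    """The 90 AAL region labels in canonical (L/R interleaved) order."""
    return list(_load_resource(path)["aal90_labels"])


def canonical_subnetworks(
    path: str | Path | None = None,
    node_labels: list[str] | None = None,
) -> dict[str, SubnetworkDefinition]:
    """DMN/ECN/SAN plus ``whole_brain`` over all labels.

    ``whole_brain`` spans ``node_labels`` if given, else the full AAL-90 list.
    """
    data = _load_resource(path)
    labels = node_labels if node_labels is not None else data["aal90_labels"]
    defs = {
        name: SubnetworkDefinition(name=name, regions=tuple(regions))
        for name, regions in data["subnetworks"].items()
    }
    defs["whole_brain"] = SubnetworkDefinition(
        name="whole_brain", regions=tuple(labels)
    )
    return defs
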