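"""Resting-state network definitions.

A :class:`NetworkDefinition` maps each of the seven canonical resting-state
networks (motor MTN, default-mode DMN, salience SAN, striatum STM, temporal
TEP, hippocampus HIP, dorsal-attention DAN) to an explicit, ordered list of
bilateral region labels.  The striatum network is special: it must contain
exactly six regions (left/right caudate nucleus, putamen, globus pallidus),
because the within-striatum analysis enumerates its 15 region pairs and the
cross-network pain index averages its six couplings to the other networks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

NETWORK_NAMES = ("MTN", "DMN", "SAN", "STM", "TEP", "HIP", "DAN")

#: Number of regions the striatum network must contain.
STM_SIZE = 6


class NetworkTableError(ValueError):
    """Raised when a network-membership table violates its invariants."""


@dataclass(frozen=True)
class NetworkDefinition:
    """Ordered mapping of the seven resting-state networks to region labels.

    Parameters
    ----------
    members
        Mapping from network name to its ordered region-label list.  Keys
        must be exactly the seven canonical names; networks must be pairwise
        disjoint and non-empty, and STM must have exactly six regions.
    """

    members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in NETWORK_NAMES if n not in self.members]
        extra = [n for n in self.members if n not in NETWORK_NAMES]
        if missing or extra:
            raise NetworkTableError(
                f"network table must define exactly {NETWORK_NAMES}; "
                f"missing={missing}, unexpected={extra}"
            )
        seen: dict[str, str] = {}
        for net in NETWORK_NAMES:
            regions = self.members[net]
            if not regions:
                raise NetworkTableError(f"network {net!r} is empty")
            for r in regions:
                if r in seen:
                    raise NetworkTableError(
                        f"region {r!r} appears in both {seen[r]!r} and {net!r}"
                    )
                seen[r] = net
        if len(self.members["STM"]) != STM_SIZE:
            raise NetworkTableError(
                f"STM must contain exactly {STM_SIZE} regions, "
                f"got {len(self.members['STM'])}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return NETWORK_NAMES

    def __getitem__(self, network: str) -> list[str]:
        return list(self.members[network])

    @property
    def all_regions(self) -> list[str]:
        """All region labels in network order (concatenated)."""
        out: list[str] = []
        for net in NETWORK_NAMES:
            out.extend(self.members[net])
        return out

    def network_of(self, region: str) -> str:
        for net in NETWORK_NAMES:
            if region in self.members[net]:
                return net
        raise KeyError(region)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {n: self.members[n] for n in NETWORK_NAMES}, fh, sort_keys=False
            )


def load_network_table(path=None) -> NetworkDefinition:
    """Load a network-membership table from YAML.

    With no argument, loads the packaged seven-network table (84 bilateral
    regions).  Validation errors name the offending region and networks.
    """
    if path is None:
        ref = importlib.resources.files("crossnet.data") / "networks.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise NetworkTableError("network table must be a mapping of name -> regions")
    members = {str(k): [str(r) for r in (v or [])] for k, v in raw.items()}
    return NetworkDefinition(members)
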