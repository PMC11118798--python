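"""Directed network models with latent inputs.

A network is a set of named anatomical regions, directed inter-region
connections, and latent (intrinsic) inputs that enter the network from
outside.  The packaged default describes a brainstem / cervical spinal cord
pain-regulation circuit with 10 regions, 32 inter-region connections, and
3 latent inputs (35 directed links in total).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "RegionSpec",
    "Connection",
    "LatentInput",
    "NetworkModel",
    "NetworkStructureError",
    "load_network",
    "save_network",
    "default_network",
    "default_network_path",
    "connection_count",
    "adjacency_mask",
]

DEFAULT_NETWORK_RESOURCE = "fm_brainstem_cord.yaml"


class NetworkStructureError(ValueError):
    """Raised when a network specification is structurally invalid."""


@dataclass(frozen=True)
class RegionSpec:
    """One anatomical region of the network."""

    name: str
    abbrev: str
    n_subregions: int = 5

    def __post_init__(self) -> None:
        if self.n_subregions < 1:
            raise NetworkStructureError(
                f"region {self.abbrev!r}: n_subregions must be >= 1"
            )


@dataclass(frozen=True)
class Connection:
    """A directed inter-region connection ``source -> target``."""

    source: str
    target: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise NetworkStructureError(
                f"self-loop {self.source!r} -> {self.target!r} is not permitted"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class LatentInput:
    """An unobserved input entering the network from outside.

    ``targets`` is the ordered tuple of region abbreviations the latent
    drives; each (latent, target) pair counts as one directed link.
    """

    name: str
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.targets:
            raise NetworkStructureError(f"latent {self.name!r} has no targets")


@dataclass
class NetworkModel:
    """Regions, directed connections, and latent inputs."""

    regions: list[RegionSpec] = field(default_factory=list)
    connections: list[Connection] = field(default_factory=list)
    latents: list[LatentInput] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def region_abbrevs(self) -> list[str]:
        return [r.abbrev for r in self.regions]

    def region(self, abbrev: str) -> RegionSpec:
        for r in self.regions:
            if r.abbrev == abbrev:
                return r
        raise KeyError(abbrev)

    def sources_of(self, abbrev: str) -> list[str]:
        """Regions with a connection into ``abbrev`` (declaration order)."""
        return [c.source for c in self.connections if c.target == abbrev]

    def targets_of(self, abbrev: str) -> list[str]:
        return [c.target for c in self.connections if c.source == abbrev]

    def latents_of(self, abbrev: str) -> list[str]:
        """Names of latent inputs driving region ``abbrev``."""
        return [l.name for l in self.latents if abbrev in l.targets]

    def has_connection(self, source: str, target: str) -> bool:
        return any(c.key == (source, target) for c in self.connections)

    def validate(self) -> None:
        """Raise :class:`NetworkStructureError` on any structural issue."""
        abbrevs = self.region_abbrevs
        dup = {a for a in abbrevs if abbrevs.count(a) > 1}
        if dup:
            raise NetworkStructureError(f"duplicate region abbreviations: {sorted(dup)}")
        known = set(abbrevs)
        seen: set[tuple[str, str]] = set()
        for c in self.connections:
            for end in (c.source, c.target):
                if end not in known:
                    raise NetworkStructureError(
                        f"connection {c.source}->{c.target} references unknown region {end!r}"
                    )
            if c.key in seen:
                raise NetworkStructureError(
                    f"duplicate connection {c.source}->{c.target}"
                )
            seen.add(c.key)
        lat_names = [l.name for l in self.latents]
        if len(lat_names) != len(set(lat_names)):
            raise NetworkStructureError("duplicate latent input names")
        for l in self.latents:
            for t in l.targets:
                if t not in known:
                    raise NetworkStructureError(
                        f"latent {l.name!r} targets unknown region {t!r}"
                    )

    # -- db keys -----------------------------------------------------------
    def connection_keys(self, include_latent: bool = True) -> list[tuple[str, str]]:
        """Ordered (source, target) keys; latent links appended last."""
        keys = [c.key for c in self.connections]
        if include_latent:
            for l in self.latents:
                keys.extend((l.name, t) for t in l.targets)
        return keys


# -- operations ------------------------------------------------------------

def _as_mapping(doc: object, what: str) -> dict:
    if not isinstance(doc, dict):
        raise NetworkStructureError(f"{what}: expected a mapping")
    return doc


def network_from_dict(doc: dict) -> NetworkModel:
    regions = [
        RegionSpec(
            name=str(r["name"]),
            abbrev=str(r["abbrev"]),
            n_subregions=int(r.get("n_subregions", 5)),
        )
        for r in doc.get("regions", [])
    ]
    connections = [
        Connection(source=str(c["source"]), target=str(c["target"]))
        for c in doc.get("connections", [])
    ]
    latents = [
        LatentInput(name=str(l["name"]), targets=tuple(l["targets"]))
        for l in doc.get("latents", [])
    ]
    return NetworkModel(regions=regions, connections=connections, latents=latents)


def network_to_dict(net: NetworkModel) -> dict:
    return {
        "regions": [
            {"name": r.name, "abbrev": r.abbrev, "n_subregions": r.n_subregions}
            for r in net.regions
        ],
        "connections": [{"source": c.source, "target": c.target} for c in net.connections],
        "latents": [{"name": l.name, "targets": list(l.targets)} for l in net.latents],
    }


def load_network(path: str | Path) -> NetworkModel:
    """Read a network specification (YAML or JSON) and validate it."""
    text = Path(path).read_text(encoding="utf-8")
    doc = _as_mapping(yaml.safe_load(text), str(path))
    return network_from_dict(doc)


def save_network(net: NetworkModel, path: str | Path) -> Path:
    """Write ``net`` as YAML; round-trips through :func:`load_network`."""
    path = Path(path)
    path.write_text(
        yaml.safe_dump(network_to_dict(net), sort_keys=False), encoding="utf-8"
    )
    return path


def default_network_path() -> Path:
    """Path of the packaged default network specification."""
    return Path(resources.files("sapm") / "networks" / DEFAULT_NETWORK_RESOURCE)


def default_network() -> NetworkModel:
    """The packaged brainstem/cord network (10 regions, 32 + 3 links)."""
    return load_network(default_network_path())


def connection_count(net: NetworkModel, include_latent: bool = True) -> int:
    """Number of directed links; latent links counted one per (latent, target)."""
    n = len(net.connections)
    if include_latent:
        n += sum(len(l.targets) for l in net.latents)
    return n


def adjacency_mask(net: NetworkModel) -> tuple[np.ndarray, list[str], list[str]]:
    """Binary matrix over (regions + latents) x regions.

    Returns ``(mask, row_labels, col_labels)`` where ``mask[i, j] == 1`` iff
    the directed link ``row_labels[i] -> col_labels[j]`` exists.  Rows are
    regions in declaration order followed by latents in declaration order;
    columns are regions in declaration order.
    """
    cols = net.region_abbrevs
    rows = cols + [l.name for l in net.latents]
    mask = np.zeros((len(rows), len(cols)), dtype=int)
    col_ix = {a: j for j, a in enumerate(cols)}
    row_ix = {a: i for i, a in enumerate(rows)}
    for c in net.connections:
        mask[row_ix[c.source], col_ix[c.target]] = 1
    for l in net.latents:
        for t in l.targets:
            mask[row_ix[l.name], col_ix[t]] = 1
    return mask, rows, cols


def edge_list(net: NetworkModel, include_latent: bool = True) -> list[str]:
    """Plain ``source->target`` strings, deterministic order."""
    return [f"{s}->{t}" for s, t in net.connection_keys(include_latent)]
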