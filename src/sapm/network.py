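"""Network model definition, validation, serialization, and weighting matrices.

A network model is an ordered set of named regions, an ordered set of
directed inter-region connections, and one or more latent inputs — driving
signals entering the network from outside (peripheral stimulation,
cognitive/emotional influences, autonomic afferents).  "Variable" latents
have freely estimated time courses; a "fixed" latent has a prescribed
temporal template (typically the stimulation paradigm convolved with the
canonical HRF) and only its amplitude is fitted.

The model is encoded in two weighting matrices over ``N = n_regions +
n_latents`` nodes (regions first, latents appended; row = receiving node,
column = sending node):

* ``M_input`` (n_regions x N) holds the non-negative D values weighting
  each incoming signal as it sums into a region's total input.
* ``M_output`` (N x N) holds the signed DB values describing how each
  input drives a region's output — positive entries are excitatory,
  negative inhibitory.  Its lower-right n_latents x n_latents block is the
  identity, which guarantees one unit eigenvalue per latent input and so
  makes latent propagation through the network well defined.

B values, the per-connection input-to-output conversion factors ("apparent
transmission effect"), are recovered as DB / D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .paradigm import Paradigm, make_paradigm_regressor

__all__ = [
    "Connection",
    "LatentInput",
    "NetworkModel",
    "ConnectionMatrices",
    "validate_network",
    "build_matrices",
    "default_pain_network",
    "connection_key",
]

VARIABLE = "variable"
FIXED = "fixed"


def connection_key(source: str, target: str) -> str:
    """Canonical string form of a directed connection, ``source->target``."""
    return f"{source}->{target}"


def _as_pair(key) -> tuple[str, str]:
    if isinstance(key, str):
        if "->" not in key:
            raise ValueError(f"connection key {key!r} is not of the form 'source->target'")
        src, tgt = key.split("->", 1)
        return src.strip(), tgt.strip()
    src, tgt = key
    return str(src), str(tgt)


@dataclass(frozen=True)
class Connection:
    source: str
    target: str
    reconstructed: bool = False
    note: str = ""

    @property
    def key(self) -> str:
        return connection_key(self.source, self.target)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class LatentInput:
    """Declaration of one latent (external) input to a region."""

    name: str
    kind: str  # "variable" | "fixed"
    target_region: str
    template: np.ndarray | None = None

    def __post_init__(self):
        if self.template is not None:
            object.__setattr__(self, "template", np.asarray(self.template, dtype=float))

    @property
    def is_fixed(self) -> bool:
        return self.kind == FIXED


@dataclass
class NetworkModel:
    """Regions, directed connections, and latent inputs of one network."""

    regions: list[str]
    connections: list[Connection]
    latents: list[LatentInput]
    name: str = "network"

    # -- basic accessors ---------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_latents(self) -> int:
        return len(self.latents)

    @property
    def n_nodes(self) -> int:
        return self.n_regions + self.n_latents

    def region_index(self, name: str) -> int:
        return self.regions.index(name)

    def connection_pairs(self) -> list[tuple[str, str]]:
        return [c.pair for c in self.connections]

    def connection_keys(self) -> list[str]:
        return [c.key for c in self.connections]

    def adjacency(self) -> np.ndarray:
        """Boolean region-block adjacency, entry (i, j) True iff j -> i."""
        adj = np.zeros((self.n_regions, self.n_regions), dtype=bool)
        for c in self.connections:
            adj[self.region_index(c.target), self.region_index(c.source)] = True
        return adj

    def variable_latents(self) -> list[LatentInput]:
        return [l for l in self.latents if not l.is_fixed]

    def fixed_latents(self) -> list[LatentInput]:
        return [l for l in self.latents if l.is_fixed]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "regions": list(self.regions),
            "connections": [
                {
                    "from": c.source,
                    "to": c.target,
                    **({"reconstructed": True} if c.reconstructed else {}),
                    **({"note": c.note} if c.note else {}),
                }
                for c in self.connections
            ],
            "latents": [
                {
                    "name": l.name,
                    "kind": l.kind,
                    "target": l.target_region,
                    **(
                        {"template": [float(v) for v in l.template]}
                        if l.template is not None
                        else {}
                    ),
                }
                for l in self.latents
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkModel":
        try:
            regions = [str(r) for r in d["regions"]]
            connections = [
                Connection(
                    source=str(c["from"]),
                    target=str(c["to"]),
                    reconstructed=bool(c.get("reconstructed", False)),
                    note=str(c.get("note", "")),
                )
                for c in d["connections"]
            ]
            latents = [
                LatentInput(
                    name=str(l["name"]),
                    kind=str(l["kind"]),
                    target_region=str(l["target"]),
                    template=np.asarray(l["template"], dtype=float)
                    if "template" in l and l["template"] is not None
                    else None,
                )
                for l in d["latents"]
            ]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"unparseable network config: missing or malformed field ({exc})") from exc
        return cls(regions=regions, connections=connections, latents=latents, name=str(d.get("name", "network")))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)


@dataclass
class ConnectionMatrices:
    """The M_input (D-valued) and M_output (DB-valued) weighting matrices."""

    m_input: np.ndarray  # (n_regions, N)
    m_output: np.ndarray  # (N, N)
    regions: list[str]
    latent_names: list[str]
    model: NetworkModel = field(repr=False, default=None)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_latents(self) -> int:
        return len(self.latent_names)

    @property
    def n_nodes(self) -> int:
        return self.n_regions + self.n_latents

    def region_block(self) -> np.ndarray:
        """The region-to-region (DB) block of M_output."""
        nr = self.n_regions
        return self.m_output[:nr, :nr]


def validate_network(model: NetworkModel) -> list[str]:
    """Return a description of every invariant violation (empty when valid)."""
    problems: list[str] = []
    seen = set()
    for r in model.regions:
        if r in seen:
            problems.append(f"duplicate region name {r!r}")
        seen.add(r)
    if not model.regions:
        problems.append("model declares no regions")

    region_set = set(model.regions)
    conn_seen = set()
    for c in model.connections:
        if c.source not in region_set:
            problems.append(f"connection {c.key}: unknown source region {c.source!r}")
        if c.target not in region_set:
            problems.append(f"connection {c.key}: unknown target region {c.target!r}")
        if c.source == c.target:
            problems.append(f"connection {c.key}: self-loop (source equals target)")
        if c.pair in conn_seen:
            problems.append(f"duplicate directed connection {c.key}")
        conn_seen.add(c.pair)

    if not model.latents:
        problems.append("model declares no latent inputs (at least one is required)")
    lat_seen = set()
    for l in model.latents:
        if l.name in lat_seen:
            problems.append(f"duplicate latent name {l.name!r}")
        lat_seen.add(l.name)
        if l.kind not in (VARIABLE, FIXED):
            problems.append(f"latent {l.name!r}: kind must be 'variable' or 'fixed', got {l.kind!r}")
        if l.target_region not in region_set:
            problems.append(f"latent {l.name!r}: unknown target region {l.target_region!r}")
        if l.kind == VARIABLE and l.template is not None:
            problems.append(f"latent {l.name!r}: variable latents must not declare a template")
        if l.kind == FIXED:
            if l.template is None:
                problems.append(f"latent {l.name!r}: fixed latents require a temporal template")
            else:
                t = np.asarray(l.template, dtype=float)
                if t.ndim != 1 or t.size < 2:
                    problems.append(f"latent {l.name!r}: template must be a 1-D series of length >= 2")
                elif not np.all(np.isfinite(t)):
                    problems.append(f"latent {l.name!r}: template contains non-finite values")
                elif np.ptp(t) == 0:
                    problems.append(f"latent {l.name!r}: template is constant")
    return problems


def _values_by_connection(model: NetworkModel, values: Mapping, what: str) -> np.ndarray:
    lookup = {}
    for key, v in values.items():
        lookup[_as_pair(key)] = float(v)
    out = np.empty(len(model.connections))
    for i, c in enumerate(model.connections):
        if c.pair not in lookup:
            raise ValueError(f"missing {what} value for connection {c.key}")
        out[i] = lookup[c.pair]
    return out


def build_matrices(
    model: NetworkModel,
    d_values: Mapping,
    db_values: Mapping,
    latent_weights: Mapping | None = None,
) -> ConnectionMatrices:
    """Assemble M_input and M_output from per-connection D and DB values.

    ``d_values`` and ``db_values`` are keyed by (source, target) pairs or
    ``"source->target"`` strings and must cover every declared connection;
    D values must be strictly positive.  ``latent_weights`` (per latent
    name, default 1.0) set the latent columns of both matrices; by default
    a latent feeds its target region with unit weight and its scale lives
    in the latent time course.
    """
    problems = validate_network(model)
    if problems:
        raise ValueError("invalid network model: " + "; ".join(problems))

    d = _values_by_connection(model, d_values, "D")
    db = _values_by_connection(model, db_values, "DB")
    bad = np.nonzero(d <= 0)[0]
    if bad.size:
        names = ", ".join(model.connections[i].key for i in bad)
        raise ValueError(f"D values must be positive; offending connection(s): {names}")

    nr, nl = model.n_regions, model.n_latents
    n = nr + nl
    m_in = np.zeros((nr, n))
    m_out = np.zeros((n, n))
    for i, c in enumerate(model.connections):
        ti = model.region_index(c.target)
        si = model.region_index(c.source)
        m_in[ti, si] = d[i]
        m_out[ti, si] = db[i]
    weights = dict(latent_weights or {})
    for k, l in enumerate(model.latents):
        w = float(weights.get(l.name, 1.0))
        ti = model.region_index(l.target_region)
        m_in[ti, nr + k] = w
        m_out[ti, nr + k] = w
        m_out[nr + k, nr + k] = 1.0
    return ConnectionMatrices(
        m_input=m_in,
        m_output=m_out,
        regions=list(model.regions),
        latent_names=[l.name for l in model.latents],
        model=model,
    )


# ---------------------------------------------------------------------------
# Default pain-processing network
# ---------------------------------------------------------------------------

_PAIN_REGIONS = [
    "C6RD",
    "DRt",
    "Hypothalamus",
    "LC",
    "NGc",
    "NRM",
    "NTS",
    "PAG",
    "PBN",
    "Thalamus",
]

# Connections supported directly by the nociceptive-processing literature and
# two-source SEM evidence (descending PAG->NRM->cord pathway, spinoreticular
# loops through DRt/NGc/NRM, LC projections, and the NTS/PBN/hypothalamus
# autonomic-affective axis).
_PAIN_EDGES_LITERATURE: list[tuple[str, str]] = [
    ("Thalamus", "PAG"),
    ("PAG", "NRM"),
    ("NRM", "C6RD"),
    ("NGc", "C6RD"),
    ("C6RD", "NRM"),
    ("C6RD", "NGc"),
    ("LC", "Thalamus"),
    ("LC", "PBN"),
    ("NTS", "PBN"),
    ("PBN", "NTS"),
    ("NTS", "Hypothalamus"),
    ("Hypothalamus", "PBN"),
    ("PBN", "Hypothalamus"),
    ("NRM", "NGc"),
    ("NGc", "NRM"),
    ("NTS", "PAG"),
    ("DRt", "C6RD"),
    ("C6RD", "DRt"),
]

# Reconstructed edges: reciprocal pairs among the NTS / PBN / hypothalamus /
# PAG / LC / DRt group, whose dense interconnection (including apparent
# DRt relationships mediated through the dorsal horn) completes the
# 32-connection network.  Flagged so analyses can distinguish them from the
# directly documented edges; the network is fully user-overridable.
_PAIN_EDGES_RECONSTRUCTED: list[tuple[str, str]] = [
    ("Hypothalamus", "NTS"),
    ("PAG", "NTS"),
    ("PAG", "PBN"),
    ("PBN", "PAG"),
    ("PAG", "Hypothalamus"),
    ("Hypothalamus", "PAG"),
    ("NTS", "DRt"),
    ("DRt", "NTS"),
    ("PAG", "DRt"),
    ("DRt", "PAG"),
    ("PBN", "LC"),
    ("NTS", "LC"),
    ("LC", "NTS"),
    ("LC", "PAG"),
]


def default_pain_network(paradigm: Paradigm | None = None) -> NetworkModel:
    """The packaged brainstem/spinal-cord nociceptive network.

    Ten regions spanning the C6 dorsal cord, medulla, pons, midbrain and
    medial thalamus; 32 directed inter-region connections; and three latent
    inputs: freely varying drives into the LC (cognitive/emotional,
    noradrenergic) and NTS (autonomic/vagal afferent), plus a fixed
    stimulus-locked drive into the C6 right dorsal horn whose template is
    the stimulation paradigm convolved with the canonical HRF (only its
    amplitude is fitted).
    """
    p = paradigm or Paradigm()
    template = make_paradigm_regressor(p)
    connections = [Connection(s, t) for s, t in _PAIN_EDGES_LITERATURE] + [
        Connection(s, t, reconstructed=True) for s, t in _PAIN_EDGES_RECONSTRUCTED
    ]
    latents = [
        LatentInput(name="int0", kind=FIXED, target_region="C6RD", template=template),
        LatentInput(name="int1", kind=VARIABLE, target_region="LC"),
        LatentInput(name="int2", kind=VARIABLE, target_region="NTS"),
    ]
    return NetworkModel(
        regions=list(_PAIN_REGIONS),
        connections=connections,
        latents=latents,
        name="pain10",
    )


def network_hash(model: NetworkModel) -> str:
    """Stable digest of the model topology (regions, edges, latents)."""
    import hashlib

    payload = json.dumps(
        {
            "regions": model.regions,
            "connections": model.connection_keys(),
            "latents": [(l.name, l.kind, l.target_region) for l in model.latents],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def replace_connections(model: NetworkModel, connections: Iterable[Connection]) -> NetworkModel:
    return replace(model, connections=list(connections))
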