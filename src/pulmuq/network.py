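"""Proximal pulmonary vascular network: geometry, topology and material laws.

The proximal domain is a strictly bifurcating network of large pulmonary
arteries (one inlet, the main pulmonary artery) and the first generations of
pulmonary veins (four outlets draining into the left atrium).  Terminal
arteries are paired one-to-one with terminal veins; each pair anchors a
two-sided structured-tree microvascular bed.

Axial convention: for every segment x in [0, L] increases in the direction of
mean flow -- root to periphery for arteries, periphery to left atrium for
veins.  The parent/daughter columns of the network table encode structural
adjacency, not flow direction; on the venous side the structural parent is
downstream of its daughters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "NetworkValidationError",
    "CycleError",
    "DaughterCountError",
    "GeometryError",
    "PairingError",
    "VesselSegment",
    "MaterialParameters",
    "ProximalNetwork",
    "load_network",
    "write_network",
    "default_network",
]

MMHG = 1333.22  # dyn/cm^2 per mmHg

# stiffness prior-box midpoints (dyn/cm^2); bounds live in pulmuq.pce
K_A_DEFAULT = 0.5 * (5.60e5 + 1.04e6)
K_V_DEFAULT = 0.5 * (5.95e5 + 1.11e6)


class NetworkValidationError(ValueError):
    """Base class for network validation failures; names the offending segment."""


class CycleError(NetworkValidationError):
    pass


class DaughterCountError(NetworkValidationError):
    pass


class GeometryError(NetworkValidationError):
    pass


class PairingError(NetworkValidationError):
    pass


@dataclass(frozen=True)
class VesselSegment:
    """One proximal vessel: reference geometry plus structural adjacency."""

    name: str
    length: float  # cm
    radius: float  # cm, reference radius r0
    side: str  # "arterial" | "venous"
    parent: str | None = None
    daughters: tuple[str, str] | tuple[()] = ()
    terminal_partner: str | None = None

    @property
    def is_terminal(self) -> bool:
        return len(self.daughters) == 0


@dataclass(frozen=True)
class MaterialParameters:
    """Wall stiffness and blood properties (CGS units).

    K_A / K_V are the proximal arterial/venous wall stiffness Eh/r0 in
    dyn/cm^2; rho (g/cm^3) and nu (cm^2/s) are blood density and kinematic
    viscosity; gamma is the power-law velocity-profile exponent (gamma = 9
    gives a blunt profile with no-slip at the wall).
    """

    K_A: float = K_A_DEFAULT
    K_V: float = K_V_DEFAULT
    rho: float = 1.055
    nu: float = 3.03e-2
    mu: float = 0.032
    gamma: float = 9.0

    def __post_init__(self) -> None:
        for name in ("K_A", "K_V", "rho", "nu", "mu", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MaterialParameters.{name} must be positive")
        if abs(self.mu - self.rho * self.nu) > 0.01 * self.mu:
            raise ValueError(
                f"mu={self.mu} inconsistent with rho*nu={self.rho * self.nu:.5g} (>1%)"
            )

    def stiffness(self, side: str) -> float:
        return self.K_A if side == "arterial" else self.K_V


@dataclass
class ProximalNetwork:
    """Validated proximal network with lookup helpers."""

    segments: dict[str, VesselSegment]
    inlet: str
    venous_outlets: tuple[str, ...]
    materials: MaterialParameters = field(default_factory=MaterialParameters)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ----------------------------------------------------------
    def __getitem__(self, name: str) -> VesselSegment:
        return self.segments[name]

    def __iter__(self):
        return iter(self.segments.values())

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def arteries(self) -> list[VesselSegment]:
        return [s for s in self if s.side == "arterial"]

    @property
    def veins(self) -> list[VesselSegment]:
        return [s for s in self if s.side == "venous"]

    @property
    def terminal_pairs(self) -> list[tuple[str, str]]:
        """(terminal artery, partner vein) pairs anchoring the beds."""
        return [
            (s.name, s.terminal_partner)
            for s in self.arteries
            if s.terminal_partner is not None
        ]

    def junctions(self) -> list[tuple[str, str, str]]:
        """(structural parent, daughter1, daughter2) triples."""
        return [(s.name, *s.daughters) for s in self if len(s.daughters) == 2]

    def with_materials(self, materials: MaterialParameters) -> "ProximalNetwork":
        return ProximalNetwork(
            dict(self.segments), self.inlet, self.venous_outlets, materials
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        segs = self.segments
        for s in segs.values():
            if s.length <= 0 or s.radius <= 0:
                raise GeometryError(f"segment '{s.name}': nonpositive length/radius")
            if len(s.daughters) not in (0, 2):
                raise DaughterCountError(
                    f"segment '{s.name}': daughter count {len(s.daughters)} not in {{0, 2}}"
                )
            if s.side not in ("arterial", "venous"):
                raise NetworkValidationError(f"segment '{s.name}': bad side '{s.side}'")
            for d in s.daughters:
                if d not in segs:
                    raise NetworkValidationError(
                        f"segment '{s.name}': unknown daughter '{d}'"
                    )
                if segs[d].parent != s.name:
                    raise NetworkValidationError(
                        f"segment '{d}': parent does not list it as a daughter"
                    )
            if s.parent is not None:
                if s.parent not in segs:
                    raise NetworkValidationError(
                        f"segment '{s.name}': unknown parent '{s.parent}'"
                    )
                if s.name not in segs[s.parent].daughters:
                    raise NetworkValidationError(
                        f"segment '{s.name}': parent '{s.parent}' does not list it"
                    )
            if s.terminal_partner is not None:
                if s.terminal_partner not in segs:
                    raise PairingError(
                        f"segment '{s.name}': dangling pair reference "
                        f"'{s.terminal_partner}'"
                    )
                partner = segs[s.terminal_partner]
                if partner.terminal_partner != s.name:
                    raise PairingError(
                        f"segment '{s.name}': pairing with '{partner.name}' is not mutual"
                    )
                if partner.side == s.side:
                    raise PairingError(
                        f"segment '{s.name}': paired with same-side '{partner.name}'"
                    )

        # cycle check via parent links
        for s in segs.values():
            seen = set()
            cur: str | None = s.name
            while cur is not None:
                if cur in seen:
                    raise CycleError(f"cycle in parent links at segment '{cur}'")
                seen.add(cur)
                cur = segs[cur].parent

        if self.inlet not in segs:
            raise NetworkValidationError(f"inlet '{self.inlet}' not in network")
        if segs[self.inlet].parent is not None:
            raise NetworkValidationError(f"inlet '{self.inlet}' has a parent")
        for v in self.venous_outlets:
            if v not in segs or segs[v].side != "venous":
                raise NetworkValidationError(f"venous outlet '{v}' invalid")

        # pairing must be a bijection between terminal arteries and venous leaves
        term_art = {s.name for s in self.arteries if s.is_terminal}
        paired_art = {a for a, _ in self.terminal_pairs}
        if term_art != paired_art:
            missing = sorted(term_art ^ paired_art)
            raise PairingError(
                f"terminal arteries without a venous partner (or vice versa): {missing}"
            )


def _none_if_blank(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    v = str(v).strip()
    return v or None


def load_network(
    table: pd.DataFrame | str | Path,
    materials: MaterialParameters | None = None,
    inlet: str = "MPA",
    venous_outlets: tuple[str, ...] = ("LIV", "LSV", "RIV", "RSV"),
) -> ProximalNetwork:
    """Build and validate a :class:`ProximalNetwork` from a vessel table.

    ``table`` is a DataFrame or CSV path with columns
    ``name,length_cm,radius_cm,side,parent,daughter1,daughter2,terminal_partner``
    (empty string for none).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, dtype=str, keep_default_na=False)
    segments: dict[str, VesselSegment] = {}
    for _, row in table.iterrows():
        d1 = _none_if_blank(row.get("daughter1"))
        d2 = _none_if_blank(row.get("daughter2"))
        if (d1 is None) != (d2 is None):
            raise DaughterCountError(
                f"segment '{row['name']}': daughter count 1 not in {{0, 2}}"
            )
        seg = VesselSegment(
            name=str(row["name"]).strip(),
            length=float(row["length_cm"]),
            radius=float(row["radius_cm"]),
            side=str(row["side"]).strip(),
            parent=_none_if_blank(row.get("parent")),
            daughters=(d1, d2) if d1 is not None else (),
            terminal_partner=_none_if_blank(row.get("terminal_partner")),
        )
        if seg.name in segments:
            raise NetworkValidationError(f"duplicate segment name '{seg.name}'")
        segments[seg.name] = seg
    return ProximalNetwork(
        segments,
        inlet=inlet,
        venous_outlets=venous_outlets,
        materials=materials or MaterialParameters(),
    )


def write_network(network: ProximalNetwork, path: str | Path | None = None) -> pd.DataFrame:
    """Serialize a network back to the tabular form accepted by load_network."""
    rows = []
    for s in network:
        d = list(s.daughters) + ["", ""]
        rows.append(
            {
                "name": s.name,
                "length_cm": f"{s.length:.2f}",
                "radius_cm": f"{s.radius:.3f}",
                "side": s.side,
                "parent": s.parent or "",
                "daughter1": d[0],
                "daughter2": d[1],
                "terminal_partner": s.terminal_partner or "",
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def default_network(materials: MaterialParameters | None = None) -> ProximalNetwork:
    """The 15-artery / 12-vein reference network with default materials."""
    with resources.as_file(
        resources.files("pulmuq.data").joinpath("network_default.csv")
    ) as p:
        net = load_network(p, materials=materials)
    n_art, n_ven = len(net.arteries), len(net.veins)
    if n_art != 15 or n_ven != 12 or len(net.terminal_pairs) != 8:
        raise NetworkValidationError(
            f"default network malformed: {n_art} arteries, {n_ven} veins, "
            f"{len(net.terminal_pairs)} terminal pairs"
        )
    return net
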