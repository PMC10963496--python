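"""Arterial-network domain: vessels, tree topology, and mean-flow distribution.

The computational domain is a bifurcating tree of straight, impermeable,
tapered cylindrical segments. Each vessel stores its reference (diastolic)
geometry as inlet/outlet radii with a linear taper in between; the main
pulmonary artery (MPA) is the single root, the left and right pulmonary
arteries (LPA/RPA) are its daughters, and everything distal is "intralobar".

Mean flow is pushed down the tree by treating each vessel as a Poiseuille
resistor: at a junction the parent's mean flow splits in proportion to the
daughters' conductances F = pi*r0^4 / (8*mu*L).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Vessel",
    "ArterialNetwork",
    "TimeSeries",
    "NetworkError",
    "TopologyError",
    "read_network",
    "write_network",
    "poiseuille_conductance",
    "distribute_mean_flow",
]

#: default blood density, g/mL
RHO_DEFAULT = 1.03
#: default blood dynamic viscosity, Poise
MU_DEFAULT = 0.03
#: default power-law velocity-profile exponent
GAMMA_DEFAULT = 5.0

ROLES = ("MPA", "LPA", "RPA", "intralobar")


class NetworkError(ValueError):
    """Malformed network description."""


class TopologyError(NetworkError):
    """Connectivity that is not a binary tree with a single root."""


@dataclass
class Vessel:
    """One straight arterial segment with a linearly tapered reference radius.

    Lengths and radii in cm; stiffness K = Eh/r0 in mmHg (optional here,
    usually assigned network-wide from the MPA estimate).
    """

    id: str
    name: str = ""
    role: str = "intralobar"
    length: float = 1.0
    inlet_radius: float = 0.5
    outlet_radius: float = 0.5
    stiffness: float | None = None
    parent: str | None = None
    children: tuple[str, ...] = field(default_factory=tuple)
    windkessel: dict | None = None  # {"Rp","Rd","C"} in mmHg*s/mL, mL/mmHg

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NetworkError(f"vessel {self.id!r}: length must be > 0")
        if self.inlet_radius <= 0 or self.outlet_radius <= 0:
            raise NetworkError(f"vessel {self.id!r}: radii must be > 0")
        if self.role not in ROLES:
            raise NetworkError(
                f"vessel {self.id!r}: role {self.role!r} not in {ROLES}"
            )
        if len(self.children) not in (0, 2):
            raise TopologyError(
                f"vessel {self.id!r}: {len(self.children)} children "
                "(a vessel must have exactly 0 or 2)"
            )
        self.children = tuple(self.children)

    def r0(self, x: np.ndarray | float) -> np.ndarray | float:
        """Reference radius at axial position x in [0, L] (linear taper)."""
        s = np.asarray(x, dtype=float) / self.length
        return self.inlet_radius + (self.outlet_radius - self.inlet_radius) * s

    def area_dia(self, x: np.ndarray | float) -> np.ndarray | float:
        """Reference (diastolic) cross-sectional area pi*r0(x)^2, cm^2."""
        r = self.r0(x)
        return math.pi * np.asarray(r) ** 2

    @property
    def mean_radius(self) -> float:
        """Length-averaged reference radius (exact for a linear taper)."""
        return 0.5 * (self.inlet_radius + self.outlet_radius)


@dataclass
class TimeSeries:
    """Samples of one quantity over exactly one cardiac cycle of period T."""

    times: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size < 16:
            raise ValueError("need at least 16 samples per period")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.period <= 0:
            raise ValueError("period must be > 0")

    @property
    def mean(self) -> float:
        """Cycle average computed with the trapezoidal rule over [0, T].

        The waveform is treated as periodic: if the samples do not reach T,
        the first sample is reused at t = T.
        """
        t, v = self.times, self.values
        if t[-1] < self.period:
            t = np.append(t, self.period)
            v = np.append(v, v[0])
        return float(np.trapezoid(v, t) / self.period)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Periodic linear interpolation at arbitrary times."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        tp, vp = self.times, self.values
        if tp[-1] < self.period:
            tp = np.append(tp, self.period)
            vp = np.append(vp, vp[0])
        return np.interp(tt, tp, vp)


@dataclass
class ArterialNetwork:
    """Bifurcating arterial tree plus the blood properties of the model."""

    vessels: dict[str, Vessel]
    rho: float = RHO_DEFAULT
    mu: float = MU_DEFAULT
    gamma: float = GAMMA_DEFAULT

    def __post_init__(self) -> None:
        self._validate()

    # -- topology ---------------------------------------------------------
    def _validate(self) -> None:
        if not self.vessels:
            raise NetworkError("network has no vessels")
        roots = [v for v in self.vessels.values() if v.parent is None]
        if len(roots) != 1:
            raise TopologyError(
                f"expected exactly one root (MPA), found {len(roots)}"
            )
        for v in self.vessels.values():
            for c in v.children:
                if c not in self.vessels:
                    raise NetworkError(
                        f"vessel {v.id!r} references unknown child {c!r}"
                    )
                if self.vessels[c].parent != v.id:
                    raise TopologyError(
                        f"child {c!r} does not point back to parent {v.id!r}"
                    )
            if v.parent is not None and v.parent not in self.vessels:
                raise NetworkError(
                    f"vessel {v.id!r} references unknown parent {v.parent!r}"
                )
        # reachability from the root == no cycles, single component
        seen: set[str] = set()
        stack = [roots[0].id]
        while stack:
            vid = stack.pop()
            if vid in seen:
                raise TopologyError(f"cycle detected at vessel {vid!r}")
            seen.add(vid)
            stack.extend(self.vessels[vid].children)
        if seen != set(self.vessels):
            orphans = sorted(set(self.vessels) - seen)
            raise TopologyError(f"vessels unreachable from the root: {orphans}")

    @property
    def root(self) -> Vessel:
        return next(v for v in self.vessels.values() if v.parent is None)

    @property
    def terminals(self) -> list[str]:
        """Leaf-vessel ids in a stable (sorted by id) order."""
        return sorted(v.id for v in self.vessels.values() if not v.children)

    @property
    def junctions(self) -> list[tuple[str, str, str]]:
        """(parent, daughter1, daughter2) triples, sorted by parent id."""
        return sorted(
            (v.id, *v.children) for v in self.vessels.values() if v.children
        )

    def downstream_terminals(self, vid: str) -> list[str]:
        """Terminal ids in the subtree rooted at vessel ``vid``."""
        out, stack = [], [vid]
        while stack:
            v = self.vessels[stack.pop()]
            if v.children:
                stack.extend(v.children)
            else:
                out.append(v.id)
        return sorted(out)

    def scale_areas(self, factor: float, roles: tuple[str, ...]) -> None:
        """Rescale reference radii of vessels with the given roles in place.

        Hook for matching extralobar reference areas to diastolic
        phase-contrast areas: an area factor f multiplies radii by sqrt(f).
        """
        if factor <= 0:
            raise NetworkError("area scale factor must be > 0")
        rs = math.sqrt(factor)
        for v in self.vessels.values():
            if v.role in roles:
                v.inlet_radius *= rs
                v.outlet_radius *= rs


# -- conductance and mean-flow distribution -------------------------------

def poiseuille_conductance(vessel: Vessel, mu: float = MU_DEFAULT) -> float:
    """Poiseuille conductance F = pi*r0^4 / (8*mu*L) of one vessel, CGS.

    Uses the length-averaged reference radius, treating the whole (possibly
    tapered) vessel as a single straight resistor. Units are
    cm^3/s per dyne/cm^2; only ratios of F enter the flow split, so the
    unit system cancels there.
    """
    r = vessel.mean_radius
    return math.pi * r**4 / (8.0 * mu * vessel.length)


def distribute_mean_flow(
    net: ArterialNetwork, q_root_mean: float
) -> dict[str, float]:
    """Split a mean root flow (mL/s) down the tree by daughter conductance.

    At every junction Q_d = F_d/(F_d1+F_d2) * Q_parent, so flow is conserved
    exactly at each level and the terminal flows sum to ``q_root_mean``.
    """
    if q_root_mean <= 0:
        raise ValueError("q_root_mean must be > 0")
    flows: dict[str, float] = {net.root.id: float(q_root_mean)}
    stack = [net.root.id]
    while stack:
        vid = stack.pop()
        v = net.vessels[vid]
        if not v.children:
            continue
        d1, d2 = v.children
        f1 = poiseuille_conductance(net.vessels[d1], net.mu)
        f2 = poiseuille_conductance(net.vessels[d2], net.mu)
        qp = flows[vid]
        flows[d1] = qp * f1 / (f1 + f2)
        flows[d2] = qp * f2 / (f1 + f2)
        stack.extend(v.children)
    return flows


# -- serialization --------------------------------------------------------

def _vessel_to_record(v: Vessel) -> dict:
    rec: dict = {
        "id": v.id,
        "name": v.name,
        "role": v.role,
        "length_cm": v.length,
        "inlet_radius_cm": v.inlet_radius,
        "outlet_radius_cm": v.outlet_radius,
        "parent": v.parent,
        "children": list(v.children),
    }
    if v.stiffness is not None:
        rec["stiffness_mmHg"] = v.stiffness
    if v.windkessel is not None:
        rec["windkessel"] = dict(v.windkessel)
    return rec


def _vessel_from_record(rec: dict) -> Vessel:
    try:
        return Vessel(
            id=str(rec["id"]),
            name=str(rec.get("name", "")),
            role=str(rec.get("role", "intralobar")),
            length=float(rec["length_cm"]),
            inlet_radius=float(rec["inlet_radius_cm"]),
            outlet_radius=float(rec["outlet_radius_cm"]),
            stiffness=(
                float(rec["stiffness_mmHg"])
                if "stiffness_mmHg" in rec
                else None
            ),
            parent=rec.get("parent"),
            children=tuple(rec.get("children", ())),
            windkessel=rec.get("windkessel"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkError(
            f"malformed vessel record {rec.get('id', '<no id>')!r}: {exc}"
        ) from exc


def read_network(path) -> ArterialNetwork:
    """Read a JSON network file and return a validated ArterialNetwork."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkError(f"cannot parse {path}: {exc}") from exc
    vessels = {}
    for rec in doc.get("vessels", []):
        v = _vessel_from_record(rec)
        if v.id in vessels:
            raise NetworkError(f"duplicate vessel id {v.id!r}")
        vessels[v.id] = v
    return ArterialNetwork(
        vessels=vessels,
        rho=float(doc.get("rho_g_per_ml", RHO_DEFAULT)),
        mu=float(doc.get("mu_poise", MU_DEFAULT)),
        gamma=float(doc.get("gamma", GAMMA_DEFAULT)),
    )


def write_network(net: ArterialNetwork, path) -> None:
    """Write the network as JSON; round-trips all numeric fields exactly."""
    doc = {
        "rho_g_per_ml": net.rho,
        "mu_poise": net.mu,
        "gamma": net.gamma,
        "vessels": [
            _vessel_to_record(net.vessels[k]) for k in sorted(net.vessels)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_timeseries(path, period: float | None = None) -> TimeSeries:
    """Read a waveform CSV with header ``time_s,value``.

    If ``period`` is not given, the sample spacing is assumed uniform and
    the period is taken as t[-1] + dt (samples cover [0, T))."""
    arr = np.genfromtxt(path, delimiter=",", names=True)
    t = np.atleast_1d(arr["time_s"]).astype(float)
    v = np.atleast_1d(arr["value"]).astype(float)
    if period is None:
        dt = t[-1] - t[-2] if t.size > 1 else 1.0
        period = float(t[-1] + dt)
        if t[0] != 0.0:
            warnings.warn("waveform does not start at t=0; period inferred")
    return TimeSeries(times=t, values=v, period=period)


def write_timeseries(ts: TimeSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(ts.times, ts.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
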