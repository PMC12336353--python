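"""Group-contribution estimation of pseudo-critical properties for DESs.

A deep eutectic solvent (an HBA:HBD mixture at molar ratio a:b) is treated as
a *pseudo-pure component*: its functional-group counts, atom count and
molecular weight are mole-fraction-weighted blends of the two components'
values, with x_HBA = a/(a+b).  Joback–Reid-type increments (including
Valderrama-style ion groups such as a quaternary nitrogen and halide anions)
then give

    T_b = 198 + sum_k N_k tb_k                                   [K]
    T_c = T_b / (0.584 + 0.965 S - S^2),   S = sum_k N_k tc_k    [K]
    P_c = (0.113 + 0.0032 N_atoms - sum_k N_k pc_k)^-2           [bar]
    V_c = 17.5 + sum_k N_k vc_k                                  [cm^3/mol]

and the acentric factor follows from T_b, T_c and P_c through a base-10
logarithmic closed form referenced to atmospheric pressure P_b.

Group decomposition is user input (no SMILES parsing); fractional counts are
legal because blending produces them.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import DataFormatError, UnknownGroupError, ValidityRangeError

#: Standard atmosphere, the default reference pressure in the acentric-factor
#: closed form, bar.
P_ATM_BAR = 1.01325

_TABLE_COLUMNS = ("group_id", "tb_k", "tc_k", "pc_k", "vc_k", "n_atoms")


@dataclass(frozen=True)
class GroupParams:
    """Increments contributed by one occurrence of a functional group.

    ``tb_k`` is in K, ``tc_k`` dimensionless, ``pc_k`` on the bar^(-1/2)
    scale of the critical-pressure bracket, ``vc_k`` in cm^3/mol and
    ``n_atoms`` counts the atoms (including hydrogens) the group brings.
    """

    group_id: str
    tb_k: float
    tc_k: float
    pc_k: float
    vc_k: float
    n_atoms: int

    def __post_init__(self) -> None:
        for name in ("tb_k", "tc_k", "pc_k", "vc_k"):
            if not math.isfinite(getattr(self, name)):
                raise DataFormatError(f"group {self.group_id!r}: {name} is not finite")
        if self.vc_k <= 0:
            raise DataFormatError(f"group {self.group_id!r}: vc_k must be positive")
        if self.n_atoms < 0:
            raise DataFormatError(f"group {self.group_id!r}: n_atoms must be >= 0")


class GroupTable(Mapping):
    """Lookup table of :class:`GroupParams`, keyed by group token.

    Ring variants carry a ``_ring`` suffix (``CH2_ring``); ion groups a
    trailing charge sign (``N+``, ``Cl-``).
    """

    def __init__(self, params: Iterable[GroupParams]):
        self._params: dict[str, GroupParams] = {}
        for p in params:
            if p.group_id in self._params:
                raise DataFormatError(f"duplicate group_id {p.group_id!r}")
            self._params[p.group_id] = p

    def __getitem__(self, group_id: str) -> GroupParams:
        try:
            return self._params[group_id]
        except KeyError:
            raise UnknownGroupError(f"unknown group {group_id!r}") from None

    def __iter__(self):
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupTable":
        df = pd.read_csv(path)
        missing = set(_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise DataFormatError(
                f"group table {path}: missing column(s) {sorted(missing)}"
            )
        return cls(
            GroupParams(
                group_id=str(r.group_id),
                tb_k=float(r.tb_k),
                tc_k=float(r.tc_k),
                pc_k=float(r.pc_k),
                vc_k=float(r.vc_k),
                n_atoms=int(r.n_atoms),
            )
            for r in df.itertuples(index=False)
        )

    @classmethod
    def builtin(cls) -> "GroupTable":
        """The bundled, checksum-pinned group-increment table."""
        from .data import load_fixture

        return load_fixture("table1")


def load_group_table(source: str | Path = "builtin") -> GroupTable:
    """Load a group-parameter table from CSV, or the built-in one."""
    if source == "builtin":
        return GroupTable.builtin()
    return GroupTable.from_csv(source)


@dataclass(frozen=True)
class GroupCounts:
    """Multiset of group occurrences; fractional counts are allowed."""

    counts: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for g, n in self.counts.items():
            if n < 0:
                raise ValidityRangeError(f"negative count for group {g!r}")

    def items(self):
        return self.counts.items()


@dataclass(frozen=True)
class Component:
    """A pure HBA or HBD: its group decomposition, formula weight and size."""

    name: str
    counts: Mapping[str, float]
    mw: float
    n_atoms: float

    def __post_init__(self) -> None:
        if not self.counts or not any(n > 0 for n in self.counts.values()):
            raise ValidityRangeError(f"component {self.name!r} has no groups")
        if self.mw <= 0:
            raise ValidityRangeError(f"component {self.name!r}: mw must be positive")

    @classmethod
    def from_spec(cls, spec: Mapping) -> "Component":
        try:
            return cls(
                name=str(spec.get("name", "")),
                counts={str(k): float(v) for k, v in spec["groups"].items()},
                mw=float(spec["mw"]),
                n_atoms=float(spec["n_atoms"]),
            )
        except KeyError as exc:
            raise DataFormatError(f"component spec missing field {exc}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Component":
        with open(path) as fh:
            return cls.from_spec(yaml.safe_load(fh))


@dataclass(frozen=True)
class PseudoComponent:
    """Mole-fraction-blended representation of an HBA:HBD mixture."""

    counts: GroupCounts
    n_atoms: float
    mw: float
    label: str = ""
    hba_fraction: float = 1.0


@dataclass(frozen=True)
class CriticalProps:
    """Pseudo-critical properties of a DES (Table-2-style record)."""

    tb: float  # K
    tc: float  # K
    pc: float  # bar
    vc: float  # cm^3/mol
    omega: float
    mw: float  # g/mol

    def to_dict(self) -> dict[str, float]:
        return {
            "tb_K": self.tb,
            "tc_K": self.tc,
            "pc_bar": self.pc,
            "vc_cm3mol": self.vc,
            "omega": self.omega,
            "mw_gmol": self.mw,
        }

    def to_frame(self, label: str = "") -> pd.DataFrame:
        """One-row frame in the column order of the reference DES table."""
        return pd.DataFrame(
            [
                {
                    "des_id": label,
                    "tc_K": self.tc,
                    "pc_bar": self.pc,
                    "vc_cm3mol": self.vc,
                    "omega": self.omega,
                    "mw_gmol": self.mw,
                    "tb_K": self.tb,
                }
            ]
        )


def parse_ratio(ratio: str) -> tuple[float, float]:
    """Parse a molar-ratio string like ``"1:2"`` into (a, b)."""
    parts = [p.strip() for p in str(ratio).split(":")]
    if len(parts) != 2:
        raise DataFormatError(
            f"ratio {ratio!r}: expected binary 'a:b' (ternary mixtures are not "
            "supported by the pseudo-component blend)"
        )
    a, b = (float(p) for p in parts)
    return a, b


def _counts_of(obj) -> Mapping[str, float]:
    if isinstance(obj, PseudoComponent):
        return obj.counts.counts
    if isinstance(obj, (GroupCounts, Component)):
        return obj.counts if isinstance(obj.counts, Mapping) else obj.counts.counts
    if isinstance(obj, Mapping):
        return obj
    raise TypeError(f"cannot extract group counts from {type(obj).__name__}")


def mix_components(
    hba: Component,
    hbd: Component,
    ratio_hba: float,
    ratio_hbd: float,
) -> PseudoComponent:
    """Blend two components into a pseudo-pure component.

    Group counts, atom count and molecular weight are all blended linearly
    with x_HBA = ratio_hba / (ratio_hba + ratio_hbd); the blend is
    order-independent and invariant to rescaling both ratios.
    """
    if ratio_hba <= 0 or ratio_hbd <= 0:
        raise ValidityRangeError(
            f"molar ratios must be positive, got {ratio_hba}:{ratio_hbd}"
        )
    x = ratio_hba / (ratio_hba + ratio_hbd)
    groups = set(_counts_of(hba)) | set(_counts_of(hbd))
    blended = {
        g: x * _counts_of(hba).get(g, 0.0) + (1 - x) * _counts_of(hbd).get(g, 0.0)
        for g in sorted(groups)
    }
    label = f"{hba.name}:{hbd.name} {ratio_hba:g}:{ratio_hbd:g}"
    return PseudoComponent(
        counts=GroupCounts(blended, provenance=label),
        n_atoms=x * hba.n_atoms + (1 - x) * hbd.n_atoms,
        mw=x * hba.mw + (1 - x) * hbd.mw,
        label=label,
        hba_fraction=x,
    )


def _group_sum(counts: Mapping[str, float], table: GroupTable, attr: str) -> float:
    missing = [g for g in counts if g not in table]
    if missing:
        raise UnknownGroupError(f"unknown group(s) {missing} in decomposition")
    return sum(n * getattr(table[g], attr) for g, n in counts.items())


def boiling_temperature(pc_comp, table: GroupTable) -> float:
    """Normal boiling temperature, K: 198 plus the tb increments."""
    return 198.0 + _group_sum(_counts_of(pc_comp), table, "tb_k")


def critical_temperature(tb: float, pc_comp, table: GroupTable) -> float:
    """Critical temperature, K, from T_b and the tc increment sum."""
    if tb <= 0:
        raise ValidityRangeError(f"tb must be positive, got {tb}")
    s = _group_sum(_counts_of(pc_comp), table, "tc_k")
    denom = 0.584 + 0.965 * s - s * s
    if denom <= 0:
        raise ValidityRangeError(
            f"GC T_c out of validity range (denominator {denom:.4g} <= 0 at "
            f"increment sum {s:.4g})"
        )
    return tb / denom


def critical_pressure(pc_comp, table: GroupTable) -> float:
    """Critical pressure, bar; uses the (possibly fractional) blended atom count."""
    counts = _counts_of(pc_comp)
    n_atoms = (
        pc_comp.n_atoms
        if hasattr(pc_comp, "n_atoms")
        else _group_sum(counts, table, "n_atoms")
    )
    bracket = 0.113 + 0.0032 * n_atoms - _group_sum(counts, table, "pc_k")
    if bracket <= 0:
        raise ValidityRangeError(
            f"GC P_c out of validity range (bracket {bracket:.4g} <= 0)"
        )
    return bracket**-2


def critical_volume(pc_comp, table: GroupTable) -> float:
    """Critical volume, cm^3/mol: 17.5 plus the vc increments."""
    return 17.5 + _group_sum(_counts_of(pc_comp), table, "vc_k")


def acentric_factor(tb: float, tc: float, pc: float, pb: float = P_ATM_BAR) -> float:
    """Acentric factor from T_b, T_c and P_c (base-10 logarithm).

    With L = log10(pc/pb):

        omega = (tb-43)(tc-43) / [(tc-tb)(0.7 tc-43)] * L
                - (tc-43)/(tc-tb) * L + L - 1

    so pc == pb forces omega = -1 exactly.
    """
    if pc <= 0 or pb <= 0:
        raise ValidityRangeError("pc and pb must be positive")
    if tc == tb:
        raise ValidityRangeError("degenerate factor: tc == tb")
    if 0.7 * tc == 43.0:
        raise ValidityRangeError("degenerate factor: 0.7*tc == 43")
    log_ratio = math.log10(pc / pb)
    a = (tb - 43.0) * (tc - 43.0) / ((tc - tb) * (0.7 * tc - 43.0))
    b = (tc - 43.0) / (tc - tb)
    return a * log_ratio - b * log_ratio + log_ratio - 1.0


def estimate_des(
    hba: Component,
    hbd: Component,
    ratio_hba: float,
    ratio_hbd: float,
    table: GroupTable | None = None,
    pb: float = P_ATM_BAR,
) -> CriticalProps:
    """Full chain: blend, then T_b, T_c, P_c, V_c and omega. Deterministic."""
    if table is None:
        table = GroupTable.builtin()
    pseudo = mix_components(hba, hbd, ratio_hba, ratio_hbd)
    tb = boiling_temperature(pseudo, table)
    tc = critical_temperature(tb, pseudo, table)
    pc = critical_pressure(pseudo, table)
    vc = critical_volume(pseudo, table)
    omega = acentric_factor(tb, tc, pc, pb)
    return CriticalProps(tb=tb, tc=tc, pc=pc, vc=vc, omega=omega, mw=pseudo.mw)


def estimate_des_from_spec(
    spec: Mapping,
    table: GroupTable | None = None,
    pb: float = P_ATM_BAR,
) -> CriticalProps:
    """Estimate from a DES spec mapping {hba, hbd, ratio}.

    ``hba``/``hbd`` may be inline component mappings or names of bundled
    components (see :func:`dessound.data.load_components`).
    """
    from .data import load_components

    def resolve(entry) -> Component:
        if isinstance(entry, str):
            components = load_components()
            if entry not in components:
                raise DataFormatError(
                    f"unknown bundled component {entry!r}; available: "
                    f"{sorted(components)}"
                )
            return components[entry]
        return Component.from_spec(entry)

    try:
        hba = resolve(spec["hba"])
        hbd = resolve(spec["hbd"])
        a, b = parse_ratio(spec["ratio"])
    except KeyError as exc:
        raise DataFormatError(f"DES spec missing field {exc}") from None
    return estimate_des(hba, hbd, a, b, table=table, pb=pb)
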