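"""Bundled reference tables, dataset IO and the synthetic databank generator.

The real speed-of-sound databank (415 literature points over 38 DESs) is not
redistributable, so this module ships (a) checksum-pinned transcriptions of
the published group-increment table, the 38-DES pseudo-critical-property
table and the 16-neuron weight table, and (b) a seeded generator that
emulates the databank's envelope: descriptors drawn uniformly inside the
published min-max boxes, a smooth teacher mapping monotonically decreasing
in temperature, and Gaussian measurement noise (default sd 1.0 m/s, the
stated standard uncertainty of the experimental sound speeds).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError, FixtureIntegrityError, ValidityRangeError
from .groups import Component, GroupTable
from .network import FEATURE_COLUMNS, ScalerParams, SoundSpeedModel, TARGET_COLUMN

DATASET_COLUMNS = ("des_id", "T_K", "Tc_K", "Vc_cm3mol", "omega", "MW_gmol", "u_ms")

#: Min-max envelope of the published modelling databank (u in m/s, Tc in K,
#: Vc in cm^3/mol, omega dimensionless, MW in g/mol).
ENVELOPE = {
    "u_ms": (1166.0, 2138.0),
    "Tc_K": (602.0, 778.21),
    "Vc_cm3mol": (146.46, 656.4),
    "omega": (0.5139, 1.3146),
    "MW_gmol": (59.39, 190.61),
}

_FIXTURES = {
    "table1": (
        "table1_groups.csv",
        "ed4d1f0f5fbb21e54bfac283f846852a24b64e663cf7a51e57d8c5fc131f5638",
    ),
    "table2": (
        "table2_des.csv",
        "6aea1446b2997a00041269933c823b7e9bffa851ce65c69f0547b2c40112958c",
    ),
    "table4": (
        "table4_weights.csv",
        "c674ed6ef8f419272000539f04b7322d520add7f925e2472cb4294527e5f7a7d",
    ),
    "components": (
        "components.yaml",
        "8f5d9b4c617842ceb38a29d8fb4f4e39dd292cabb21855658514441894942c05",
    ),
}


@dataclass(frozen=True)
class DESRecord:
    """One row of the published 38-DES property table.

    ``mw`` is derived (mole-fraction blend of standard formula weights; the
    source table prints no MW column) and carried for provenance only.
    """

    des_id: str
    hba: str
    hbd: str
    ratio: str
    tc: float
    pc: float
    vc: float
    omega: float
    mw: float
    ref: str


def _fixture_bytes(name: str) -> bytes:
    try:
        fname, digest = _FIXTURES[name]
    except KeyError:
        raise DataFormatError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    raw = resources.files("dessound").joinpath("resources", fname).read_bytes()
    actual = hashlib.sha256(raw).hexdigest()
    if actual != digest:
        raise FixtureIntegrityError(
            f"fixture {fname} checksum mismatch (expected {digest[:12]}..., "
            f"got {actual[:12]}...); the bundled table has been edited"
        )
    return raw


def load_fixture(name: str):
    """Load a bundled, checksum-pinned reference table.

    ``table1`` -> :class:`~dessound.groups.GroupTable`;
    ``table2`` -> tuple of 38 :class:`DESRecord`;
    ``table4`` -> dict with the (16, 4) hidden weights (input order
    V_c, omega, MW, T), the 16 output weights, labels and the raw frame.
    """
    import io

    raw = _fixture_bytes(name)
    if name == "table1":
        return GroupTable.from_csv(io.BytesIO(raw))
    if name == "table2":
        df = pd.read_csv(io.BytesIO(raw), dtype={"ref": str})
        records = tuple(
            DESRecord(
                des_id=r.des_id, hba=r.hba, hbd=r.hbd, ratio=r.ratio,
                tc=float(r.tc_K), pc=float(r.pc_bar), vc=float(r.vc_cm3mol),
                omega=float(r.omega), mw=float(r.mw_gmol), ref=str(r.ref),
            )
            for r in df.itertuples(index=False)
        )
        if len(records) != 38:
            raise FixtureIntegrityError(
                f"expected 38 DES records, got {len(records)}"
            )
        return records
    if name == "table4":
        df = pd.read_csv(io.BytesIO(raw))
        w_ih = df[["w_Vc", "w_omega", "w_MW", "w_T"]].to_numpy(dtype=float)
        w_ho = df["w_out"].to_numpy(dtype=float)
        if w_ih.shape != (16, 4):
            raise FixtureIntegrityError(f"expected 16x4 weights, got {w_ih.shape}")
        return {
            "w_ih": w_ih,
            "w_ho": w_ho,
            "input_labels": ("Vc", "omega", "MW", "T"),
            "frame": df,
        }
    if name == "components":
        return yaml.safe_load(io.BytesIO(raw))
    raise AssertionError(name)


def load_components() -> dict[str, Component]:
    """Bundled group decompositions of the fully-covered HBA/HBD components."""
    spec = load_fixture("components")
    return {
        name: Component(
            name=name,
            counts={str(k): float(v) for k, v in entry["groups"].items()},
            mw=float(entry["mw"]),
            n_atoms=float(entry["n_atoms"]),
        )
        for name, entry in spec.items()
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the emulated databank.

    Defaults: 38 DESs on an 11-point temperature grid 293.15-343.15 K
    (step 5 K) gives 418 points, matching the published databank size of 415
    to within one grid row, and noise sd 1.0 m/s matches the stated
    experimental standard uncertainty.
    """

    n_des: int = 38
    t_start: float = 293.15
    t_stop: float = 343.15
    t_step: float = 5.0
    noise_sd: float = 1.0
    seed: int = 42
    teacher: str = "analytic"  # or "network"

    def __post_init__(self) -> None:
        if self.n_des < 2:
            raise ValidityRangeError("need at least 2 DESs")
        if self.noise_sd < 0:
            raise ValidityRangeError("noise sd must be non-negative")
        if self.teacher not in ("analytic", "network"):
            raise ValidityRangeError(f"unknown teacher {self.teacher!r}")
        if self.t_step <= 0 or self.t_stop < self.t_start:
            raise ValidityRangeError("invalid temperature grid")


def make_teacher_network(seed: int, n_hidden: int = 16) -> SoundSpeedModel:
    """A fixed random 4-n_hidden-1 network mapping the envelope boxes to m/s."""
    rng = np.random.default_rng(seed)
    scaler = ScalerParams(
        x_min=np.array([293.15, *(ENVELOPE[c][0] for c in FEATURE_COLUMNS[1:])]),
        x_max=np.array([343.15, *(ENVELOPE[c][1] for c in FEATURE_COLUMNS[1:])]),
        y_min=ENVELOPE["u_ms"][0],
        y_max=ENVELOPE["u_ms"][1],
    )
    return SoundSpeedModel(
        w_ih=rng.uniform(-1.0, 1.0, size=(n_hidden, 4)),
        b_h=rng.uniform(-0.5, 0.5, size=n_hidden),
        w_ho=rng.uniform(-0.8, 0.8, size=n_hidden) / np.sqrt(n_hidden),
        b_o=0.0,
        scaler=scaler,
        metadata={"teacher_seed": seed},
    )


def _analytic_teacher_coefficients(rng: np.random.Generator) -> dict[str, float]:
    # Ranges chosen once so the worst-case term sum stays inside the u envelope.
    return {
        "u0": 1652.0,
        "b": rng.uniform(2.0, 4.0),  # m/s per K, u decreasing in T
        "c": rng.uniform(150.0, 250.0),  # m/s per unit omega
        "d": rng.uniform(100.0, 180.0),  # m/s per ln(Vc)
        "e": rng.uniform(0.8, 1.5),  # m/s per g/mol
    }


def analytic_teacher(T, Vc, omega, MW, coeff) -> np.ndarray:
    """Smooth surrogate u(T, Vc, omega, MW), monotone decreasing in T."""
    return (
        coeff["u0"]
        - coeff["b"] * (np.asarray(T) - 318.15)
        + coeff["c"] * (np.asarray(omega) - 0.9142)
        - coeff["d"] * np.log(np.asarray(Vc) / 401.43)
        + coeff["e"] * (np.asarray(MW) - 125.0)
    )


def generate_synthetic(config: SyntheticConfig = SyntheticConfig()) -> pd.DataFrame:
    """Emulate the modelling databank; fully reproducible per seed.

    Descriptors are drawn uniformly inside the published min-max boxes; u
    comes from the configured teacher plus Gaussian noise.  With the
    analytic teacher the noise-free surface is inside the published u
    envelope by construction; the final (noisy) values are range-checked
    and a warning is raised if any fall outside.
    """
    rng = np.random.default_rng(config.seed)
    temps = np.arange(config.t_start, config.t_stop + 1e-9, config.t_step)
    desc = {
        col: rng.uniform(*ENVELOPE[col], size=config.n_des)
        for col in ("Tc_K", "Vc_cm3mol", "omega", "MW_gmol")
    }
    if config.teacher == "analytic":
        coeff = _analytic_teacher_coefficients(rng)
        teacher = None
    else:
        teacher = make_teacher_network(int(rng.integers(2**31)))
        coeff = None
    rows = []
    for i in range(config.n_des):
        des_id = f"SYN{i + 1:02d}"
        vc, om, mw = (desc[c][i] for c in ("Vc_cm3mol", "omega", "MW_gmol"))
        if config.teacher == "analytic":
            u = analytic_teacher(temps, vc, om, mw, coeff)
        else:
            X = np.column_stack(
                [temps, np.full_like(temps, vc), np.full_like(temps, om),
                 np.full_like(temps, mw)]
            )
            u = teacher.forward(X)
        u = u + rng.normal(0.0, config.noise_sd, size=temps.size)
        for t, ui in zip(temps, u):
            rows.append(
                {
                    "des_id": des_id,
                    "T_K": t,
                    "Tc_K": desc["Tc_K"][i],
                    "Vc_cm3mol": vc,
                    "omega": om,
                    "MW_gmol": mw,
                    "u_ms": ui,
                }
            )
    df = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    lo, hi = ENVELOPE["u_ms"]
    n_outside = int(((df["u_ms"] < lo) | (df["u_ms"] > hi)).sum())
    if n_outside:
        warnings.warn(
            f"{n_outside} generated u values fall outside the published "
            f"envelope [{lo}, {hi}] m/s",
            RuntimeWarning,
            stacklevel=2,
        )
    return df


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset CSV, 12 significant digits (lossless round-trip)."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"dataset missing column(s) {missing}")
    df.loc[:, list(DATASET_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset CSV (columns addressed by name)."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {missing}")
    df = df.loc[:, list(DATASET_COLUMNS)]
    for col in DATASET_COLUMNS[1:]:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            line = int(values.isna().idxmax()) + 2  # header + 1-based
            raise DataFormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = values
    neg = df[TARGET_COLUMN] <= 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise DataFormatError(f"{path}: non-positive u_ms at line {line}")
    t = df["T_K"]
    if ((t < 250) | (t > 400)).any():
        warnings.warn(
            f"{path}: temperatures outside the plausible 250-400 K band",
            RuntimeWarning,
            stacklevel=2,
        )
    return df
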