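"""Intrinsic exchange rates and deuterium-uptake kinetics.

The observed exchange rate of residue i is k_obs = k_int / P_i, where k_int
is the rate the residue would have in an unstructured peptide. Uptake of a
single residue follows pseudo-first-order kinetics,

    d_i(t) = 1 - exp(-(k_int / P_i) * t),

and the fractional uptake of a proteolytic peptide is the mean of d_i over
its exchangeable positions. Because the first two residues of a peptide lose
their deuterium to back-exchange during sample workup, they are excluded
from that mean along with prolines (which have no amide N-H).

Intrinsic rates are predicted from sequence with the standard
reference-parameter method: poly-DL-alanine base rates for acid, base and
water catalysis, nearest-neighbor inductive corrections from a packaged
reference table, and Arrhenius temperature scaling. Units are minutes and
min^-1 throughout. A user-supplied per-residue rate table can bypass the
prediction entirely (see :func:`load_rates_csv`).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .structures import ONE_TO_THREE

logger = logging.getLogger(__name__)

__all__ = [
    "IntrinsicRates",
    "Peptide",
    "UptakeCurve",
    "intrinsic_rates",
    "residue_uptake",
    "exchangeable_positions",
    "peptide_uptake",
    "load_rates_csv",
    "write_rates_csv",
]

# poly-DL-Ala reference rates at 293 K in D2O (log10; acid in 1/(M min),
# base in 1/(M min), water in 1/min) and the D2O ion product
LOG10_KA_REF = 1.62
LOG10_KB_REF = 10.05
LOG10_KW_REF = -1.5
PKD = 15.05
T_REF = 293.0
# Arrhenius activation energies (cal/mol) for the three catalysis channels
EA_ACID = 14000.0
EA_BASE = 17000.0
EA_WATER = 19000.0
R_GAS = 1.987  # cal / (mol K)


@dataclass(frozen=True)
class IntrinsicRates:
    """Per-residue intrinsic exchange rates (min^-1) with their conditions."""

    values: Mapping[int, float]
    pH: float
    temperature: float

    def __post_init__(self) -> None:
        for i, k in self.values.items():
            if not (k > 0 and np.isfinite(k)):
                raise ValueError(f"k_int for residue {i} must be positive and finite")


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide: inclusive residue span in internal numbering."""

    id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"peptide {self.id}: invalid span {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.id}: sequence length does not match span"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class UptakeCurve:
    """Fractional deuterium uptake versus time (minutes)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("uptake values must lie in [0, 1]")


def _load_nn_table() -> dict[str, tuple[float, float, float, float]]:
    table: dict[str, tuple[float, float, float, float]] = {}
    ref = resources.files("pfkit.data") / "intrinsic_rate_params.csv"
    with ref.open() as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")))]
    for row in rows:
        table[row["residue"]] = (
            float(row["acid_lambda"]), float(row["acid_rho"]),
            float(row["base_lambda"]), float(row["base_rho"]),
        )
    return table


_NN_TABLE: Optional[dict[str, tuple[float, float, float, float]]] = None


def _nn_table() -> dict[str, tuple[float, float, float, float]]:
    global _NN_TABLE
    if _NN_TABLE is None:
        _NN_TABLE = _load_nn_table()
    return _NN_TABLE


def intrinsic_rates(sequence: str, pH: float = 7.0,
                    temperature: float = 293.0) -> IntrinsicRates:
    """Predict per-residue intrinsic exchange rates (min^-1) from sequence.

    ``pH`` is read as the pD of the labelling buffer. The N-terminal residue
    and prolines carry no amide N-H and are omitted from the result. The
    amide of residue 2 feels the protonated N-terminus, the last amide the
    C-terminal carboxylate.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must be in [0, 14]")
    if not 250.0 < temperature < 350.0:
        raise ValueError("temperature must be in (250, 350) K")
    table = _nn_table()
    for pos, aa in enumerate(sequence, start=1):
        if aa not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {aa!r} at position {pos}")

    d_conc = 10.0 ** (-pH)
    od_conc = 10.0 ** (pH - PKD)
    # Arrhenius scaling of each catalytic channel from the 293 K reference
    tfac = 1.0 / temperature - 1.0 / T_REF
    ka = 10.0 ** LOG10_KA_REF * np.exp(-EA_ACID / R_GAS * tfac)
    kb = 10.0 ** LOG10_KB_REF * np.exp(-EA_BASE / R_GAS * tfac)
    kw = 10.0 ** LOG10_KW_REF * np.exp(-EA_WATER / R_GAS * tfac)

    values: dict[int, float] = {}
    n = len(sequence)
    for i in range(2, n + 1):
        aa = sequence[i - 1]
        if aa == "P":
            continue
        prev = sequence[i - 2]
        al, _, bl, _ = table[aa]
        _, ar, _, br = table[prev]
        acid_log = al + ar
        base_log = bl + br
        if i == 2:
            acid_log += table["NTERM"][1]
            base_log += table["NTERM"][3]
        if i == n:
            acid_log += table["CTERM"][0]
            base_log += table["CTERM"][2]
        k = (
            ka * 10.0 ** acid_log * d_conc
            + kb * 10.0 ** base_log * od_conc
            + kw * 10.0 ** base_log
        )
        values[i] = float(k)
    return IntrinsicRates(values=values, pH=pH, temperature=temperature)


def residue_uptake(lnP: float, k_int: float, times: Sequence[float]) -> UptakeCurve:
    """Pseudo-first-order uptake d(t) = 1 - exp(-(k_int / P) t), P = e^lnP."""
    if not np.isfinite(lnP):
        raise ValueError("lnP must be finite")
    if not k_int > 0:
        raise ValueError("k_int must be positive")
    t = np.asarray(times, dtype=float)
    k_obs = k_int * np.exp(-lnP)
    return UptakeCurve(times=t, values=-np.expm1(-k_obs * t))


def exchangeable_positions(pep: Peptide) -> list[int]:
    """Residue indices of ``pep`` contributing to its uptake average.

    The peptide's first two positions are excluded (terminal back-exchange,
    regardless of identity), as are prolines anywhere in the peptide.
    """
    positions = [
        pep.start + off
        for off, aa in enumerate(pep.sequence)
        if off >= 2 and aa != "P"
    ]
    if not positions:
        warnings.warn(
            f"peptide {pep.id} has no exchangeable positions; uptake undefined",
            stacklevel=2,
        )
    return positions


def peptide_uptake(pep: Peptide,
                   residue_curves: Mapping[int, UptakeCurve]) -> UptakeCurve:
    """Peptide uptake D_j(t): mean of member-residue curves over the
    exchangeable positions (shared time grid required)."""
    positions = exchangeable_positions(pep)
    if not positions:
        raise ValueError(f"peptide {pep.id}: uptake undefined (no exchangeable positions)")
    missing = [i for i in positions if i not in residue_curves]
    if missing:
        raise KeyError(f"peptide {pep.id}: missing residue curves for {missing}")
    curves = [residue_curves[i] for i in positions]
    t0 = curves[0].times
    for i, c in zip(positions[1:], curves[1:]):
        if c.times.shape != t0.shape or not np.allclose(c.times, t0):
            raise ValueError(f"peptide {pep.id}: residue {i} is on a different time grid")
    values = np.mean([c.values for c in curves], axis=0)
    return UptakeCurve(times=t0.copy(), values=values)


# ---------------------------------------------------------------------------
# tabular I/O


def load_rates_csv(path: str | Path) -> IntrinsicRates:
    """Read user-supplied rates: CSV columns residue_index, k_int_per_min."""
    values: dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            values[int(row["residue_index"])] = float(row["k_int_per_min"])
    if not values:
        raise ValueError(f"{path}: no rates found")
    return IntrinsicRates(values=values, pH=float("nan"), temperature=float("nan"))


def write_rates_csv(rates: IntrinsicRates, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue_index", "k_int_per_min"])
        for i in sorted(rates.values):
            writer.writerow([i, f"{rates.values[i]:.6g}"])
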