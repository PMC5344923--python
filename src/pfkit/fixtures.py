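"""Packaged experimental tables and synthetic structure/data generators.

Two residue-resolved protection-factor datasets ship with the package:

* ``CI2`` — 14 residues of a truncated chymotrypsin inhibitor 2 construct
  (64 residues; construct residue 1 is residue 20 of the full protein),
  native-state ln P values from HDX-NMR.
* ``Im7`` — 26 residues of the bacterial immunity protein Im7 (86 residues),
  ln P values characterizing its on-pathway folding intermediate, a state
  whose helix III is unformed.

Both tables are keyed by author residue numbering and are verified against a
stored checksum at load time; loaders never recompute values.

The synthetic builders produce ideal poly-alanine conformations (helix or
extended chain) and forward-simulated "observed" datasets with optional
Gaussian noise, so the whole pipeline is testable without any downloads.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _geom
from .exchange import ModelParams, ProtectionFactorSet, protection_factors
from .kinetics import IntrinsicRates, Peptide, UptakeCurve
from .structures import Atom, Conformation, Residue, place_amide_hydrogens

__all__ = [
    "PackagedDataset",
    "load_dataset",
    "make_ideal_helix",
    "make_extended_chain",
    "synthesize_observation",
]

_DATASETS = {
    "CI2": (
        "ci2_protection_factors.csv",
        "208dcfdae19da48fcf01f4cea61502f1184da85d621a55e7d89d1218e1806a36",
        "HDX-NMR ln P, native state of truncated CI2 (64 aa; construct "
        "residue 1 = residue 20 of the full protein); crystal structure "
        "PDB 1TM1",
    ),
    "IM7": (
        "im7_protection_factors.csv",
        "2e9baf479bbbd8c87bfe12b69aa5b5ae3dbd3338d00f85ace36740ae7542632c",
        "HDX-NMR ln P, folding intermediate of Im7 (86 aa); native crystal "
        "structure PDB 1AYI",
    ),
}


@dataclass(frozen=True)
class PackagedDataset:
    name: str
    residues: tuple[tuple[str, str, float], ...]  # (author label, resname, ln P)
    provenance: str

    def to_protection_factors(self) -> ProtectionFactorSet:
        """ln P keyed by author residue number (as integer)."""
        return ProtectionFactorSet(
            values={int(label): lnp for label, _, lnp in self.residues}
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["residue", "value", "log_base"])
            for label, _, lnp in self.residues:
                writer.writerow([label, lnp, "ln"])


def load_dataset(name: str) -> PackagedDataset:
    """Load a packaged protection-factor table (``CI2`` or ``Im7``)."""
    key = name.upper()
    if key not in _DATASETS:
        raise KeyError(
            f"unknown dataset {name!r}: packaged datasets are CI2 and Im7"
        )
    fname, checksum, provenance = _DATASETS[key]
    ref = resources.files("pfkit.data") / fname
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksum:
        raise RuntimeError(f"dataset {name}: checksum mismatch ({digest})")
    rows = list(csv.DictReader(raw.decode().splitlines()))
    residues = tuple(
        (row["residue"], row["resname"], float(row["lnP"])) for row in rows
    )
    return PackagedDataset(name=name, residues=residues, provenance=provenance)


# ---------------------------------------------------------------------------
# synthetic structures


def _poly_ala(phi_psi: tuple[float, float], n: int, label: str) -> Conformation:
    if n < 4:
        raise ValueError("need at least 4 residues")
    phi = np.full(n, phi_psi[0])
    psi = np.full(n, phi_psi[1])
    phi[0] = np.nan
    bb = _geom.build_backbone(np.where(np.isfinite(phi), phi, 180.0), psi)
    residues = []
    for i in range(n):
        atoms = [
            Atom("N", "N", bb["N"][i]),
            Atom("CA", "C", bb["CA"][i]),
            Atom("C", "C", bb["C"][i]),
            Atom("O", "O", bb["O"][i]),
            Atom("CB", "C", bb["CB"][i]),
        ]
        residues.append(Residue(index=i + 1, resname="ALA", atoms=atoms,
                                author_id=str(i + 1)))
    return place_amide_hydrogens(Conformation(residues, label=label))


def make_ideal_helix(n: int) -> Conformation:
    """Ideal poly-alanine alpha-helix, (phi, psi) = (-57, -47)."""
    return _poly_ala((-57.0, -47.0), n, f"helix{n}")


def make_extended_chain(n: int) -> Conformation:
    """Fully extended poly-alanine chain, (phi, psi) = (180, 180)."""
    return _poly_ala((180.0, 180.0), n, f"extended{n}")


# ---------------------------------------------------------------------------
# synthetic observations


def synthesize_observation(
    conf: Conformation,
    mode: str = "nmr",
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: ModelParams = ModelParams(),
    rates: Optional[IntrinsicRates] = None,
    peptides: Optional[Sequence[Peptide]] = None,
    times: Optional[Sequence[float]] = None,
):
    """Forward-simulate an observed-style dataset from a conformation.

    ``mode='nmr'`` returns a :class:`ProtectionFactorSet` (ln P plus
    Gaussian noise of ``noise_sigma``); ``mode='ms'`` runs the full uptake
    pipeline and returns a dict peptide id -> :class:`UptakeCurve` with
    noisy values clipped to [0, 1]. Deterministic for a fixed seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    pf = protection_factors(conf, params)
    if mode == "nmr":
        values = {
            i: v + (rng.normal(0.0, noise_sigma) if noise_sigma else 0.0)
            for i, v in sorted(pf.values.items())
        }
        return ProtectionFactorSet(values=values)
    if mode == "ms":
        if rates is None or peptides is None or times is None:
            raise ValueError("ms mode needs rates, peptides and times")
        from .fitting import derive_uptake

        curves = derive_uptake(pf, rates, peptides, times)
        if noise_sigma:
            for pid in sorted(curves):
                c = curves[pid]
                noisy = np.clip(c.values + rng.normal(0.0, noise_sigma,
                                                      size=c.values.shape), 0.0, 1.0)
                curves[pid] = UptakeCurve(times=c.times, values=noisy)
        return curves
    raise ValueError(f"unknown mode {mode!r} (expected 'nmr' or 'ms')")
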