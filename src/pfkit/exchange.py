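"""Phenomenological protection-factor model.

Protection of a backbone amide from hydrogen/deuterium exchange is modelled
as arising from two local structural determinants measured around the amide
hydrogen of residue i in a conformation C:

* ``N_h``: the number of hydrogen bonds the amide hydrogen forms, counted as
  main-chain carbonyl oxygens within 2.4 A of the amide H. Oxygens of
  residues i-2..i+2 are excluded, because the hydrogen bonds that maintain
  helices and sheets involve residues at least three positions apart.
* ``N_c``: the packing density around the amide, counted as heavy atoms
  (main-chain or side-chain, any residue except i-2..i+2) within 6.5 A of
  the amide hydrogen.

The natural-log protection factor is the weighted sum

    ln P_i(C) = beta_h * N_h + beta_c * N_c

with weights beta_h = 2 and beta_c = 0.35 fitted previously to experimental
exchange data. For a conformational ensemble S the model averages ln P (not
P) over the members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structures import Conformation, Ensemble

__all__ = [
    "ModelParams",
    "ProtectionFactorSet",
    "log_protection_factor",
    "count_amide_hbonds",
    "count_heavy_contacts",
    "protection_factors",
    "ensemble_protection_factors",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the protection-factor model.

    beta_h / beta_c are dimensionless weights per hydrogen bond / contact;
    cutoffs are in Angstrom, measured from the amide hydrogen; the exclusion
    window is the half-width of the sequence neighborhood i-w..i+w whose
    atoms never count.
    """

    beta_h: float = 2.0
    beta_c: float = 0.35
    hbond_cutoff: float = 2.4
    contact_cutoff: float = 6.5
    exclusion_window: int = 2

    def __post_init__(self) -> None:
        if self.hbond_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.exclusion_window < 0:
            raise ValueError("exclusion_window must be >= 0")


@dataclass
class ProtectionFactorSet:
    """Per-residue natural-log protection factors (ln P).

    ``values`` maps the 1-based residue index to ln P; residues without an
    amide hydrogen (prolines, the N-terminal residue) are absent. ``counts``
    optionally carries the (N_h, N_c) pair each value was derived from.
    """

    values: dict[int, float]
    counts: Optional[dict[int, tuple[int, int]]] = None
    log_base: str = field(default="ln", repr=False)

    def __post_init__(self) -> None:
        if self.log_base == "log10":
            self.values = {i: v * LN10 for i, v in self.values.items()}
            self.log_base = "ln"
        elif self.log_base != "ln":
            raise ValueError(f"unknown log base {self.log_base!r}")

    def __len__(self) -> int:
        return len(self.values)

    def residues(self) -> list[int]:
        return sorted(self.values)


def log_protection_factor(n_hbonds: int, n_contacts: int,
                          params: ModelParams = ModelParams()) -> float:
    """ln P for a residue with the given hydrogen-bond and contact counts."""
    if n_hbonds < 0 or n_contacts < 0:
        raise ValueError("counts must be non-negative")
    return params.beta_h * n_hbonds + params.beta_c * n_contacts


def _mainchain_oxygens(conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
    """Backbone carbonyl O coordinates and their residue indices.

    Only the backbone O counts as candidate acceptor; the C-terminal OXT is
    deliberately excluded.
    """
    coords, owner = [], []
    for r in conf:
        o = r.coord("O")
        if o is not None:
            coords.append(o)
            owner.append(r.index)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.asarray(coords), np.asarray(owner, dtype=int)


def _amide_h(conf: Conformation, i: int) -> np.ndarray:
    res = conf.residue(i)
    if res.amide_h is None:
        raise ValueError(
            f"residue {i} ({res.resname}) has no amide hydrogen; "
            "place hydrogens first"
        )
    return res.amide_h


def count_amide_hbonds(conf: Conformation, i: int,
                       params: ModelParams = ModelParams()) -> int:
    """Number of main-chain carbonyl oxygens within ``hbond_cutoff`` of the
    amide hydrogen of residue i, excluding residues i-w..i+w."""
    h = _amide_h(conf, i)
    coords, owner = _mainchain_oxygens(conf)
    if len(coords) == 0:
        return 0
    keep = np.abs(owner - i) > params.exclusion_window
    d = np.linalg.norm(coords[keep] - h, axis=1)
    return int(np.count_nonzero(d <= params.hbond_cutoff))


def count_heavy_contacts(conf: Conformation, i: int,
                         params: ModelParams = ModelParams()) -> int:
    """Number of heavy atoms (any residue except i-w..i+w, main-chain or
    side-chain) within ``contact_cutoff`` of the amide hydrogen of residue i."""
    h = _amide_h(conf, i)
    coords, owner = conf.heavy_atoms()
    if len(coords) == 0:
        return 0
    keep = np.abs(owner - i) > params.exclusion_window
    d = np.linalg.norm(coords[keep] - h, axis=1)
    return int(np.count_nonzero(d <= params.contact_cutoff))


def protection_factors(conf: Conformation,
                       params: ModelParams = ModelParams()) -> ProtectionFactorSet:
    """ln P for every residue of ``conf`` that carries an amide hydrogen."""
    o_coords, o_owner = _mainchain_oxygens(conf)
    a_coords, a_owner = conf.heavy_atoms()
    values: dict[int, float] = {}
    counts: dict[int, tuple[int, int]] = {}
    w = params.exclusion_window
    for res in conf:
        if res.amide_h is None:
            continue
        h = res.amide_h
        i = res.index
        if len(o_coords):
            sel = np.abs(o_owner - i) > w
            dh = np.linalg.norm(o_coords[sel] - h, axis=1)
            n_h = int(np.count_nonzero(dh <= params.hbond_cutoff))
        else:
            n_h = 0
        if len(a_coords):
            sel = np.abs(a_owner - i) > w
            dc = np.linalg.norm(a_coords[sel] - h, axis=1)
            n_c = int(np.count_nonzero(dc <= params.contact_cutoff))
        else:
            n_c = 0
        values[i] = log_protection_factor(n_h, n_c, params)
        counts[i] = (n_h, n_c)
    return ProtectionFactorSet(values=values, counts=counts)


def ensemble_protection_factors(ens: Ensemble,
                                params: ModelParams = ModelParams()
                                ) -> ProtectionFactorSet:
    """Ensemble-average ln P: the arithmetic mean of ln P over members.

    The average is taken over ln P, not over P itself.
    """
    per_member = [protection_factors(c, params) for c in ens]
    residues = set(per_member[0].values)
    for pf in per_member[1:]:
        residues &= set(pf.values)
    values = {
        i: float(np.mean([pf.values[i] for pf in per_member])) for i in residues
    }
    return ProtectionFactorSet(values=values)
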