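"""Coarse-grained backbone conformational sampling.

Conformations are represented by their backbone (phi, psi) dihedral vector;
bond lengths and angles are held ideal and the peptide torsion is fixed
trans (omega = 180 deg), so a chain of N+1 residues has 2N degrees of
freedom. Moves perturb the (phi, psi) angles of a *fragment* — a set of
residues with a sampling weight — by Gaussian noise, rebuild cartesian
coordinates kinematically, and are accepted when a soft-sphere clash score
stays under a threshold. Side chains are carried rigidly in each residue's
local backbone frame (no repacking).

The refinement loop alternates exploration with reweighting: fragments
covering the regions where derived and experimental exchange data disagree
most are given a higher probability of being perturbed in the next round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from . import _geom
from .exchange import ModelParams
from .fitting import (
    ExperimentalData,
    MSFitReport,
    NMRFitReport,
    nmr_fit,
    ms_fit,
    score_conformation,
)
from .kinetics import IntrinsicRates, Peptide
from .structures import Atom, Conformation, Ensemble, place_amide_hydrogens

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "DihedralVector",
    "SamplerConfig",
    "RefineTrace",
    "extract_dihedrals",
    "rebuild_conformation",
    "clash_score",
    "propose_move",
    "explore",
    "discrepancy_weights",
    "iterate_refine",
]

#: Soft-sphere clash distance between non-bonded heavy atoms (Angstrom).
CLASH_DISTANCE = 3.0


@dataclass(frozen=True)
class Fragment:
    """A set of residues perturbed as a unit, with a sampling weight."""

    id: str
    residue_indices: frozenset[int]
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_indices", frozenset(self.residue_indices))
        if self.weight < 0:
            raise ValueError(f"fragment {self.id}: weight must be >= 0")
        if not self.residue_indices:
            raise ValueError(f"fragment {self.id}: empty residue set")


@dataclass
class DihedralVector:
    """Backbone (phi, psi) per residue, degrees; NaN where undefined
    (phi of residue 1, psi of the last residue)."""

    phi: np.ndarray
    psi: np.ndarray
    last_o_torsion: float = 0.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have equal length")

    def __len__(self) -> int:
        return len(self.phi)

    def copy(self) -> "DihedralVector":
        return DihedralVector(self.phi.copy(), self.psi.copy(), self.last_o_torsion)


@dataclass
class SamplerConfig:
    n_conformations: int = 100
    perturbation_sigma: float = 5.0
    energy_threshold: Optional[float] = None  # None -> 1.1 x start score
    fragments: Optional[list[Fragment]] = None  # None -> one whole-chain fragment
    seed: int = 0
    max_attempts_per_accept: int = 50

    def __post_init__(self) -> None:
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")
        if self.perturbation_sigma <= 0:
            raise ValueError("perturbation_sigma must be > 0")
        if self.max_attempts_per_accept < 1:
            raise ValueError("max_attempts_per_accept must be >= 1")


@dataclass
class RefineTrace:
    """Per-round record of the refinement loop."""

    best_scores: list[float] = field(default_factory=list)
    best_labels: list[str] = field(default_factory=list)
    weights: list[dict[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal coordinates


def extract_dihedrals(conf: Conformation) -> DihedralVector:
    """Standard phi = C(i-1)-N-CA-C and psi = N-CA-C-N(i+1) torsions."""
    n = len(conf)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    bb = []
    for r in conf:
        atoms = {name: r.coord(name) for name in ("N", "CA", "C", "O")}
        if atoms["N"] is None or atoms["CA"] is None or atoms["C"] is None:
            raise ValueError(f"residue {r.index}: missing backbone atom")
        bb.append(atoms)
    for i in range(n):
        if i > 0:
            phi[i] = _geom.torsion(bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"], bb[i]["C"])
        if i < n - 1:
            psi[i] = _geom.torsion(bb[i]["N"], bb[i]["CA"], bb[i]["C"], bb[i + 1]["N"])
    last_o = 0.0
    if bb[-1]["O"] is not None:
        last_o = _geom.torsion(bb[-1]["N"], bb[-1]["CA"], bb[-1]["C"], bb[-1]["O"])
    return DihedralVector(phi=phi, psi=psi, last_o_torsion=last_o)


def _local_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Orthonormal residue frame (rows) from backbone N, CA, C."""
    e1 = n - ca
    e1 /= np.linalg.norm(e1)
    v = c - ca
    e2 = v - np.dot(v, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.vstack([e1, e2, e3])


def rebuild_conformation(dv: DihedralVector, template: Conformation) -> Conformation:
    """Rebuild cartesian coordinates from a dihedral vector.

    The backbone is reconstructed with ideal bond geometry and omega = 180,
    then superposed onto the template's first-residue frame. Side-chain atoms
    are carried rigidly in each residue's local backbone frame; the amide
    hydrogens are re-placed from the new geometry.
    """
    n = len(template)
    if len(dv) != n:
        raise ValueError(f"dihedral vector length {len(dv)} != chain length {n}")
    phi = dv.phi.copy()
    psi = dv.psi.copy()
    # undefined terminal angles do not affect the build; give them inert values
    if not np.isfinite(phi[0]):
        phi[0] = 180.0
    if n > 1 and not np.isfinite(psi[-1]):
        psi[-1] = 180.0
    bb = _geom.build_backbone(phi, psi, last_o_torsion=dv.last_o_torsion)

    # anchor on the template's first residue frame
    t0 = template.residues[0]
    target = np.array([t0.coord("N"), t0.coord("CA"), t0.coord("C")])
    mobile = np.array([bb["N"][0], bb["CA"][0], bb["C"][0]])
    R, t = _geom.kabsch(mobile, target)
    for key in bb:
        bb[key] = bb[key] @ R.T + t

    backbone_names = {"N", "CA", "C", "O"}
    residues = []
    out = template.copy()
    for i, res in enumerate(out.residues):
        new_atoms: list[Atom] = []
        old = {name: res.coord(name) for name in ("N", "CA", "C")}
        frame_old = _local_frame(old["N"], old["CA"], old["C"])
        frame_new = _local_frame(bb["N"][i], bb["CA"][i], bb["C"][i])
        for a in res.atoms:
            if a.name in backbone_names:
                new_atoms.append(Atom(a.name, a.element, bb[a.name][i].copy()))
            else:
                local = frame_old @ (a.coords - old["CA"])
                new_atoms.append(
                    Atom(a.name, a.element, bb["CA"][i] + frame_new.T @ local)
                )
        res.atoms = new_atoms
        res.amide_h = None
        residues.append(res)
    rebuilt = Conformation(residues, label=template.label)
    return place_amide_hydrogens(rebuilt)


# ---------------------------------------------------------------------------
# scoring and moves


def clash_score(conf: Conformation) -> float:
    """Soft-sphere clash score over heavy-atom pairs.

    Sum of (d_clash - d)^2 over non-bonded heavy-atom pairs closer than
    d_clash = 3.0 A, where non-bonded means a sequence separation of at
    least 2 residues. Zero for clash-free structures.
    """
    coords, owner = conf.heavy_atoms()
    if len(coords) < 2:
        return 0.0
    tree = cKDTree(coords)
    pairs = tree.query_pairs(CLASH_DISTANCE, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    sep = np.abs(owner[pairs[:, 0]] - owner[pairs[:, 1]])
    pairs = pairs[sep >= 2]
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(np.sum((CLASH_DISTANCE - d) ** 2))


def _default_fragments(conf: Conformation) -> list[Fragment]:
    return [Fragment(id="chain", residue_indices=frozenset(range(1, len(conf) + 1)))]


def _pick_fragment(fragments: Sequence[Fragment], rng: np.random.Generator) -> Fragment:
    weights = np.array([f.weight for f in fragments], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all fragment weights are zero")
    return fragments[rng.choice(len(fragments), p=weights / total)]


def propose_move(conf: Conformation, config: SamplerConfig,
                 rng: np.random.Generator) -> Conformation:
    """One move: pick a fragment with probability proportional to its weight,
    add Gaussian noise (sigma = perturbation_sigma) to the (phi, psi) of its
    residues, and rebuild coordinates."""
    fragments = config.fragments or _default_fragments(conf)
    frag = _pick_fragment(fragments, rng)
    dv = extract_dihedrals(conf)
    for i in sorted(frag.residue_indices):
        if np.isfinite(dv.phi[i - 1]):
            dv.phi[i - 1] = _wrap_angle(
                dv.phi[i - 1] + rng.normal(0.0, config.perturbation_sigma))
        if np.isfinite(dv.psi[i - 1]):
            dv.psi[i - 1] = _wrap_angle(
                dv.psi[i - 1] + rng.normal(0.0, config.perturbation_sigma))
    return rebuild_conformation(dv, conf)


def _wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def explore(start: Conformation, config: SamplerConfig) -> Ensemble:
    """Grow an ensemble from ``start`` by random perturbation.

    Each step perturbs a randomly chosen existing member and accepts the
    proposal iff its clash score is at or below the energy threshold
    (default: 1.1 x the start conformation's own score). Deterministic for a
    fixed seed. Raises if the attempt budget ends with zero acceptances.
    """
    rng = np.random.default_rng(config.seed)
    threshold = config.energy_threshold
    if threshold is None:
        threshold = 1.1 * clash_score(start)
    accepted: list[Conformation] = []
    pool: list[Conformation] = [start]
    budget = config.n_conformations * config.max_attempts_per_accept
    attempts = 0
    while len(accepted) < config.n_conformations and attempts < budget:
        attempts += 1
        parent = pool[rng.integers(len(pool))]
        cand = propose_move(parent, config, rng)
        if clash_score(cand) <= threshold:
            cand.label = f"{start.label or 'start'}/s{len(accepted) + 1}"
            accepted.append(cand)
            pool.append(cand)
    if not accepted:
        raise RuntimeError(
            f"no conformation accepted in {attempts} attempts; "
            "raise energy_threshold or lower perturbation_sigma"
        )
    if len(accepted) < config.n_conformations:
        logger.warning("explore: accepted %d/%d conformations within budget",
                       len(accepted), config.n_conformations)
    return Ensemble(accepted, source=f"explore(seed={config.seed})")


# ---------------------------------------------------------------------------
# discrepancy-guided refinement


def _per_residue_errors(report: Union[NMRFitReport, MSFitReport]) -> dict[int, float]:
    if isinstance(report, NMRFitReport):
        return dict(report.per_residue_error)
    if report.peptide_spans is None:
        raise ValueError("MS report lacks peptide spans; pass peptides to ms_fit")
    sums: dict[int, float] = {}
    hits: dict[int, int] = {}
    for pid, err in report.per_peptide_error.items():
        start, end = report.peptide_spans[pid]
        for i in range(start, end + 1):
            sums[i] = sums.get(i, 0.0) + err
            hits[i] = hits.get(i, 0) + 1
    return {i: sums[i] / hits[i] for i in sums}


def discrepancy_weights(report: Union[NMRFitReport, MSFitReport],
                        fragments: Sequence[Fragment],
                        boost: float = 4.0) -> list[Fragment]:
    """Reweight fragments toward the regions of largest data discrepancy.

    Each fragment's discrepancy is the mean per-residue error over its
    residues (peptide errors are first spread over the peptide's span). The
    ceil(k/4) highest-discrepancy fragments get their weight multiplied by
    ``boost``; weights are then renormalized to sum to 1. With uniform
    errors no fragment stands out and all are boosted equally, which the
    renormalization cancels.
    """
    errors = _per_residue_errors(report)
    disc = []
    any_overlap = False
    for f in fragments:
        vals = [errors[i] for i in f.residue_indices if i in errors]
        if vals:
            any_overlap = True
        disc.append(float(np.mean(vals)) if vals else 0.0)
    if not any_overlap:
        raise ValueError("no overlap between fit report and fragments")
    k = len(fragments)
    n_top = max(1, -(-k // 4))  # ceil(k/4)
    order = sorted(range(k), key=lambda j: (-disc[j], j))
    top = set(order[:n_top])
    # ties at the quartile boundary are all boosted
    cut = disc[order[n_top - 1]]
    top |= {j for j in range(k) if disc[j] == cut and cut > 0}
    new_weights = np.array(
        [f.weight * (boost if j in top else 1.0) for j, f in enumerate(fragments)]
    )
    total = new_weights.sum()
    if total <= 0:
        raise ValueError("all reweighted fragments have zero weight")
    new_weights /= total
    return [replace(f, weight=float(wt)) for f, wt in zip(fragments, new_weights)]


def _fit_report(conf: Conformation, experimental: ExperimentalData,
                params: ModelParams,
                rates: Optional[IntrinsicRates],
                peptides: Optional[Sequence[Peptide]],
                times) -> Union[NMRFitReport, MSFitReport]:
    from .exchange import ProtectionFactorSet, protection_factors
    from .fitting import derive_uptake

    pf = protection_factors(conf, params)
    if isinstance(experimental, ProtectionFactorSet):
        return nmr_fit(pf, experimental)
    derived = derive_uptake(pf, rates, peptides, times)
    return ms_fit(derived, experimental, peptides)


def iterate_refine(start: Conformation, experimental: ExperimentalData,
                   config: SamplerConfig, n_rounds: int = 5,
                   stop_score: float = 0.0,
                   params: ModelParams = ModelParams(),
                   rates: Optional[IntrinsicRates] = None,
                   peptides: Optional[Sequence[Peptide]] = None,
                   times=None,
                   boost: float = 4.0) -> tuple[Conformation, RefineTrace]:
    """Iterative discrepancy-guided search for a single best-fit conformation.

    Round 1 explores from ``start`` with the configured (uniform by default)
    fragment weights. Each later round recomputes the fit report of the
    current best conformation, boosts the weights of the worst-fitting
    fragments, and explores again seeded from the current best. Stops early
    once the best score reaches ``stop_score``. The best-so-far score is
    non-increasing across rounds by construction.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    from .exchange import ProtectionFactorSet

    if times is None and not isinstance(experimental, ProtectionFactorSet):
        times = next(iter(experimental.values())).times

    def score(conf: Conformation) -> float:
        return score_conformation(conf, experimental, params, rates, peptides, times)

    base_fragments = config.fragments or _default_fragments(start)
    seeds = np.random.SeedSequence(config.seed).spawn(n_rounds)
    trace = RefineTrace()
    best = start
    best_score = score(start)
    if best_score <= stop_score:
        trace.best_scores.append(best_score)
        trace.best_labels.append(best.label or "start")
        trace.weights.append({f.id: f.weight for f in base_fragments})
        return best, trace

    fragments = list(base_fragments)
    for round_idx in range(n_rounds):
        if round_idx > 0:
            report = _fit_report(best, experimental, params, rates, peptides, times)
            fragments = discrepancy_weights(report, base_fragments, boost)
        round_cfg = replace(
            config,
            fragments=fragments,
            seed=int(seeds[round_idx].generate_state(1)[0] % (2**31)),
        )
        ens = explore(best, round_cfg)
        for conf in ens:
            s = score(conf)
            if s < best_score:
                best_score = s
                best = conf
        trace.best_scores.append(best_score)
        trace.best_labels.append(best.label or "start")
        trace.weights.append({f.id: f.weight for f in fragments})
        if best_score <= stop_score:
            break
    return best, trace
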