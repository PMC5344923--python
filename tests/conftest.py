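import numpy as np
import pytest

from pfkit._geom import build_backbone
from pfkit.fixtures import make_extended_chain, make_ideal_helix
from pfkit.structures import Atom, Conformation, Residue, place_amide_hydrogens


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def extended12():
    return make_extended_chain(12)


def make_random_coil(n: int, seed: int) -> Conformation:
    """Poly-alanine chain with random backbone dihedrals, H placed."""
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-180.0, 180.0, size=n)
    psi = rng.uniform(-180.0, 180.0, size=n)
    bb = build_backbone(phi, psi)
    residues = []
    for i in range(n):
        atoms = [
            Atom("N", "N", bb["N"][i]),
            Atom("CA", "C", bb["CA"][i]),
            Atom("C", "C", bb["C"][i]),
            Atom("O", "O", bb["O"][i]),
            Atom("CB", "C", bb["CB"][i]),
        ]
        residues.append(Residue(index=i + 1, resname="ALA", atoms=atoms))
    return place_amide_hydrogens(Conformation(residues, label=f"coil{n}s{seed}"))


def make_toy_chain(n: int, spacing: float = 100.0) -> Conformation:
    """Chain of well-separated single-bead residues for constructed-geometry
    tests: each residue has N/CA/C/O collapsed near one point ``spacing``
    apart along x, and an amide H 1 A from its N (except residue 1)."""
    residues = []
    for i in range(n):
        base = np.array([i * spacing, 0.0, 0.0])
        atoms = [
            Atom("N", "N", base),
            Atom("CA", "C", base + [1.0, 0.0, 0.0]),
            Atom("C", "C", base + [2.0, 0.0, 0.0]),
            Atom("O", "O", base + [2.0, 1.0, 0.0]),
        ]
        amide_h = None if i == 0 else base + [0.0, 1.0, 0.0]
        residues.append(
            Residue(index=i + 1, resname="ALA", atoms=atoms, amide_h=amide_h)
        )
    return Conformation(residues, label="toy")


def plant_recovery_case(start, seed, fragments, clash_threshold=2.0,
                        min_signal=0.15, move_sigma=8.0):
    """Plant a recovery target for a refinement experiment.

    The target is one clash-feasible single-fragment move away from
    ``start`` and must produce a detectable discrepancy (mean |delta ln P|
    >= ``min_signal``) — a planted signal indistinguishable from the start
    cannot meaningfully be recovered. Returns (target, observed ln P,
    start error).
    """
    from pfkit.exchange import protection_factors
    from pfkit.fitting import nmr_fit
    from pfkit.fixtures import synthesize_observation
    from pfkit.sampler import SamplerConfig, clash_score, propose_move

    rng = np.random.default_rng(1000 + seed)
    while True:
        k = rng.integers(len(fragments))
        cfg = SamplerConfig(perturbation_sigma=move_sigma,
                            fragments=[fragments[k]])
        target = propose_move(start, cfg, rng)
        if clash_score(target) > clash_threshold:
            continue
        observed = synthesize_observation(target, mode="nmr", noise_sigma=0.0)
        start_error = nmr_fit(protection_factors(start),
                              observed).mean_abs_error
        if start_error >= min_signal:
            return target, observed, start_error


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.729   6.768  -4.156  1.00  0.00           C
ATOM      4  O   ALA A   1       9.580   7.075  -4.474  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.864   4.628  -4.717  1.00  0.00           C
ATOM      6  N   GLY A   2      11.255   7.037  -2.965  1.00  0.00           N
ATOM      7  CA  GLY A   2      10.466   7.689  -1.929  1.00  0.00           C
ATOM      8  C   GLY A   2      11.030   7.407  -0.555  1.00  0.00           C
ATOM      9  O   GLY A   2      12.219   7.111  -0.414  1.00  0.00           O
ATOM     10  N   SER A   3      10.175   7.507   0.459  1.00  0.00           N
ATOM     11  CA  SER A   3      10.560   7.280   1.846  1.00  0.00           C
ATOM     12  C   SER A   3       9.796   8.199   2.780  1.00  0.00           C
ATOM     13  O   SER A   3       8.602   8.424   2.599  1.00  0.00           O
ATOM     14  CB  SER A   3      10.285   5.828   2.246  1.00  0.00           C
ATOM     15  OG  SER A   3      10.960   5.507   3.447  1.00  0.00           O
TER
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    body = "".join(l + "\n" for l in MINIMAL_PDB.splitlines() if l not in ("TER", "END"))
    p = tmp_path / "two.pdb"
    p.write_text(
        "MODEL        1\n" + body + "ENDMDL\n"
        "MODEL        2\n" + body + "ENDMDL\nEND\n"
    )
    return p


@pytest.fixture
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_ONLY_PDB)
    return p
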