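"""Synthetic-input generators: idealized base geometry and test fixtures.

Everything the tool needs for demonstrations and tests is generated here from
first principles — no downloads, no external coordinate files.

The geometry is deliberately idealized: purine and pyrimidine rings are
regular polygons with a 1.38 Å bond length, base pairs are built by docking
two base edges (Watson-Crick, Hoogsteen or Sugar) at a fixed 2.9 Å contact
gap, and helices stack such pairs with A-form-like twist and rise.  The
resulting inter-bead distances define the pair-restraint targets used across
the package; they are internally consistent rather than copied from any
crystallographic survey.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cg_model_io import CGConformation, Nucleotide, PURINES

RING_BOND = 1.38     # ring bond length, Angstrom
EDGE_GAP = 2.9       # edge-to-edge docking distance (H-bond scale), Angstrom
GLYCO_C4P = 2.4      # glycosidic N -> C4' bead distance, Angstrom
GLYCO_P = 4.0        # glycosidic N -> P bead distance (in-plane part), Angstrom
P_LIFT = 1.2         # out-of-plane lift of the P bead, Angstrom
HELIX_TWIST = np.deg2rad(32.7)  # A-form-like twist per base pair
HELIX_RISE = 3.2                # helical rise per base pair, Angstrom; a bit
                                # above A-form so one-step slipped pairs stay
                                # clearly outside the detection tolerance
COIL_SPACING = 7.0   # residue spacing in the extended-coil fixture, Angstrom

_HEX_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6")


def _rotz(th: float) -> np.ndarray:
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_about(axis: np.ndarray, th: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * K @ K


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def base_atoms(res_type: str) -> dict[str, np.ndarray]:
    """Idealized ring-atom coordinates of a base, in its own plane (z = 0).

    Pyrimidines are a regular hexagon N1..C6; purines add a regular pentagon
    C4-C5-N7-C8-N9 fused on the C4-C5 edge.
    """
    ang = np.deg2rad(90.0 - 60.0 * np.arange(6))
    hexa = RING_BOND * np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
    atoms = dict(zip(_HEX_NAMES, hexa))
    if res_type in PURINES:
        pts = [atoms["C4"], atoms["C5"]]
        v = atoms["C5"] - atoms["C4"]
        for _ in range(3):
            v = _rotz(np.deg2rad(72.0)) @ v
            pts.append(pts[-1] + v)
        atoms["N7"], atoms["C8"], atoms["N9"] = pts[2], pts[3], pts[4]
    return atoms


def _ring_center(atoms: dict[str, np.ndarray], res_type: str) -> np.ndarray:
    """Center of the ring bearing the glycosidic nitrogen."""
    if res_type in PURINES:
        ring = ("C4", "C5", "N7", "C8", "N9")
    else:
        ring = _HEX_NAMES
    return np.mean([atoms[a] for a in ring], axis=0)


def base_edge(atoms: dict[str, np.ndarray], res_type: str, edge: str):
    """Anchor point and outward in-plane unit vector of a pairing edge.

    W = Watson-Crick edge, H = Hoogsteen (C-H edge for pyrimidines),
    S = sugar edge.
    """
    hexc = np.mean([atoms[a] for a in _HEX_NAMES], axis=0)
    if res_type in PURINES:
        allc = np.mean(list(atoms.values()), axis=0)
        table = {
            "W": (0.5 * (atoms["N1"] + atoms["C6"]), hexc),
            "H": (0.5 * (atoms["N7"] + atoms["C6"]), allc),
            "S": (0.5 * (atoms["C2"] + atoms["N3"]), hexc),
        }
    else:
        table = {
            "W": (atoms["N3"], hexc),
            "H": (0.5 * (atoms["C4"] + atoms["C5"]), hexc),
            "S": (atoms["C2"], hexc),
        }
    if edge not in table:
        raise ValueError(f"unknown edge {edge!r}")
    p, ref = table[edge]
    return p, _unit(p - ref)


def glycosidic_direction(atoms: dict[str, np.ndarray], res_type: str) -> np.ndarray:
    n_name = "N9" if res_type in PURINES else "N1"
    return _unit(atoms[n_name] - _ring_center(atoms, res_type))


def base_normal(atoms: dict[str, np.ndarray], res_type: str) -> np.ndarray:
    """Unit normal of the base plane (orientation-sensitive: flips with the base)."""
    n_name = "N9" if res_type in PURINES else "N1"
    a = atoms["C2"] - atoms[n_name]
    b = atoms["C6" if res_type in PURINES else "C4"] - atoms[n_name]
    return _unit(np.cross(a, b))


def beads_from_atoms(atoms: dict[str, np.ndarray], res_type: str) -> np.ndarray:
    """The 5 coarse-grained beads (P, C4', N, C2, C4|C6) of a placed base."""
    n_name = "N9" if res_type in PURINES else "N1"
    c_name = "C6" if res_type in PURINES else "C4"
    n = atoms[n_name]
    g = glycosidic_direction(atoms, res_type)
    nz = base_normal(atoms, res_type)
    c4p = n + GLYCO_C4P * g
    p = n + GLYCO_P * g + P_LIFT * nz
    return np.stack([p, c4p, n, atoms["C2"], atoms[c_name]])


def make_ideal_pair(
    type_i: str, type_j: str, edge_i: str, edge_j: str, orientation: str
) -> tuple[np.ndarray, np.ndarray]:
    """Dock base j against base i along the requested edges.

    Returns the two residues' bead sets (each (5, 3)).  *cis* pairs flip base
    j out of plane (180° about the docking axis) so both glycosidic bonds end
    up on the same side, as in a canonical Watson-Crick pair; *trans* pairs
    keep both faces up.
    """
    ai = base_atoms(type_i)
    aj0 = base_atoms(type_j)
    pi, ui = base_edge(ai, type_i, edge_i)
    pj, uj = base_edge(aj0, type_j, edge_j)
    th = np.arctan2(-ui[1], -ui[0]) - np.arctan2(uj[1], uj[0])
    R = _rotz(th)
    aj = {k: R @ v for k, v in aj0.items()}
    pj = R @ pj
    if orientation == "cis":
        F = _rot_about(ui, np.pi)
        aj = {k: F @ (v - pj) + pj for k, v in aj.items()}
    elif orientation != "trans":
        raise ValueError(f"unknown orientation {orientation!r}")
    t = pi + EDGE_GAP * ui - pj
    aj = {k: v + t for k, v in aj.items()}
    return beads_from_atoms(ai, type_i), beads_from_atoms(aj, type_j)


def measure_pair_distances(
    type_i: str, type_j: str, edge_i: str, edge_j: str, orientation: str
) -> tuple[float, float, float]:
    """The three base-bead distances (N-N, C2-C2, C46-C46) of an ideal pair."""
    bi, bj = make_ideal_pair(type_i, type_j, edge_i, edge_j, orientation)
    return tuple(float(np.linalg.norm(bi[k] - bj[k])) for k in (2, 3, 4))


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    kind: str                      # ideal_helix | hairpin | two_register | coil | quadruplex_like
    sequence: str | None = None    # chains separated by spaces; kind default if None
    stem: int = 8                  # base pairs in helix/hairpin stems
    loop: int = 4                  # hairpin loop length
    noise_sigma: float = 0.0       # Gaussian coordinate noise, Angstrom
    seed: int = 0


def _pair_frame(type_i: str, type_j: str) -> tuple[np.ndarray, np.ndarray]:
    """A cWW pair re-centered so the glycosidic-N axis lies along x with its
    midpoint at the origin (strand-i nitrogen at +x)."""
    bi, bj = make_ideal_pair(type_i, type_j, "W", "W", "cis")
    mid = 0.5 * (bi[2] + bj[2])
    bi = bi - mid
    bj = bj - mid
    th = -np.arctan2(bi[2][1], bi[2][0])
    R = _rotz(th)
    return bi @ R.T, bj @ R.T


def _helix_pair_coords(seq1: str, n_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of a stacked run of cWW pairs: strand-1 bases seq1[:n_pairs],
    partners complementary.  Returns (strand1, strand2) bead arrays."""
    s1 = np.zeros((n_pairs, 5, 3))
    s2 = np.zeros((n_pairs, 5, 3))
    for k in range(n_pairs):
        ti = seq1[k]
        tj = _COMPLEMENT[ti]
        bi, bj = _pair_frame(ti, tj)
        R = _rotz(k * HELIX_TWIST)
        z = np.array([0.0, 0.0, k * HELIX_RISE])
        s1[k] = bi @ R.T + z
        s2[k] = bj @ R.T + z
    return s1, s2


def _coil_coords(seq: str, y_offset: float = 0.0) -> np.ndarray:
    """Fully extended chain: glycosidic nitrogens collinear along x at 7 Å
    residue spacing, each residue's beads at their ideal template geometry
    (rotated so the glycosidic bond points along +y)."""
    out = np.zeros((len(seq), 5, 3))
    for i, t in enumerate(seq):
        atoms = base_atoms(t)
        g = glycosidic_direction(atoms, t)
        th = np.pi / 2 - np.arctan2(g[1], g[0])
        beads = beads_from_atoms(atoms, t) @ _rotz(th).T
        beads -= beads[2]  # glycosidic N at the origin
        beads += np.array([COIL_SPACING * i, y_offset, 0.0])
        out[i] = beads
    return out


def build_ideal_pair_or_helix(spec: FixtureSpec):
    """Construct a fixture conformation and its designed canonical pair list.

    Returns ``(conformation, pairs)`` where pairs are 0-based global residue
    index tuples (i, j), i < j.
    """
    rng = np.random.default_rng(spec.seed)
    kind = spec.kind
    if kind == "ideal_helix":
        seq1 = spec.sequence or "G" * spec.stem
        if " " in seq1:
            seq1 = seq1.split()[0]
        n = len(seq1)
        s1, s2 = _helix_pair_coords(seq1, n)
        residues = [Nucleotide("A", i + 1, seq1[i], s1[i]) for i in range(n)]
        # strand 2 runs antiparallel: residue m of chain B pairs residue n-1-m of A
        seq2 = "".join(_COMPLEMENT[t] for t in seq1[::-1])
        residues += [Nucleotide("B", m + 1, seq2[m], s2[n - 1 - m]) for m in range(n)]
        pairs = [(i, 2 * n - 1 - i) for i in range(n)]
    elif kind == "hairpin":
        if spec.sequence:
            seq = spec.sequence
            s = spec.stem
            l = len(seq) - 2 * s
        else:
            s, l = spec.stem, spec.loop
            seq = "G" * s + "A" * l + "C" * s
        if l < 3:
            raise ValueError("hairpin loop must have at least 3 residues")
        n = len(seq)
        s1, s2 = _helix_pair_coords(seq, s)
        coords = np.zeros((n, 5, 3))
        for i in range(s):
            coords[i] = s1[i]
            coords[n - 1 - i] = s2[i]
        # loop: semicircular arc above the top pair bridging the two strand
        # ends, each residue oriented with its glycosidic bond pointing
        # radially outward so neighbors fan apart
        e1 = coords[s - 1, 1]
        e2 = coords[n - s, 1]
        c = 0.5 * (e1 + e2)
        ax = _unit((e1 - e2) - np.array([0.0, 0.0, e1[2] - e2[2]]))
        zhat = np.array([0.0, 0.0, 1.0])
        oop = _unit(np.cross(ax, zhat))
        r0 = max(0.5 * np.linalg.norm(e1 - e2) + 2.0, 1.1 * l)
        for r in np.arange(r0, r0 + 20.0, 1.0):
            # glycosidic bonds point radially outward; grow the arc until the
            # inward-facing ring atoms of neighboring residues stop clashing
            for t in range(l):
                th = np.pi * (t + 1) / (l + 1)
                u = np.cos(th) * ax + np.sin(th) * zhat
                rt = seq[s + t]
                atoms = base_atoms(rt)
                tmpl = beads_from_atoms(atoms, rt)
                g = glycosidic_direction(atoms, rt)
                nz = base_normal(atoms, rt)
                A = np.stack([g, nz, np.cross(g, nz)], axis=1)
                B = np.stack([u, oop, np.cross(u, oop)], axis=1)
                coords[s + t] = (tmpl - tmpl[2]) @ (B @ A.T).T + c + r * u
            flat = coords.reshape(-1, 3)
            dmin = np.inf
            for i in range(s - 1, min(n - s + 1, n)):
                for j in range(i + 1, min(n - s + 1, n)):
                    d = np.linalg.norm(coords[i][:, None] - coords[j][None], axis=-1)
                    dmin = min(dmin, float(d.min()))
            if dmin >= 2.6:
                break
        residues = [Nucleotide("A", i + 1, seq[i], coords[i]) for i in range(n)]
        pairs = [(i, n - 1 - i) for i in range(s)]
    elif kind == "coil":
        chains = (spec.sequence or "G" * 8).split()
        residues = []
        for ci, seq in enumerate(chains):
            xyz = _coil_coords(seq, y_offset=15.0 * ci)
            cid = chr(ord("A") + ci)
            residues += [Nucleotide(cid, i + 1, seq[i], xyz[i]) for i in range(len(seq))]
        pairs = []
    elif kind == "two_register":
        seq, _lines = make_two_register_fixture()
        xyz = _coil_coords(seq)
        residues = [Nucleotide("A", i + 1, seq[i], xyz[i]) for i in range(len(seq))]
        pairs = []
    elif kind == "quadruplex_like":
        seq = spec.sequence or "GGGG"
        if set(seq) != {"G"}:
            raise ValueError("quadruplex_like fixture is all-G")
        # chain of W:H cis G-G pairs, each placed against the previous one
        bi, bj = make_ideal_pair("G", "G", "W", "H", "cis")
        # relative transform bi -> bj, applied repeatedly
        coords = [bi]
        ref, moved = bi.copy(), bj.copy()
        for _ in range(len(seq) - 1):
            Rt, tt = _rigid_fit(ref, moved)
            coords.append(coords[-1] @ Rt.T + tt)
        residues = [Nucleotide("A", i + 1, "G", coords[i]) for i in range(len(seq))]
        pairs = []  # pairs here are noncanonical (G-G WHc), not canonical
    else:
        raise ValueError(f"unsupported fixture kind {kind!r}")
    conf = CGConformation(residues)
    if spec.noise_sigma > 0:
        xyz = conf.coords() + rng.normal(0.0, spec.noise_sigma, (len(conf), 5, 3))
        conf = conf.with_coords(xyz)
    return conf, pairs


def _rigid_fit(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t with Y ≈ X @ R.T + t (least squares)."""
    xm, ym = X.reshape(-1, 3).mean(axis=0), Y.reshape(-1, 3).mean(axis=0)
    H = (X.reshape(-1, 3) - xm).T @ (Y.reshape(-1, 3) - ym)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, ym - R @ xm


def make_two_register_fixture(biased: bool = False) -> tuple[str, list[str]]:
    """A short sequence that can fold into two mutually exclusive hairpins.

    The middle C-run can pair either with the 5' G-run (register 1) or with
    the 3' G-run (register 2); the registers share residues but no pairs.
    With ``biased=True`` register 1 is one base pair longer than register 2,
    which makes it the energetically preferred fold in unrestrained runs —
    useful for demonstrating restraints that select the minority register.
    """
    if biased:
        seq = "GGGGGGAAAACCCCCCAAAGGGGG"
        line1 = "((((((....))))))" + "." * 8
        line2 = "." * 10 + "(((((" + "...." + ")))))"
    else:
        seq = "GGGGGAAAACCCCCAAAAGGGGG"
        line1 = "(((((....)))))" + "." * 9
        line2 = "." * 9 + "(((((....)))))"
    assert len(line1) == len(seq) and len(line2) == len(seq)
    return seq, [line1, line2]


def synth_reactivities(
    flags: Sequence[int],
    chain_lengths: Sequence[int],
    sigma: float = 0.0,
    seed: int = 0,
    na_fraction: float = 0.0,
) -> str:
    """Synthetic chemical-probing text emulating SHAPE/DMS-style profiles.

    Paired residues (flag 0) get reactivities near 0, unpaired (flag 1) near
    1, with Gaussian noise ``sigma`` and clamping to [0, 1]; a random
    ``na_fraction`` of residues is marked ``NA`` (unassigned).  Real probing
    data is noisier and reactivity is influenced by more than pairing; this
    generator captures only the paired/unpaired contrast the restraint uses.
    """
    flags = np.asarray(flags, dtype=float)
    if flags.size != sum(chain_lengths):
        raise ValueError("flags length must match total chain length")
    rng = np.random.default_rng(seed)
    vals = np.clip(flags + rng.normal(0.0, sigma, flags.size), 0.0, 1.0)
    na = rng.random(flags.size) < na_fraction
    toks = ["NA" if m else f"{v:.3f}" for v, m in zip(vals, na)]
    out, k = [], 0
    for ln in chain_lengths:
        out.append(",".join(toks[k:k + ln]))
        k += ln
    return " ".join(out)
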