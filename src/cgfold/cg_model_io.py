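"""Coarse-grained RNA data model and file I/O.

The model represents each nucleotide by five beads: the backbone phosphate
``P`` and sugar ``C4'``, plus three base atoms — the glycosidic nitrogen
(``N9`` for purines, ``N1`` for pyrimidines), ``C2``, and a third ring carbon
(``C6`` for purines, ``C4`` for pyrimidines).  Three base beads are the
minimum that pins both the position and the mutual orientation of a base,
which is what three-distance base-pair restraints require.

Coordinate files are read and written as PDB or PDBx/mmCIF (via gemmi);
trajectories use a self-describing plain-text dialect: a header of
``key = value`` lines terminated by a blank line, then one whitespace
delimited record per frame.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("cgfold")

PURINES = ("A", "G")
PYRIMIDINES = ("C", "U")
RNA_TYPES = ("A", "C", "G", "U")

PURINE_BEADS = ("P", "C4'", "N9", "C2", "C6")
PYRIMIDINE_BEADS = ("P", "C4'", "N1", "C2", "C4")

#: residue-name aliases accepted on input
_RNA_ALIASES = {
    "A": "A", "RA": "A", "ADE": "A",
    "C": "C", "RC": "C", "CYT": "C",
    "G": "G", "RG": "G", "GUA": "G",
    "U": "U", "RU": "U", "URA": "U", "URI": "U",
}
#: residue names silently skipped (non-RNA chains, solvent, ions, DNA)
_SKIP_NAMES = {
    "HOH", "WAT", "MG", "NA", "K", "CL", "ZN", "MN", "CA", "SO4", "PO4",
    "DA", "DC", "DG", "DT",
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_ELEMENT = {"P": "P", "C4'": "C", "N9": "N", "N1": "N", "C2": "C", "C6": "C", "C4": "C"}


def bead_names(res_type: str) -> tuple[str, ...]:
    """Bead-name tuple for a residue type (bijective per type)."""
    if res_type in PURINES:
        return PURINE_BEADS
    if res_type in PYRIMIDINES:
        return PYRIMIDINE_BEADS
    raise ValueError(f"unknown residue type {res_type!r}")


@dataclass
class Nucleotide:
    """One coarse-grained residue: 5 labeled beads."""

    chain_id: str
    res_number: int
    res_type: str
    beads: np.ndarray  # (5, 3) float, in bead_names(res_type) order

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.shape != (5, 3):
            raise ValueError(
                f"residue {self.chain_id}/{self.res_number} needs exactly 5 beads"
            )
        bead_names(self.res_type)  # validates type

    @property
    def bead_labels(self) -> tuple[str, ...]:
        return bead_names(self.res_type)


@dataclass
class CGConformation:
    """An ordered, chain-grouped list of nucleotides plus a frozen mask."""

    residues: list[Nucleotide]
    frozen_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.residues)
        if self.frozen_mask is None:
            self.frozen_mask = np.zeros(n, dtype=bool)
        self.frozen_mask = np.asarray(self.frozen_mask, dtype=bool)
        if self.frozen_mask.shape != (n,):
            raise ValueError("frozen_mask length must equal residue count")
        last: dict[str, int] = {}
        for r in self.residues:
            if r.chain_id in last and r.res_number <= last[r.chain_id]:
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {r.chain_id}"
                )
            last[r.chain_id] = r.res_number

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if not out or out[-1] != r.chain_id:
                out.append(r.chain_id)
        return out

    @property
    def sequences(self) -> dict[str, str]:
        seqs: dict[str, str] = {}
        for r in self.residues:
            seqs[r.chain_id] = seqs.get(r.chain_id, "") + r.res_type
        return seqs

    @property
    def sequence(self) -> str:
        """Concatenated sequence over all chains."""
        return "".join(r.res_type for r in self.residues)

    def coords(self) -> np.ndarray:
        """All bead coordinates as an (n_res, 5, 3) array (a copy)."""
        return np.stack([r.beads for r in self.residues]).astype(float)

    def with_coords(self, coords: np.ndarray) -> "CGConformation":
        """A new conformation with replaced coordinates, same topology."""
        coords = np.asarray(coords, dtype=float).reshape(len(self.residues), 5, 3)
        res = [
            Nucleotide(r.chain_id, r.res_number, r.res_type, c.copy())
            for r, c in zip(self.residues, coords)
        ]
        return CGConformation(res, self.frozen_mask.copy())

    def index_of(self, chain_id: str, res_number: int) -> int:
        for i, r in enumerate(self.residues):
            if r.chain_id == chain_id and r.res_number == res_number:
                return i
        raise KeyError(f"no residue {chain_id}/{res_number}")


@dataclass
class TrajectoryFrame:
    step: int
    replica: int
    temperature: float
    energy_total: float
    energy_terms: dict[str, float]
    coordinates: np.ndarray  # flat, 5 * n_res * 3

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).ravel()
        s = sum(self.energy_terms.values())
        if abs(s - self.energy_total) > 1e-9 * max(1.0, abs(self.energy_total)):
            raise ValueError(
                f"energy_total {self.energy_total} != sum of terms {s}"
            )


@dataclass
class Trajectory:
    """Headered frame sequence. Frames are kept sorted by (replica, step)."""

    header: dict[str, str]
    frames: list[TrajectoryFrame]

    def __post_init__(self) -> None:
        self.frames = sorted(self.frames, key=lambda f: (f.replica, f.step))

    @property
    def term_names(self) -> list[str]:
        fields = self.header["fields"].split()
        return fields[4 : fields.index("coordinates")]

    def replicas(self) -> dict[int, list[TrajectoryFrame]]:
        out: dict[int, list[TrajectoryFrame]] = {}
        for f in self.frames:
            out.setdefault(f.replica, []).append(f)
        return out


# ---------------------------------------------------------------------------
# sequence input
# ---------------------------------------------------------------------------

def read_sequence(path: str | Path) -> list[str]:
    """Read chain sequences from FASTA (one record per chain) or plain text
    (chains separated by whitespace)."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        chains = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        chains = text.split()
    chains = [c.upper().replace("T", "U") for c in chains]
    for c in chains:
        bad = set(c) - set(RNA_TYPES)
        if bad:
            raise ValueError(f"non-RNA letters in sequence: {sorted(bad)}")
    if not chains:
        raise ValueError(f"no sequence found in {path}")
    return chains


# ---------------------------------------------------------------------------
# structure I/O (PDB / PDBx-mmCIF via gemmi)
# ---------------------------------------------------------------------------

def _classify(name: str) -> str | None:
    name = name.strip().upper()
    if name in _RNA_ALIASES:
        return _RNA_ALIASES[name]
    if name in _SKIP_NAMES:
        return None
    raise ValueError(f"unknown residue type {name!r}")


def _gemmi_read(path: str | Path, format: str) -> gemmi.Structure:
    path = str(path)
    if format == "pdb":
        return gemmi.read_pdb(path)
    if format == "mmcif":
        return gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    if format == "auto":
        return gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
    raise ValueError(f"unknown format {format!r}")


def _model_to_conformation(model: gemmi.Model, path: str) -> CGConformation:
    residues: list[Nucleotide] = []
    for chain in model:
        for res in chain:
            try:
                rtype = _classify(res.name)
            except ValueError:
                raise ValueError(
                    f"{path}: unknown residue type {res.name!r} "
                    f"at {chain.name}/{res.seqid.num}"
                )
            if rtype is None:
                logger.warning(
                    "%s: skipping non-RNA residue %s %s/%s",
                    path, res.name, chain.name, res.seqid.num,
                )
                continue
            labels = bead_names(rtype)
            pts = np.full((5, 3), np.nan)
            seen: set[str] = set()
            for atom in res:
                nm = atom.name.strip().replace("*", "'")
                if nm in labels and nm not in seen:  # first altloc wins
                    if atom.altloc not in ("", "\0", "A"):
                        logger.warning(
                            "%s: ignoring altloc %r of %s in %s/%s",
                            path, atom.altloc, nm, chain.name, res.seqid.num,
                        )
                        continue
                    i = labels.index(nm)
                    pts[i] = (atom.pos.x, atom.pos.y, atom.pos.z)
                    seen.add(nm)
            missing = [l for l in labels if l not in seen]
            if missing:
                raise ValueError(
                    f"{path}: residue {chain.name}/{res.seqid.num} ({rtype}) "
                    f"missing atoms {missing}"
                )
            residues.append(Nucleotide(chain.name, res.seqid.num, rtype, pts))
    if not residues:
        raise ValueError(f"{path}: no RNA residues found")
    return CGConformation(residues)


def read_models(path: str | Path, format: str = "auto") -> list[CGConformation]:
    """Read every model in a (possibly multi-model) file."""
    st = _gemmi_read(path, format)
    st.setup_entities()
    return [_model_to_conformation(m, str(path)) for m in st]


def read_structure(path: str | Path, format: str = "auto") -> CGConformation:
    """Read the first model of a PDB or PDBx/mmCIF file as a conformation."""
    models = read_models(path, format)
    if len(models) > 1:
        logger.warning("%s: %d models present, using the first", path, len(models))
    return models[0]


def _conformation_to_gemmi(conf: CGConformation, name: str = "cgfold") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    serial = 1
    for cid in conf.chain_ids:
        chain = gemmi.Chain(cid)
        for r in conf.residues:
            if r.chain_id != cid:
                continue
            res = gemmi.Residue()
            res.name = r.res_type
            res.seqid = gemmi.SeqId(r.res_number, " ")
            for label, xyz in zip(r.bead_labels, r.beads):
                atom = gemmi.Atom()
                atom.name = label
                atom.element = gemmi.Element(_ELEMENT[label])
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = 0.0
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(conf: CGConformation, path: str | Path, format: str = "pdb") -> None:
    """Write a conformation as PDB or PDBx/mmCIF."""
    st = _conformation_to_gemmi(conf)
    path = str(path)
    if format == "pdb":
        st.write_pdb(path)
    elif format == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def make_header(
    sequence_chains: Sequence[str],
    chain_ids: Sequence[str],
    term_names: Sequence[str],
    n_replicas: int,
    seed: int,
    **params: object,
) -> dict[str, str]:
    """Build a trajectory header describing the per-frame record layout."""
    fields = ["step", "replica", "temperature", "energy_total", *term_names,
              "coordinates"]
    header = {
        "sequence": " ".join(sequence_chains),
        "chains": " ".join(chain_ids),
        "beads": "P C4' N9|N1 C2 C6|C4",
        "fields": " ".join(fields),
        "n_replicas": str(n_replicas),
        "seed": str(seed),
    }
    for k, v in params.items():
        header[k] = str(v)
    return header


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the headered text trajectory; lossless for float64 values."""
    fields = traj.header["fields"].split()
    terms = traj.term_names
    n_res = sum(len(c) for c in traj.header["sequence"].split())
    with open(path, "w") as fh:
        for k, v in traj.header.items():
            fh.write(f"{k} = {v}\n")
        fh.write("\n")
        for f in traj.frames:
            if f.coordinates.size != 5 * n_res * 3:
                raise ValueError(
                    f"frame (replica {f.replica}, step {f.step}) has "
                    f"{f.coordinates.size} coordinates, expected {5 * n_res * 3}"
                )
            rec = [str(f.step), str(f.replica), _fmt(f.temperature),
                   _fmt(f.energy_total)]
            for t in terms:
                rec.append(_fmt(f.energy_terms.get(t, 0.0)))
            rec.extend(_fmt(x) for x in f.coordinates)
            fh.write(" ".join(rec) + "\n")
    # sanity: layout advertised in header matches what we wrote
    if fields[: 4 + len(terms)] != ["step", "replica", "temperature",
                                    "energy_total", *terms]:
        raise ValueError("header field list inconsistent with frame records")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    header: dict[str, str] = {}
    frames: list[TrajectoryFrame] = []
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip() == "":
                break
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
            k, _, v = line.partition("=")
            header[k.strip()] = v.strip()
        if "fields" not in header:
            raise ValueError(f"{path}: header missing 'fields'")
        fields = header["fields"].split()
        terms = fields[4 : fields.index("coordinates")]
        n_res = sum(len(c) for c in header["sequence"].split())
        want = 4 + len(terms) + 5 * n_res * 3
        for line in fh:
            lineno += 1
            tok = line.split()
            if not tok:
                continue
            if len(tok) != want:
                raise ValueError(
                    f"{path}:{lineno}: record has {len(tok)} fields, expected {want}"
                )
            frames.append(
                TrajectoryFrame(
                    step=int(tok[0]),
                    replica=int(tok[1]),
                    temperature=float(tok[2]),
                    energy_total=float(tok[3]),
                    energy_terms={t: float(x) for t, x in zip(terms, tok[4:4 + len(terms)])},
                    coordinates=np.array([float(x) for x in tok[4 + len(terms):]]),
                )
            )
    return Trajectory(header, frames)


def frame_to_conformation(traj: Trajectory, frame: TrajectoryFrame) -> CGConformation:
    """Rebuild a conformation from a frame using the trajectory header."""
    chains = traj.header["sequence"].split()
    ids = traj.header["chains"].split()
    residues: list[Nucleotide] = []
    coords = frame.coordinates.reshape(-1, 5, 3)
    k = 0
    for cid, seq in zip(ids, chains):
        for j, t in enumerate(seq):
            residues.append(Nucleotide(cid, j + 1, t, coords[k]))
            k += 1
    return CGConformation(residues)
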