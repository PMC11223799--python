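"""Parsing and compilation of all restraint inputs.

Four kinds of user input steer a simulation:

* secondary structure in dot-bracket notation (one line per non-nested helix
  set, so pseudoknots are multi-line), with ``x`` marking residues whose
  Watson-Crick edge should stay unpaired;
* noncanonical base-pair records ``chain;num;type;chain;num;type;EEo`` in
  Leontis-Westhof nomenclature (edges W/H/S, orientation c/t);
* per-residue chemical-probing reactivities in [0, 1], comma-separated,
  chains separated by spaces, ``NA`` for unassigned residues;
* raw pairwise distance restraints (``SLOPE``/``WELL`` lines).

Every base-pair restraint compiles to three atom-atom distance restraints
between the three base beads of the two residues; hard restraints become
slope penalties (grow linearly outside the distance window), soft restraints
become well bonuses (a fixed reward inside the window, no penalty outside).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cg_model_io import PURINES, RNA_TYPES, bead_names

# Target base-bead distances (N-N, C2-C2, C4|C6-C4|C6, in Angstrom) of
# idealized pair geometries; measured once from the constructed ideal pairs
# (see fixtures.make_ideal_pair).  All canonical cWW combinations share one
# geometry because the idealized purine/pyrimidine templates do.
PAIR_GEOMETRY: dict[tuple[str, str, str, str, str], tuple[float, float, float]] = {
    ("A", "U", "W", "W", "cis"): (8.3962, 5.4340, 4.0548),
    ("G", "C", "W", "W", "cis"): (8.3962, 5.4340, 4.0548),
    ("G", "U", "W", "W", "cis"): (8.3962, 5.4340, 4.0548),
    ("G", "G", "W", "H", "cis"): (8.2868, 6.6105, 3.6473),
    ("A", "G", "H", "S", "trans"): (6.4165, 5.5255, 5.5094),
}

CANONICAL_CWW = (8.3962, 5.4340, 4.0548)

#: default half-width of the restraint distance window, Angstrom
DEFAULT_TOLERANCE = 0.5
#: default slope weight / well depth, energy units per restraint
DEFAULT_WEIGHT = 1.0
#: default energy penalty per detected canonical pair on an 'x' residue
DEFAULT_EXCLUSION_PENALTY = 2.0
#: unassigned-reactivity marker (negative sentinels are unusable: any value
#: below 0 is clamped to 0 by the stated input rules)
NA_TOKEN = "NA"

EDGES = ("W", "H", "S")
ORIENTATIONS = {"c": "cis", "t": "trans"}


def lookup_pair_geometry(
    type_i: str, type_j: str, edge_i: str, edge_j: str, orientation: str,
    table: dict | None = None,
) -> tuple[float, float, float]:
    """Geometry-table lookup, symmetric under swapping the two residues."""
    table = PAIR_GEOMETRY if table is None else table
    key = (type_i, type_j, edge_i, edge_j, orientation)
    if key in table:
        return table[key]
    rkey = (type_j, type_i, edge_j, edge_i, orientation)
    if rkey in table:
        return table[rkey]
    fams = sorted({f"{a}{b} {e1}{e2}{o[0]}" for a, b, e1, e2, o in table})
    raise KeyError(
        f"no pair geometry for {type_i}-{type_j} {edge_i}{edge_j} {orientation}; "
        f"supported families: {', '.join(fams)}"
    )


def load_pair_geometry(path: str | Path) -> dict:
    """Extend the shipped geometry table from a config file.

    Each non-comment line: ``type_i type_j edge_i edge_j cis|trans d1 d2 d3``.
    """
    table = dict(PAIR_GEOMETRY)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        tok = line.split()
        if len(tok) != 8:
            raise ValueError(f"{path}:{lineno}: expected 8 fields, got {len(tok)}")
        ti, tj, ei, ej, o = tok[0], tok[1], tok[2], tok[3], tok[4]
        table[(ti, tj, ei, ej, o)] = tuple(float(x) for x in tok[5:])
    return table


# ---------------------------------------------------------------------------
# chain addressing
# ---------------------------------------------------------------------------

def chain_offsets(chains: dict[str, str]) -> dict[str, int]:
    out, k = {}, 0
    for cid, seq in chains.items():
        out[cid] = k
        k += len(seq)
    return out


def global_index(chains: dict[str, str], chain_id: str, res_number: int) -> int:
    """Author (1-based) residue number -> global 0-based index."""
    if chain_id not in chains:
        raise KeyError(f"unknown chain {chain_id!r}")
    if not 1 <= res_number <= len(chains[chain_id]):
        raise IndexError(f"residue {res_number} out of range for chain {chain_id}")
    return chain_offsets(chains)[chain_id] + res_number - 1


def concat_sequence(chains: dict[str, str]) -> str:
    return "".join(chains.values())


# ---------------------------------------------------------------------------
# dot-bracket secondary structure
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructureSpec:
    lines: list[str]
    pairs: list[tuple[int, int]]         # 0-based global indices, i < j
    excluded: set[int] = field(default_factory=set)
    pairs_per_line: list[list[tuple[int, int]]] = field(default_factory=list)


def parse_dotbracket(lines: str | list[str], sequence: str) -> SecondaryStructureSpec:
    """Parse one or more dot-bracket lines over the full sequence.

    Each line must be individually balanced (pairs within a line are nested);
    pairs from different lines may cross, which is how pseudoknots are given.
    ``x`` marks residues excluded from canonical pairing.
    """
    sequence = sequence.replace(" ", "")
    if isinstance(lines, str):
        lines = [l for l in lines.splitlines() if l.strip()]
    lines = [l.replace(" ", "") for l in lines]
    n = len(sequence)
    all_pairs: list[tuple[int, int]] = []
    per_line: list[list[tuple[int, int]]] = []
    excluded: set[int] = set()
    for li, line in enumerate(lines):
        if len(line) != n:
            raise ValueError(
                f"structure line {li + 1} has length {len(line)}, sequence has {n}"
            )
        bad = set(line) - set(".()x")
        if bad:
            raise ValueError(f"structure line {li + 1}: invalid characters {sorted(bad)}")
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for pos, ch in enumerate(line):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValueError(
                        f"structure line {li + 1}: unbalanced ')' at position {pos + 1}"
                    )
                pairs.append((stack.pop(), pos))
            elif ch == "x":
                excluded.add(pos)
        if stack:
            raise ValueError(
                f"structure line {li + 1}: unbalanced '(' at position {stack[-1] + 1}"
            )
        pairs.sort()
        per_line.append(pairs)
        all_pairs.extend(pairs)
    for i, j in all_pairs:
        for p in (i, j):
            if p in excluded:
                raise ValueError(
                    f"position {p + 1} marked 'x' but paired in another line"
                )
    return SecondaryStructureSpec(lines, sorted(all_pairs), excluded, per_line)


def serialize_dotbracket(spec: SecondaryStructureSpec) -> str:
    return "\n".join(spec.lines)


# ---------------------------------------------------------------------------
# noncanonical / canonical base-pair records
# ---------------------------------------------------------------------------

@dataclass
class BasePairRestraint:
    chain_i: str
    res_i: int
    type_i: str
    chain_j: str
    res_j: int
    type_j: str
    edge_i: str
    edge_j: str
    orientation: str            # "cis" | "trans"
    mode: str = "hard"          # "hard" | "soft"

    def __post_init__(self) -> None:
        if self.edge_i not in EDGES or self.edge_j not in EDGES:
            raise ValueError(f"edges must be in {EDGES}")
        if self.orientation not in ("cis", "trans"):
            raise ValueError("orientation must be 'cis' or 'trans'")
        for t in (self.type_i, self.type_j):
            if t not in RNA_TYPES:
                raise ValueError(f"unknown residue type {t!r}")

    @property
    def family(self) -> str:
        return f"{self.edge_i}{self.edge_j}{self.orientation[0]}"


def parse_noncanonical_line(
    line: str, chains: dict[str, str], mode: str = "hard"
) -> BasePairRestraint:
    """Parse one ``chain;num;type;chain;num;type;EEo`` record.

    The residue types in the record are cross-checked against the sequence at
    the addressed positions.
    """
    tok = [t.strip() for t in line.strip().split(";")]
    if len(tok) != 7:
        raise ValueError(f"expected 7 ';'-separated fields, got {len(tok)}: {line!r}")
    ci, ni, ti, cj, nj, tj, fam = tok
    ni, nj = int(ni), int(nj)
    if len(fam) != 3 or fam[0] not in EDGES or fam[1] not in EDGES \
            or fam[2] not in ORIENTATIONS:
        raise ValueError(
            f"pair type {fam!r} must be two edge letters (W/H/S) plus c or t"
        )
    for cid, num, typ in ((ci, ni, ti), (cj, nj, tj)):
        gi = global_index(chains, cid, num)
        actual = concat_sequence(chains)[gi]
        if actual != typ.upper():
            raise ValueError(
                f"residue {cid}/{num} is {actual}, record says {typ}"
            )
    return BasePairRestraint(
        ci, ni, ti.upper(), cj, nj, tj.upper(),
        fam[0], fam[1], ORIENTATIONS[fam[2]], mode,
    )


def serialize_noncanonical(r: BasePairRestraint) -> str:
    return (f"{r.chain_i};{r.res_i};{r.type_i};{r.chain_j};{r.res_j};{r.type_j};"
            f"{r.edge_i}{r.edge_j}{r.orientation[0]}")


def parse_noncanonical_file(
    text: str, chains: dict[str, str], mode: str = "hard"
) -> list[BasePairRestraint]:
    out = []
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if line:
            out.append(parse_noncanonical_line(line, chains, mode))
    return out


# ---------------------------------------------------------------------------
# distance restraints
# ---------------------------------------------------------------------------

@dataclass
class DistanceRestraint:
    res_a: int                  # global 0-based residue index
    bead_a: str
    res_b: int
    bead_b: str
    d_min: float
    d_max: float
    weight: float
    form: str                   # "slope" | "well"

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.form not in ("slope", "well"):
            raise ValueError("form must be 'slope' or 'well'")


def slope_energy(d: float, r: DistanceRestraint) -> float:
    """Hard-restraint penalty: zero inside [d_min, d_max], linear outside."""
    if r.form != "slope":
        raise ValueError("slope_energy needs a slope restraint")
    if d > r.d_max:
        return r.weight * (d - r.d_max)
    if d < r.d_min:
        return r.weight * (r.d_min - d)
    return 0.0


def well_energy(d: float, r: DistanceRestraint) -> float:
    """Soft-restraint bonus: -weight inside [d_min, d_max], zero outside."""
    if r.form != "well":
        raise ValueError("well_energy needs a well restraint")
    return -r.weight if r.d_min <= d <= r.d_max else 0.0


def compile_pair(
    restraint: BasePairRestraint,
    chains: dict[str, str],
    geometry: dict | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    weight: float = DEFAULT_WEIGHT,
) -> list[DistanceRestraint]:
    """Translate one base-pair restraint into three distance restraints.

    The three restrained atom pairs are the three base beads of each residue
    (glycosidic N against glycosidic N, C2 against C2, C4|C6 against C4|C6);
    three non-collinear anchors pin both the separation and the mutual
    orientation of the bases.  The window brackets the family's ideal target
    distances by ``tolerance``.
    """
    targets = lookup_pair_geometry(
        restraint.type_i, restraint.type_j,
        restraint.edge_i, restraint.edge_j, restraint.orientation,
        geometry,
    )
    gi = global_index(chains, restraint.chain_i, restraint.res_i)
    gj = global_index(chains, restraint.chain_j, restraint.res_j)
    names_i = bead_names(restraint.type_i)
    names_j = bead_names(restraint.type_j)
    form = "slope" if restraint.mode == "hard" else "well"
    out = []
    for k, t in zip((2, 3, 4), targets):
        out.append(
            DistanceRestraint(
                gi, names_i[k], gj, names_j[k],
                t - tolerance, t + tolerance, weight, form,
            )
        )
    return out


def compile_secondary_structure(
    spec: SecondaryStructureSpec,
    mode: str,
    chains: dict[str, str],
    geometry: dict | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    weight: float = DEFAULT_WEIGHT,
) -> tuple[list[DistanceRestraint], set[int]]:
    """Compile a dot-bracket spec into canonical-cWW distance restraints.

    In hard mode a residue may have only one partner across all lines:
    restraining one residue to several different partners in a hard manner
    makes the sampler attempt to bring all pairing partners together at once,
    producing overlapping pairs and distorted structures.  Soft mode permits
    alternative (mutually exclusive) partners.
    """
    if mode not in ("hard", "soft"):
        raise ValueError("mode must be 'hard' or 'soft'")
    if mode == "hard":
        seen: dict[int, int] = {}
        for i, j in spec.pairs:
            for a, b in ((i, j), (j, i)):
                if a in seen and seen[a] != b:
                    raise ValueError(
                        f"hard restraints give residue {a + 1} conflicting partners "
                        f"{seen[a] + 1} and {b + 1}; restraining one residue to "
                        "several different partners in a hard manner forces all "
                        "partners together (use soft mode for alternatives)"
                    )
                seen[a] = b
    seq = concat_sequence(chains)
    restraints: list[DistanceRestraint] = []
    for i, j in spec.pairs:
        ti, tj = seq[i], seq[j]
        targets = lookup_pair_geometry(ti, tj, "W", "W", "cis", geometry)
        form = "slope" if mode == "hard" else "well"
        names_i, names_j = bead_names(ti), bead_names(tj)
        for k, t in zip((2, 3, 4), targets):
            restraints.append(
                DistanceRestraint(i, names_i[k], j, names_j[k],
                                  t - tolerance, t + tolerance, weight, form)
            )
    return restraints, set(spec.excluded)


def parse_distance_restraints(text: str, chains: dict[str, str]) -> list[DistanceRestraint]:
    """Parse ``SLOPE chain/res/bead chain/res/bead d_min d_max weight`` lines
    (and ``WELL`` ditto)."""
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        tok = line.split()
        if len(tok) != 6:
            raise ValueError(f"line {lineno}: expected 6 fields, got {len(tok)}")
        form = {"SLOPE": "slope", "WELL": "well"}.get(tok[0].upper())
        if form is None:
            raise ValueError(f"line {lineno}: unknown restraint kind {tok[0]!r}")
        addr = []
        for a in tok[1:3]:
            cid, num, bead = a.split("/")
            addr.append((global_index(chains, cid, int(num)), bead))
        out.append(
            DistanceRestraint(addr[0][0], addr[0][1], addr[1][0], addr[1][1],
                              float(tok[3]), float(tok[4]), float(tok[5]), form)
        )
    return out


def serialize_distance_restraint(r: DistanceRestraint, chains: dict[str, str]) -> str:
    offs = chain_offsets(chains)
    def addr(g, bead):
        for cid, seq in chains.items():
            if offs[cid] <= g < offs[cid] + len(seq):
                return f"{cid}/{g - offs[cid] + 1}/{bead}"
        raise IndexError(g)
    kind = "SLOPE" if r.form == "slope" else "WELL"
    return (f"{kind} {addr(r.res_a, r.bead_a)} {addr(r.res_b, r.bead_b)} "
            f"{r.d_min:g} {r.d_max:g} {r.weight:g}")


# ---------------------------------------------------------------------------
# chemical-probing reactivities
# ---------------------------------------------------------------------------

@dataclass
class ReactivityProfile:
    """Per-residue reactivities in [0, 1]; NaN marks unassigned residues."""

    values: np.ndarray
    chain_lengths: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != sum(self.chain_lengths):
            raise ValueError("values length must equal total chain length")
        assigned = self.values[~np.isnan(self.values)]
        if assigned.size and (assigned.min() < 0 or assigned.max() > 1):
            raise ValueError("assigned reactivities must lie in [0, 1]")

    @property
    def assigned(self) -> np.ndarray:
        return ~np.isnan(self.values)


def parse_reactivities(text: str, chains: dict[str, str]) -> ReactivityProfile:
    """Parse comma-separated reactivities, one space-separated block per chain.

    Values below 0 are interpreted as 0 and values above 1 as 1; ``NA`` marks
    a residue with no assigned reactivity (it is skipped by the probing
    score).
    """
    blocks = text.split()
    ids = list(chains)
    if len(blocks) != len(ids):
        raise ValueError(
            f"{len(blocks)} reactivity blocks for {len(ids)} chains"
        )
    values: list[float] = []
    lengths: list[int] = []
    for cid, block in zip(ids, blocks):
        toks = block.split(",")
        if len(toks) != len(chains[cid]):
            raise ValueError(
                f"chain {cid}: {len(toks)} reactivities for "
                f"{len(chains[cid])} residues"
            )
        for t in toks:
            if t.strip().upper() == NA_TOKEN:
                values.append(math.nan)
            else:
                values.append(min(1.0, max(0.0, float(t))))
        lengths.append(len(toks))
    return ReactivityProfile(np.array(values), lengths)


def serialize_reactivities(profile: ReactivityProfile) -> str:
    toks = [NA_TOKEN if math.isnan(v) else f"{v:.17g}" for v in profile.values]
    out, k = [], 0
    for ln in profile.chain_lengths:
        out.append(",".join(toks[k:k + ln]))
        k += ln
    return " ".join(out)


def probing_score(paired_flags, profile: ReactivityProfile) -> float:
    """Squared error between the pairing pattern and the probing profile.

    ``paired_flags`` holds 0 for residues in a detected canonical pair and 1
    for unpaired residues; residues without an assigned reactivity contribute
    nothing.
    """
    flags = np.asarray(paired_flags, dtype=float)
    if flags.size != profile.values.size:
        raise ValueError("flags length must equal residue count")
    m = profile.assigned
    diff = flags[m] - profile.values[m]
    return float(diff @ diff)


# ---------------------------------------------------------------------------
# the compiled bundle
# ---------------------------------------------------------------------------

@dataclass
class RestraintSet:
    """Everything the energy function needs to score restraints."""

    restraints: list[DistanceRestraint] = field(default_factory=list)
    excluded: set[int] = field(default_factory=set)
    reactivity: ReactivityProfile | None = None
    frozen_mask: np.ndarray | None = None
    exclusion_penalty: float = DEFAULT_EXCLUSION_PENALTY

    def slope_restraints(self) -> list[DistanceRestraint]:
        return [r for r in self.restraints if r.form == "slope"]

    def well_restraints(self) -> list[DistanceRestraint]:
        return [r for r in self.restraints if r.form == "well"]
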