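"""Surrogate coarse-grained energy function and geometric pair detection.

The scoring context in which all restraint terms act.  The potential is a
deliberately simple, fully documented surrogate — chain connectivity,
excluded volume, a funnel-shaped canonical-pair attraction, and a stacking
bonus — chosen so that sampling, restraints and trajectory analysis are
exercisable end to end.  Every functional form and constant lives in
:class:`EnergyModel`; the evaluation context is a pluggable interface (any
object with an ``evaluate(coords)`` method can stand in), so a
knowledge-based parameter set can drop in later.

Secondary structure is detected geometrically: a candidate pair must be
complementary (AU, GC or GU), separated by at least 3 residues within a
chain, and have all three base-bead distances within tolerance of the ideal
cWW targets; candidates are resolved to at most one partner per residue,
greedily by total deviation.  Detection is therefore pseudoknot-capable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cg_model_io import CGConformation, bead_names
from .restraints import CANONICAL_CWW, RestraintSet, probing_score

_COMPLEMENTARY = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                  ("G", "U"), ("U", "G")}

try:  # optional JIT for the O(n^2) excluded-volume loop
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _ev_sum(xyz, mask, radius):  # pragma: no cover - thin kernel
        nb = xyz.shape[0]
        acc = 0.0
        r2 = radius * radius
        for i in range(nb):
            xi, yi, zi = xyz[i, 0], xyz[i, 1], xyz[i, 2]
            for j in range(i + 1, nb):
                if not mask[i, j]:
                    continue
                dx = xi - xyz[j, 0]
                dy = yi - xyz[j, 1]
                dz = zi - xyz[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < r2:
                    pen = radius - np.sqrt(d2)
                    acc += pen * pen
        return acc

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _ev_sum(xyz, mask, radius):
        sq = np.einsum("ij,ij->i", xyz, xyz)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (xyz @ xyz.T)
        close = (d2 < radius ** 2) & mask
        if not close.any():
            return 0.0
        pen = radius - np.sqrt(np.maximum(d2[close], 0.0))
        return float((pen ** 2).sum())

#: idealized intra-residue bead-link targets (Angstrom), measured from the
#: bead templates: P-C4', C4'-N, N-C2, C2-C4|C6
_INTRA_TARGETS = {
    "purine": (2.0, 2.4, 3.7272, 2.3902),
    "pyrimidine": (2.0, 2.4, 1.38, 2.3902),
}


@dataclass
class EnergyModel:
    """All tunable constants of the surrogate potential (energy units are
    arbitrary; the Monte Carlo temperature factor is expressed in them)."""

    bond_k: float = 5.0            # intra-residue harmonic constant, per A^2
    tether_lo: float = 3.0         # chain tether flat window, A
    tether_hi: float = 7.5
    tether_k: float = 5.0          # harmonic constant outside the window
    ev_radius: float = 2.5         # excluded-volume contact radius, A
    ev_k: float = 10.0             # quadratic clash penalty, per A^2
    pair_depth: float = 3.0        # canonical-pair well depth, energy units
    pair_tolerance: float = 1.0    # detection tolerance per base-bead distance, A
    funnel_inner: float = 3.0      # summed deviation with full attraction, A
    funnel_range: float = 12.0     # summed deviation where attraction ends, A
    stack_depth: float = 1.0       # stacking bonus, energy units
    stack_lo: float = 2.5          # base-centroid stacking window, A
    stack_hi: float = 6.5
    stack_shoulder: float = 1.5    # linear decay width outside the window, A
    coop_depth: float = 2.0        # helix cooperativity: bonus per adjacent
                                   # pair of formed pairs (i,j),(i+1,j-1)
    probing_weight: float = 1.0    # weight of the chemical-probing score

    def __post_init__(self) -> None:
        for name in ("bond_k", "tether_k", "ev_k", "pair_depth", "stack_depth",
                     "probing_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.funnel_inner < self.funnel_range:
            raise ValueError("funnel_inner must be < funnel_range")

    def to_dict(self) -> dict:
        return asdict(self)


def load_energy_model(path) -> EnergyModel:
    """Read energy-model parameters from a ``key = value`` config file.

    ``[section]`` headers and ``#`` comments are allowed and ignored; keys
    must be :class:`EnergyModel` field names.
    """
    from pathlib import Path

    kwargs: dict[str, float] = {}
    valid = set(EnergyModel.__dataclass_fields__)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line or (line.startswith("[") and line.endswith("]")):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        k, _, v = line.partition("=")
        k = k.strip()
        if k not in valid:
            raise ValueError(f"{path}:{lineno}: unknown parameter {k!r}")
        kwargs[k] = float(v)
    return EnergyModel(**kwargs)


@dataclass
class PairingState:
    """Canonical pairing detected from 3D coordinates."""

    pairs: list[tuple[int, int]]
    flags: np.ndarray              # per residue: 0 = paired, 1 = unpaired
    dotbracket: list[str] = field(default_factory=list)


def _layer_dotbracket(pairs: list[tuple[int, int]], n: int) -> list[str]:
    """Assign pairs to bracket layers (lines) by greedy graph coloring so that
    pairs within one line never cross."""
    layers: list[list[tuple[int, int]]] = []
    for i, j in sorted(pairs):
        for layer in layers:
            if all(not (a < i < b < j or i < a < j < b) for a, b in layer):
                layer.append((i, j))
                break
        else:
            layers.append([(i, j)])
    lines = []
    for layer in layers:
        s = ["."] * n
        for i, j in layer:
            s[i], s[j] = "(", ")"
        lines.append("".join(s))
    return lines or ["." * n]


class EnergyContext:
    """Precompiled evaluation context for one sequence + restraint set.

    Builds flat index arrays once so that each energy evaluation is a handful
    of vectorized operations; the Monte Carlo engine calls
    :meth:`evaluate` for every proposed move.
    """

    TERMS = ("bond", "excluded_volume", "pairing", "cooperativity", "stacking",
             "restraint_slope", "restraint_well", "exclusion", "probing")

    def __init__(
        self,
        chains: dict[str, str],
        model: EnergyModel | None = None,
        restraints: RestraintSet | None = None,
    ) -> None:
        self.chains = chains
        self.model = model or EnergyModel()
        self.restraints = restraints or RestraintSet()
        seq = "".join(chains.values())
        self.sequence = seq
        n = len(seq)
        self.n_res = n
        chain_of = np.concatenate(
            [np.full(len(s), k) for k, s in enumerate(chains.values())]
        )
        self.chain_of = chain_of

        # intra-residue bead links
        ia, ib, t0 = [], [], []
        for i, t in enumerate(seq):
            cls = "purine" if t in "AG" else "pyrimidine"
            for (a, b), d0 in zip(((0, 1), (1, 2), (2, 3), (3, 4)),
                                  _INTRA_TARGETS[cls]):
                ia.append(5 * i + a)
                ib.append(5 * i + b)
                t0.append(d0)
        self._bond_i = np.array(ia)
        self._bond_j = np.array(ib)
        self._bond_t = np.array(t0)

        # inter-residue chain tether C4'(i) - P(i+1)
        link = np.nonzero((chain_of[:-1] == chain_of[1:]))[0]
        self._teth_i = 5 * link + 1
        self._teth_j = 5 * (link + 1) + 0
        self._stack_pairs = link  # same consecutive pairs used for stacking

        # excluded volume: all bead pairs from different residues, except the
        # chain-tether pair itself; evaluated on the full square distance
        # matrix (one small matmul) against this upper-triangular mask
        nb = 5 * n
        res_of = np.arange(nb) // 5
        mask = (res_of[:, None] != res_of[None, :]) & np.triu(
            np.ones((nb, nb), dtype=bool), k=1
        )
        mask[self._teth_i, self._teth_j] = False
        mask[self._teth_j, self._teth_i] = False
        self._ev_mask = mask

        # canonical-pair candidates
        ci, cj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (seq[i], seq[j]) not in _COMPLEMENTARY:
                    continue
                if chain_of[i] == chain_of[j] and j - i < 3:
                    continue
                ci.append(i)
                cj.append(j)
        self._cand_i = np.array(ci, dtype=int)
        self._cand_j = np.array(cj, dtype=int)
        self._cand_bi = (5 * self._cand_i[:, None] + np.array([2, 3, 4]))
        self._cand_bj = (5 * self._cand_j[:, None] + np.array([2, 3, 4]))
        self._cww = np.array(CANONICAL_CWW)

        # compiled distance restraints
        si, sj, slo, shi, sw = [], [], [], [], []
        wi, wj, wlo, whi, ww = [], [], [], [], []
        for r in self.restraints.restraints:
            a = self._bead_flat(r.res_a, r.bead_a)
            b = self._bead_flat(r.res_b, r.bead_b)
            if r.form == "slope":
                si.append(a); sj.append(b)
                slo.append(r.d_min); shi.append(r.d_max); sw.append(r.weight)
            else:
                wi.append(a); wj.append(b)
                wlo.append(r.d_min); whi.append(r.d_max); ww.append(r.weight)
        self._sl = tuple(np.array(x) for x in (si, sj, slo, shi, sw))
        self._we = tuple(np.array(x) for x in (wi, wj, wlo, whi, ww))

        self._excluded = np.array(sorted(self.restraints.excluded), dtype=int)

        # fused gather for every fixed bead-bead distance (bonds, tether,
        # slope and well restraints) — one fancy index per evaluation
        self._gath_i = np.concatenate(
            [self._bond_i, self._teth_i, self._sl[0], self._we[0]]
        ).astype(int)
        self._gath_j = np.concatenate(
            [self._bond_j, self._teth_j, self._sl[1], self._we[1]]
        ).astype(int)
        nb_, nt_, ns_ = len(self._bond_i), len(self._teth_i), len(si)
        self._sec = (nb_, nb_ + nt_, nb_ + nt_ + ns_)
        # plain-python candidate lists for the matching loop
        self._ci_list = self._cand_i.tolist()
        self._cj_list = self._cand_j.tolist()

    def _bead_flat(self, res: int, bead: str) -> int:
        if not 0 <= res < self.n_res:
            raise IndexError(f"restraint addresses nonexistent residue {res}")
        names = bead_names(self.sequence[res])
        if bead not in names:
            raise KeyError(
                f"residue {res} ({self.sequence[res]}) has no bead {bead!r}"
            )
        return 5 * res + names.index(bead)

    # -- pairing ----------------------------------------------------------

    def _candidate_distances(self, xyz: np.ndarray) -> np.ndarray:
        d = xyz[self._cand_bi] - xyz[self._cand_bj]
        return np.sqrt(np.einsum("ijk,ijk->ij", d, d))

    def _greedy_match(self, order, eligible) -> list[int]:
        """One-partner-per-residue matching; candidates taken in the given
        order (ascending total deviation, ties resolved by lower index pair
        since the candidate list is built in lexicographic order and the sort
        is stable)."""
        ci, cj = self._ci_list, self._cj_list
        used = [False] * self.n_res
        chosen = []
        for k in order:
            if not eligible[k]:
                continue
            i, j = ci[k], cj[k]
            if used[i] or used[j]:
                continue
            used[i] = used[j] = True
            chosen.append(k)
        return chosen

    def detect(self, coords: np.ndarray) -> PairingState:
        """Contracted geometric detection at the model's pair tolerance."""
        xyz = coords.reshape(-1, 3)
        flags = np.ones(self.n_res)
        if self._cand_i.size == 0:
            return PairingState([], flags, ["." * self.n_res])
        dist = self._candidate_distances(xyz)
        dev = np.abs(dist - self._cww)
        ok = (dev <= self.model.pair_tolerance).all(axis=1)
        D = dev.sum(axis=1)
        order = np.argsort(D, kind="stable").tolist()
        chosen = self._greedy_match(order, ok.tolist())
        pairs = [(int(self._cand_i[k]), int(self._cand_j[k])) for k in chosen]
        pairs.sort()
        for i, j in pairs:
            flags[i] = flags[j] = 0.0
        return PairingState(pairs, flags, _layer_dotbracket(pairs, self.n_res))

    # -- evaluation -------------------------------------------------------

    def evaluate(self, coords: np.ndarray) -> tuple[float, dict[str, float]]:
        """Total energy and per-term breakdown for bead coordinates
        (n_res, 5, 3)."""
        m = self.model
        xyz = coords.reshape(-1, 3)
        terms = dict.fromkeys(self.TERMS, 0.0)

        # every fixed bead-bead distance in one gather
        diff = xyz[self._gath_i] - xyz[self._gath_j]
        dd = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        b1, b2, b3 = self._sec
        e_bond = m.bond_k * float(((dd[:b1] - self._bond_t) ** 2).sum())
        dt = dd[b1:b2]
        if dt.size:
            out = np.maximum(dt - m.tether_hi, 0.0) + np.maximum(m.tether_lo - dt, 0.0)
            e_bond += m.tether_k * float((out ** 2).sum())
        terms["bond"] = e_bond

        ds = dd[b2:b3]
        if ds.size:
            slo, shi, sw = self._sl[2], self._sl[3], self._sl[4]
            viol = np.maximum(ds - shi, 0.0) + np.maximum(slo - ds, 0.0)
            terms["restraint_slope"] = float((sw * viol).sum())
        dw = dd[b3:]
        if dw.size:
            wlo, whi, ww = self._we[2], self._we[3], self._we[4]
            hit = (dw >= wlo) & (dw <= whi)
            terms["restraint_well"] = -float((ww * hit).sum())

        terms["excluded_volume"] = m.ev_k * float(
            _ev_sum(xyz, self._ev_mask, m.ev_radius)
        )

        detected: list[tuple[int, int]] = []
        flags = np.ones(self.n_res)
        if self._cand_i.size:
            dist = self._candidate_distances(xyz)
            dev = np.abs(dist - self._cww)
            D = dev.sum(axis=1)
            s = np.clip(
                1.0 - np.maximum(D - m.funnel_inner, 0.0)
                / (m.funnel_range - m.funnel_inner),
                0.0, 1.0,
            )
            order = np.argsort(D, kind="stable").tolist()
            att = self._greedy_match(order, (s > 0.0).tolist())
            if att:
                terms["pairing"] = -m.pair_depth * float(s[att].sum())
                if m.coop_depth > 0.0:
                    # zipping cooperativity: neighboring formed pairs
                    # (i, j) and (i+1, j-1) reinforce each other
                    sm = {(self._ci_list[k], self._cj_list[k]): s[k] for k in att}
                    e = 0.0
                    for (i, j), sv in sm.items():
                        nb = sm.get((i + 1, j - 1))
                        if nb is not None:
                            e += sv * nb
                    terms["cooperativity"] = -m.coop_depth * e
            ok = (dev <= m.pair_tolerance).all(axis=1)
            det = self._greedy_match(order, ok.tolist())
            detected = sorted(
                (self._ci_list[k], self._cj_list[k]) for k in det
            )
            for i, j in detected:
                flags[i] = flags[j] = 0.0

        if self._stack_pairs.size:
            cent = coords.reshape(self.n_res, 5, 3)[:, 2:5, :].mean(axis=1)
            cd = cent[self._stack_pairs] - cent[self._stack_pairs + 1]
            dc = np.sqrt(np.einsum("ij,ij->i", cd, cd))
            out = np.maximum(dc - m.stack_hi, 0.0) + np.maximum(m.stack_lo - dc, 0.0)
            sstk = np.clip(1.0 - out / m.stack_shoulder, 0.0, 1.0)
            terms["stacking"] = -m.stack_depth * float(sstk.sum())

        if self._excluded.size and detected:
            excl = set(self._excluded.tolist())
            nhit = sum(1 for i, j in detected if i in excl or j in excl)
            terms["exclusion"] = self.restraints.exclusion_penalty * nhit

        if self.restraints.reactivity is not None:
            terms["probing"] = m.probing_weight * probing_score(
                flags, self.restraints.reactivity
            )

        return sum(terms.values()), terms


def detect_canonical_pairs(
    conf: CGConformation,
    model: EnergyModel | None = None,
    tolerance: float | None = None,
) -> PairingState:
    """Detect canonical pairs in a conformation from geometry alone."""
    model = model or EnergyModel()
    if tolerance is not None:
        model = EnergyModel(**{**model.to_dict(), "pair_tolerance": tolerance})
    ctx = EnergyContext(conf.sequences, model)
    return ctx.detect(conf.coords())


def total_energy(
    conf: CGConformation,
    model: EnergyModel | None = None,
    restraints: RestraintSet | None = None,
) -> tuple[float, dict[str, float]]:
    """Total surrogate energy of a conformation with its restraint terms."""
    ctx = EnergyContext(conf.sequences, model, restraints)
    return ctx.evaluate(conf.coords())
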