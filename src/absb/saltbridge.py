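"""Arginine-carboxylate salt-bridge geometry over conformer ensembles.

A guanidinium group (Arg side chain: CZ with NE, NH1, NH2) can pair with a
carboxylate (Asp OD1/OD2 or Glu OE1/OE2) in three modes:

* ``side_on``  — bidentate: NH1 and NH2 each contact a distinct oxygen;
* ``end_on``   — bidentate: NE and one NH each contact a distinct oxygen;
* ``backside`` — monodentate: exactly one nitrogen carries any contact.

A contact is a heavy-atom N...O distance within a cutoff (default 3.5 A, the
standard salt-bridge criterion).  When several patterns hold simultaneously
the highest-denticity interpretation wins: side_on > end_on > backside.

Given an ensemble of conformers (e.g. frames of an MD trajectory of the
amyloid-beta monomer) the module reports per donor-acceptor pair occupancies
and mode breakdowns, the fraction of conformers in which one arginine bridges
two acceptors at once, and Calpha-Calpha distance statistics conditioned on
bridge presence — the quantities linking transient N-terminal salt bridges to
chain compaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "ConformerEnsemble",
    "GuanidiniumGroup",
    "CarboxylateGroup",
    "SaltBridgeAssignment",
    "EnsembleBridgeStats",
    "ConditionalDistance",
    "extract_groups",
    "classify_mode",
    "mode_from_contacts",
    "scan_ensemble",
    "simultaneous_bridging",
    "conditional_ca_distance",
]

MODES = ("side_on", "end_on", "backside")
#: residues carrying a side-chain carboxylate and their (carbon, O1, O2) atoms
_CARBOXYLATE_ATOMS = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CD", "OE1", "OE2")}
_GUANIDINIUM_ATOMS = ("CZ", "NE", "NH1", "NH2")
_BOND_MAX = 1.6  # A, covalent-bond sanity limit

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class ConformerEnsemble:
    """Ordered set of conformers sharing one atom roster.

    Atoms are stored as parallel arrays (roster) plus a coordinate block of
    shape ``(n_conformers, n_atoms, 3)`` in Angstrom.  Residue numbering is
    1-based and contiguous.
    """

    residue_index: np.ndarray  # (n_atoms,) int
    residue_name: np.ndarray  # (n_atoms,) <U3
    atom_name: np.ndarray  # (n_atoms,) <U4
    coords: np.ndarray  # (n_conformers, n_atoms, 3) float

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype="U3")
        self.atom_name = np.asarray(self.atom_name, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidParameterError("coords must have shape (n_conformers, n_atoms, 3)")
        if self.coords.shape[1] != self.residue_index.size:
            raise InvalidParameterError("coords second axis must match the atom roster")
        resids = np.unique(self.residue_index)
        if resids.size and (resids[0] != 1 or np.any(np.diff(resids) != 1)):
            raise InvalidParameterError("residue numbering must be contiguous from 1")

    @property
    def n_conformers(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    @property
    def n_residues(self) -> int:
        return int(np.unique(self.residue_index).size)

    @property
    def sequence(self) -> str:
        """1-letter sequence derived from the roster."""
        out = []
        for r in np.unique(self.residue_index):
            name = str(self.residue_name[self.residue_index == r][0])
            out.append(_THREE_TO_ONE.get(name, "X"))
        return "".join(out)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Roster position of one atom; -1 if absent."""
        hits = np.nonzero(
            (self.residue_index == residue_index) & (self.atom_name == atom_name)
        )[0]
        return int(hits[0]) if hits.size else -1

    def residue_name_of(self, residue_index: int) -> str:
        mask = self.residue_index == residue_index
        if not mask.any():
            raise InvalidParameterError(f"no residue {residue_index} in ensemble")
        return str(self.residue_name[mask][0])


@dataclass(frozen=True)
class GuanidiniumGroup:
    """Arg side-chain guanidinium: CZ centre with NE, NH1, NH2."""

    residue_index: int
    cz: np.ndarray
    ne: np.ndarray
    nh1: np.ndarray
    nh2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ne", "nh1", "nh2"):
            d = float(np.linalg.norm(getattr(self, name) - self.cz))
            if d >= _BOND_MAX:
                raise InvalidParameterError(
                    f"guanidinium {name.upper()}-CZ distance {d:.2f} A >= {_BOND_MAX} A "
                    f"(residue {self.residue_index})"
                )

    @property
    def nitrogens(self) -> np.ndarray:
        """(3, 3) array ordered NE, NH1, NH2."""
        return np.stack([self.ne, self.nh1, self.nh2])


@dataclass(frozen=True)
class CarboxylateGroup:
    """Asp/Glu side-chain carboxylate: carbon with two oxygens."""

    residue_index: int
    residue_name: str
    carbon: np.ndarray
    o1: np.ndarray
    o2: np.ndarray

    def __post_init__(self) -> None:
        if self.residue_name not in _CARBOXYLATE_ATOMS:
            raise InvalidParameterError(
                f"residue {self.residue_name!r} is not ASP/GLU (residue {self.residue_index})"
            )
        for label, o in (("O1", self.o1), ("O2", self.o2)):
            d = float(np.linalg.norm(o - self.carbon))
            if d >= _BOND_MAX:
                raise InvalidParameterError(
                    f"carboxylate {label}-C distance {d:.2f} A >= {_BOND_MAX} A "
                    f"(residue {self.residue_index})"
                )

    @property
    def oxygens(self) -> np.ndarray:
        """(2, 3) array ordered O1, O2."""
        return np.stack([self.o1, self.o2])


@dataclass
class SaltBridgeAssignment:
    """Mode assignment of one donor-acceptor pair in one conformer."""

    conformer_id: int
    donor_residue: int
    acceptor_residue: int
    mode: str  # side_on | end_on | backside | none
    contacts: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in MODES + ("none",):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if (self.mode != "none") != bool(self.contacts):
            raise InvalidParameterError("mode/contacts inconsistency")


@dataclass
class ConditionalDistance:
    """Calpha-Calpha distance summary split by bridge presence (nm)."""

    residue_pair: tuple[int, int]
    mean_with: float
    sd_with: float
    n_with: int
    mean_without: float
    sd_without: float
    n_without: int


@dataclass
class EnsembleBridgeStats:
    """Ensemble-level occupancy statistics.

    ``pair_occupancy[(donor, acceptor)]`` is the fraction of conformers with
    any bridge mode for that pair; ``pair_modes`` breaks the occupancy down by
    mode (the mode fractions sum to the pair occupancy).
    """

    n_conformers: int
    cutoff: float
    pair_occupancy: dict[tuple[int, int], float]
    pair_modes: dict[tuple[int, int], dict[str, float]]
    modes_per_conformer: dict[tuple[int, int], np.ndarray]

    def occupancy(self, donor: int, acceptor: int) -> float:
        return self.pair_occupancy.get((donor, acceptor), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (d, a), occ in sorted(self.pair_occupancy.items()):
            row = {"donor": d, "acceptor": a, "occupancy": occ}
            row.update({m: self.pair_modes[(d, a)].get(m, 0.0) for m in MODES})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group extraction


def extract_groups(
    ensemble: ConformerEnsemble,
    conformer_id: int,
    include_cterm_backbone: bool = False,
) -> tuple[list[GuanidiniumGroup], list[CarboxylateGroup]]:
    """Extract guanidinium and side-chain carboxylate groups of one conformer.

    Residues with incomplete side-chain groups are skipped with a warning.
    The C-terminal backbone carboxylate (O/OXT) is excluded unless
    ``include_cterm_backbone`` is set; only side-chain partners are considered.
    """
    xyz = ensemble.coords[conformer_id]
    gdms: list[GuanidiniumGroup] = []
    carbs: list[CarboxylateGroup] = []
    for r in np.unique(ensemble.residue_index):
        r = int(r)
        name = ensemble.residue_name_of(r)
        if name == "ARG":
            idx = [ensemble.atom_index(r, a) for a in _GUANIDINIUM_ATOMS]
            if min(idx) < 0:
                missing = [a for a, i in zip(_GUANIDINIUM_ATOMS, idx) if i < 0]
                warnings.warn(
                    f"ARG {r}: missing guanidinium atom(s) {missing}; skipped",
                    stacklevel=2,
                )
                continue
            gdms.append(
                GuanidiniumGroup(r, xyz[idx[0]], xyz[idx[1]], xyz[idx[2]], xyz[idx[3]])
            )
        elif name in _CARBOXYLATE_ATOMS:
            atoms = _CARBOXYLATE_ATOMS[name]
            idx = [ensemble.atom_index(r, a) for a in atoms]
            if min(idx) < 0:
                missing = [a for a, i in zip(atoms, idx) if i < 0]
                warnings.warn(
                    f"{name} {r}: missing carboxylate atom(s) {missing}; skipped",
                    stacklevel=2,
                )
                continue
            carbs.append(CarboxylateGroup(r, name, xyz[idx[0]], xyz[idx[1]], xyz[idx[2]]))
    if include_cterm_backbone:
        r = int(ensemble.residue_index.max())
        idx_c = ensemble.atom_index(r, "C")
        idx_o = ensemble.atom_index(r, "O")
        idx_oxt = ensemble.atom_index(r, "OXT")
        if min(idx_c, idx_o, idx_oxt) >= 0:
            name = ensemble.residue_name_of(r)
            # backbone carboxylate re-labelled through the same container
            grp = CarboxylateGroup.__new__(CarboxylateGroup)
            object.__setattr__(grp, "residue_index", r)
            object.__setattr__(grp, "residue_name", name)
            object.__setattr__(grp, "carbon", xyz[idx_c])
            object.__setattr__(grp, "o1", xyz[idx_o])
            object.__setattr__(grp, "o2", xyz[idx_oxt])
            carbs.append(grp)
    return gdms, carbs


# ---------------------------------------------------------------------------
# mode classification


def mode_from_contacts(contacts: np.ndarray) -> str:
    """Mode implied by a 3x2 boolean contact matrix (rows NE, NH1, NH2).

    side_on: NH1 and NH2 each contact a distinct oxygen; end_on: NE and one NH
    each contact a distinct oxygen; backside: exactly one nitrogen has any
    contact.  Precedence side_on > end_on > backside.
    """
    c = np.asarray(contacts, dtype=bool)
    if c.shape != (3, 2):
        raise InvalidParameterError("contact matrix must be 3x2 (NE,NH1,NH2 x O1,O2)")
    ne, nh1, nh2 = c
    if (nh1[0] and nh2[1]) or (nh1[1] and nh2[0]):
        return "side_on"
    if (ne[0] and (nh1[1] or nh2[1])) or (ne[1] and (nh1[0] or nh2[0])):
        return "end_on"
    if int(ne.any()) + int(nh1.any()) + int(nh2.any()) == 1:
        return "backside"
    return "none"


def classify_mode(
    gdm: GuanidiniumGroup,
    carb: CarboxylateGroup,
    cutoff: float = 3.5,
    conformer_id: int = 0,
) -> SaltBridgeAssignment:
    """Classify the interaction mode of one guanidinium-carboxylate pair."""
    if cutoff <= 0:
        raise InvalidParameterError(f"cutoff must be > 0 A, got {cutoff}")
    dists = np.linalg.norm(gdm.nitrogens[:, None, :] - carb.oxygens[None, :, :], axis=2)
    contact = dists <= cutoff
    mode = mode_from_contacts(contact)
    n_names = ("NE", "NH1", "NH2")
    o_names = ("O1", "O2")
    contacts = [
        (n_names[i], o_names[j], float(dists[i, j]))
        for i in range(3)
        for j in range(2)
        if contact[i, j]
    ]
    if mode == "none":
        contacts = []
    return SaltBridgeAssignment(
        conformer_id=conformer_id,
        donor_residue=gdm.residue_index,
        acceptor_residue=carb.residue_index,
        mode=mode,
        contacts=contacts,
    )


def _pair_atom_indices(
    ensemble: ConformerEnsemble, donor: int, acceptor: int
) -> tuple[list[int], list[int]] | None:
    """Roster indices of (NE,NH1,NH2) and (O1,O2) for one pair; None if incomplete."""
    if ensemble.residue_name_of(donor) != "ARG":
        raise InvalidParameterError(f"donor residue {donor} is not ARG")
    aname = ensemble.residue_name_of(acceptor)
    if aname not in _CARBOXYLATE_ATOMS:
        raise InvalidParameterError(f"acceptor residue {acceptor} ({aname}) is not ASP/GLU")
    n_idx = [ensemble.atom_index(donor, a) for a in ("NE", "NH1", "NH2")]
    _, o1n, o2n = _CARBOXYLATE_ATOMS[aname]
    o_idx = [ensemble.atom_index(acceptor, o1n), ensemble.atom_index(acceptor, o2n)]
    if min(n_idx) < 0 or min(o_idx) < 0:
        return None
    return n_idx, o_idx


def _modes_for_pair(
    ensemble: ConformerEnsemble, donor: int, acceptor: int, cutoff: float
) -> np.ndarray:
    """Vectorised per-conformer mode codes for one donor-acceptor pair.

    Returns an int array (0 none, 1 side_on, 2 end_on, 3 backside).
    """
    idx = _pair_atom_indices(ensemble, donor, acceptor)
    if idx is None:
        return np.zeros(ensemble.n_conformers, dtype=int)
    n_idx, o_idx = idx
    n_xyz = ensemble.coords[:, n_idx, :]  # (n, 3, 3)
    o_xyz = ensemble.coords[:, o_idx, :]  # (n, 2, 3)
    d = np.linalg.norm(n_xyz[:, :, None, :] - o_xyz[:, None, :, :], axis=3)  # (n,3,2)
    c = d <= cutoff
    ne, nh1, nh2 = c[:, 0, :], c[:, 1, :], c[:, 2, :]
    side = (nh1[:, 0] & nh2[:, 1]) | (nh1[:, 1] & nh2[:, 0])
    end = (ne[:, 0] & (nh1[:, 1] | nh2[:, 1])) | (ne[:, 1] & (nh1[:, 0] | nh2[:, 0]))
    n_touched = (
        ne.any(axis=1).astype(int)
        + nh1.any(axis=1).astype(int)
        + nh2.any(axis=1).astype(int)
    )
    back = n_touched == 1
    modes = np.zeros(ensemble.n_conformers, dtype=int)
    modes[back] = 3
    modes[end] = 2
    modes[side] = 1
    return modes


_MODE_CODES = {1: "side_on", 2: "end_on", 3: "backside"}


def scan_ensemble(
    ensemble: ConformerEnsemble,
    cutoff: float = 3.5,
    donor_filter: Sequence[int] | None = None,
    acceptor_filter: Sequence[int] | None = None,
) -> EnsembleBridgeStats:
    """Scan every Arg x Asp/Glu pair of an ensemble for salt bridges.

    Returns per-pair occupancy fractions and mode breakdowns; deterministic
    given the ensemble and cutoff.  ``donor_filter`` / ``acceptor_filter``
    restrict to the listed residue indices.
    """
    if ensemble.n_conformers == 0:
        raise InvalidParameterError("empty ensemble")
    if cutoff <= 0:
        raise InvalidParameterError(f"cutoff must be > 0 A, got {cutoff}")
    resids = [int(r) for r in np.unique(ensemble.residue_index)]
    donors = [r for r in resids if ensemble.residue_name_of(r) == "ARG"]
    acceptors = [r for r in resids if ensemble.residue_name_of(r) in _CARBOXYLATE_ATOMS]
    if donor_filter is not None:
        donors = [r for r in donors if r in set(donor_filter)]
    if acceptor_filter is not None:
        acceptors = [r for r in acceptors if r in set(acceptor_filter)]
    n = ensemble.n_conformers
    pair_occ: dict[tuple[int, int], float] = {}
    pair_modes: dict[tuple[int, int], dict[str, float]] = {}
    per_conf: dict[tuple[int, int], np.ndarray] = {}
    for d in donors:
        for a in acceptors:
            modes = _modes_for_pair(ensemble, d, a, cutoff)
            per_conf[(d, a)] = modes
            pair_occ[(d, a)] = float(np.count_nonzero(modes) / n)
            pair_modes[(d, a)] = {
                name: float(np.count_nonzero(modes == code) / n)
                for code, name in _MODE_CODES.items()
            }
    return EnsembleBridgeStats(
        n_conformers=n,
        cutoff=cutoff,
        pair_occupancy=pair_occ,
        pair_modes=pair_modes,
        modes_per_conformer=per_conf,
    )


def simultaneous_bridging(
    ensemble: ConformerEnsemble,
    donor: int,
    acceptors: Sequence[int],
    cutoff: float = 3.5,
) -> float:
    """Fraction of conformers where the donor bridges every listed acceptor.

    A conformer counts when the donor shows any mode (side_on, end_on or
    backside) with each acceptor simultaneously.
    """
    if len(acceptors) < 2:
        raise InvalidParameterError("need >= 2 acceptor residues")
    if ensemble.n_conformers == 0:
        raise InvalidParameterError("empty ensemble")
    mask = np.ones(ensemble.n_conformers, dtype=bool)
    for a in acceptors:
        mask &= _modes_for_pair(ensemble, donor, int(a), cutoff) != 0
    return float(np.count_nonzero(mask) / ensemble.n_conformers)


def conditional_ca_distance(
    ensemble: ConformerEnsemble,
    bridge_spec: Sequence[tuple[int, int]],
    residue_pair: tuple[int, int],
    cutoff: float = 3.5,
) -> ConditionalDistance:
    """Calpha-Calpha distance statistics conditioned on bridge presence.

    Splits the ensemble by whether *any* (donor, acceptor) pair in
    ``bridge_spec`` shows a bridge, and summarises the Calpha-Calpha distance
    of ``residue_pair`` in nanometres on each side.  An empty partition is
    reported with n = 0 and NaN mean/sd.
    """
    i, j = residue_pair
    ca_i = ensemble.atom_index(int(i), "CA")
    ca_j = ensemble.atom_index(int(j), "CA")
    if ca_i < 0 or ca_j < 0:
        raise InvalidParameterError(f"residue pair {residue_pair} lacks CA atoms")
    bridged = np.zeros(ensemble.n_conformers, dtype=bool)
    for d, a in bridge_spec:
        bridged |= _modes_for_pair(ensemble, int(d), int(a), cutoff) != 0
    dist_nm = (
        np.linalg.norm(ensemble.coords[:, ca_i, :] - ensemble.coords[:, ca_j, :], axis=1)
        / 10.0
    )

    def _summ(x: np.ndarray) -> tuple[float, float, int]:
        if x.size == 0:
            return float("nan"), float("nan"), 0
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return float(np.mean(x)), sd, int(x.size)

    mw, sw, nw = _summ(dist_nm[bridged])
    mo, so, no = _summ(dist_nm[~bridged])
    return ConditionalDistance(
        residue_pair=(int(i), int(j)),
        mean_with=mw,
        sd_with=sw,
        n_with=nw,
        mean_without=mo,
        sd_without=so,
        n_without=no,
    )
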