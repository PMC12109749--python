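"""Core domain types for bent-DNA (DNA-bow) trajectory analysis.

The frame of reference for every metric in this package is a 30-bp duplex:
residues 1..30 are strand B (5'->3'), residues 31..60 the complementary
strand C, and base pair *i* joins residues (i, 61-i).  Coordinates are always
in Angstrom, times in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "DnabowError",
    "InvalidSequenceError",
    "MissingAtomError",
    "DegenerateInputError",
    "InsufficientFramesError",
    "NoHydrogensError",
    "AtomRecord",
    "BasePair",
    "Topology",
    "Trajectory",
    "Selection",
    "COMPLEMENT",
    "ION_SPECIES",
    "ION_CHARGE",
    "complement_sequence",
    "build_pair_map",
    "select",
    "infer_element",
]


class DnabowError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(DnabowError):
    pass


class MissingAtomError(DnabowError):
    pass


class DegenerateInputError(DnabowError):
    pass


class InsufficientFramesError(DnabowError):
    pass


class NoHydrogensError(DnabowError):
    pass


COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Ion species handled by the ion-shell analyses, with formal charges.
ION_SPECIES = ("MG", "NA", "CL")
ION_CHARGE = {"MG": 2, "NA": 1, "CL": -1}

_ION_ELEMENT = {"MG": "Mg", "NA": "Na", "CL": "Cl"}

DUPLEX_LENGTH = 30
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def infer_element(name: str, res_name: str = "") -> str:
    """Element symbol for an atom, from PDB v3 nucleic-acid name conventions.

    Monatomic ion residues (MG/NA/CL) map to their two-letter elements;
    everything else takes the first alphabetic character of the atom name.
    """
    if res_name in _ION_ELEMENT:
        return _ION_ELEMENT[res_name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


class AtomRecord(NamedTuple):
    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain_id: str


@dataclass(frozen=True)
class BasePair:
    """One Watson-Crick pair of the duplex: residues (res_b, res_c) with res_b + res_c = 61."""

    res_b: int
    res_c: int
    wc_type: str

    def __post_init__(self):
        if not (1 <= self.res_b <= DUPLEX_LENGTH):
            raise ValueError(f"res_b {self.res_b} outside 1..{DUPLEX_LENGTH}")
        if self.res_b + self.res_c != 2 * DUPLEX_LENGTH + 1:
            raise ValueError(
                f"pair ({self.res_b}, {self.res_c}) violates res_b + res_c = {2 * DUPLEX_LENGTH + 1}"
            )
        b, c = self.wc_type
        if COMPLEMENT.get(b) != c:
            raise ValueError(f"wc_type {self.wc_type!r} is not Watson-Crick complementary")


def complement_sequence(sequence: str) -> str:
    """Complement (not reversed) of a DNA sequence."""
    try:
        return "".join(COMPLEMENT[b] for b in sequence)
    except KeyError as exc:
        raise InvalidSequenceError(f"non-ACGT character {exc.args[0]!r}") from None


def build_pair_map(sequence_b: str) -> list[BasePair]:
    """Pair map of a 30-bp duplex: pair i joins strand-B residue i to residue 61-i.

    The numbering is continuous across the duplex (B then C), so e.g. pair 4
    is (4, 57) and pair 21 is (21, 40).
    """
    if len(sequence_b) != DUPLEX_LENGTH:
        raise InvalidSequenceError(
            f"sequence must be {DUPLEX_LENGTH} bases, got {len(sequence_b)}"
        )
    if any(b not in COMPLEMENT for b in sequence_b):
        bad = next(b for b in sequence_b if b not in COMPLEMENT)
        raise InvalidSequenceError(f"non-ACGT character {bad!r}")
    return [
        BasePair(i, 2 * DUPLEX_LENGTH + 1 - i, b + COMPLEMENT[b])
        for i, b in enumerate(sequence_b, start=1)
    ]


@dataclass
class Topology:
    """Atoms plus the duplex pairing map.

    Atom attributes are stored as parallel numpy arrays for vectorised
    selection; ``atoms`` yields :class:`AtomRecord` views in file order.
    DNA residues obey res_id 1..30 <-> chain "B" and 31..60 <-> chain "C";
    ions live on chain "I" with res_ids above 60.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    sequence_b: str = ""
    pairs: list[BasePair] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.serial)
        for arr in (self.name, self.element, self.res_name, self.res_id, self.chain_id):
            if len(arr) != n:
                raise ValueError("topology attribute arrays must have equal length")
        b_mask = self.chain_id == "B"
        c_mask = self.chain_id == "C"
        if np.any((self.res_id[b_mask] < 1) | (self.res_id[b_mask] > DUPLEX_LENGTH)):
            raise ValueError("chain B residues must have res_id 1..30")
        if np.any(
            (self.res_id[c_mask] <= DUPLEX_LENGTH) | (self.res_id[c_mask] > 2 * DUPLEX_LENGTH)
        ):
            raise ValueError("chain C residues must have res_id 31..60")
        if self.sequence_b and not self.pairs:
            self.pairs = build_pair_map(self.sequence_b)
        self._index_cache: dict[tuple[int, str], int] = {}

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def atoms(self) -> Iterable[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                int(self.serial[i]),
                str(self.name[i]),
                str(self.element[i]),
                str(self.res_name[i]),
                int(self.res_id[i]),
                str(self.chain_id[i]),
            )

    @property
    def dna_mask(self) -> np.ndarray:
        return np.isin(self.chain_id, ("B", "C"))

    @property
    def ion_mask(self) -> np.ndarray:
        return np.isin(self.res_name, ION_SPECIES)

    def species_indices(self, species: str) -> np.ndarray:
        if species not in ION_SPECIES:
            raise ValueError(f"unknown ion species {species!r}")
        return np.flatnonzero(self.res_name == species)

    def atom_index(self, res_id: int, name: str) -> int:
        """Index of a named atom in a residue; MissingAtomError if absent."""
        key = (res_id, name)
        if key not in self._index_cache:
            hits = np.flatnonzero((self.res_id == res_id) & (self.name == name))
            if hits.size == 0:
                raise MissingAtomError(f"residue {res_id} has no atom {name!r}")
            self._index_cache[key] = int(hits[0])
        return self._index_cache[key]

    def residue_indices(self, res_id: int) -> np.ndarray:
        return np.flatnonzero(self.res_id == res_id)


@dataclass(frozen=True)
class Selection:
    """Conjunction of atom-name / residue-id / chain-id / element filters.

    Attributes left as ``None`` match everything; an empty set matches
    nothing.  Applying a selection to a topology yields strictly increasing
    atom indices.
    """

    names: frozenset[str] | None = None
    res_ids: frozenset[int] | None = None
    chains: frozenset[str] | None = None
    elements: frozenset[str] | None = None

    @classmethod
    def of(cls, names=None, res_ids=None, chains=None, elements=None) -> "Selection":
        conv = lambda x: None if x is None else frozenset(x)
        return cls(conv(names), conv(res_ids), conv(chains), conv(elements))

    def mask(self, topology: Topology) -> np.ndarray:
        m = np.ones(topology.n_atoms, dtype=bool)
        if self.names is not None:
            m &= np.isin(topology.name, list(self.names))
        if self.res_ids is not None:
            m &= np.isin(topology.res_id, list(self.res_ids))
        if self.chains is not None:
            m &= np.isin(topology.chain_id, list(self.chains))
        if self.elements is not None:
            m &= np.isin(topology.element, list(self.elements))
        return m

    def indices(self, topology: Topology) -> np.ndarray:
        return np.flatnonzero(self.mask(topology))


def select(topology: Topology, selection: Selection) -> np.ndarray:
    """Ordered atom indices matched by ``selection`` (empty result allowed)."""
    return selection.indices(topology)


@dataclass
class Trajectory:
    """Ordered coordinate frames (Angstrom) over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``dt_ns`` is the frame
    spacing; ``box`` optionally holds orthorhombic box lengths.
    """

    topology: Topology
    coords: np.ndarray
    dt_ns: float
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not self.dt_ns > 0:
            raise ValueError("dt_ns must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


def trailing_window(n_frames: int, window_fraction: float) -> slice:
    """Slice selecting the trailing ceil(window_fraction * n_frames) frames.

    The default reporting window elsewhere in the package is 100/260, the
    proportion of a 260-ns run covered by its last 100 ns.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    n = int(np.ceil(window_fraction * n_frames))
    if n < 1:
        raise ValueError("empty averaging window")
    return slice(n_frames - n, n_frames)
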