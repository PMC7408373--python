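"""Protein-block structural alphabet: prototypes and nearest-prototype assignment.

Protein Blocks (PBs) are 16 prototype local backbone conformations, labelled
``a`` through ``p``.  Each prototype is an 8-dimensional vector of backbone
dihedral angles spanning five consecutive residues, ordered::

    psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2)

where ``i`` is the central residue.  A residue is assigned the label of the
prototype closest in root-mean-square deviation over angular differences
(RMSDA).  Residues whose five-residue window is incomplete — the two residues
at each chain end, or any window spanning a chain break or an undefined
dihedral — receive the undefined label ``Z``.

The prototype table ships as plain-text package data
(``data/pb_prototypes.dat``); an alternative alphabet of any size ``n`` can be
substituted via :meth:`PBPrototypeTable.from_text`, in which case the entropy
index N_eq ranges over ``[1, n]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "UNDEFINED_LABEL",
    "WINDOW_SIZE",
    "WINDOW_COORDS",
    "InvalidAngleError",
    "UndefinedWindowError",
    "PBPrototypeTable",
    "angular_distance",
    "normalize_angle",
    "rmsda",
    "assign_pb",
    "assign_sequence",
    "window_angles",
    "separation_matrix",
]

#: Label used for residues without a complete, valid dihedral window.
UNDEFINED_LABEL = "Z"

#: A PB window spans five consecutive residues (eight dihedrals).
WINDOW_SIZE = 5

#: Window layout as (residue offset from centre, angle kind).
WINDOW_COORDS = (
    (-2, "psi"),
    (-1, "phi"),
    (-1, "psi"),
    (0, "phi"),
    (0, "psi"),
    (+1, "phi"),
    (+1, "psi"),
    (+2, "phi"),
)

_PB_LABELS = tuple("abcdefghijklmnop")


class InvalidAngleError(ValueError):
    """An angle argument was non-finite."""


class UndefinedWindowError(ValueError):
    """An operation requiring a valid dihedral window received an invalid one."""


def normalize_angle(angle):
    """Reduce an angle in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -np.mod(-a, 360.0)  # (-360, 0]
    out = np.where(out <= -180.0, out + 360.0, out)
    return out if out.ndim else float(out)


def angular_distance(x, y):
    """Shortest arc between two angles in degrees; result in [0, 180].

    Broadcasts over array inputs.  Non-finite input raises
    :class:`InvalidAngleError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidAngleError("angular_distance requires finite angles")
    d = np.abs(x - y) % 360.0
    d = np.minimum(d, 360.0 - d)
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class PBPrototypeTable:
    """An ordered structural alphabet of dihedral-window prototypes.

    Attributes
    ----------
    labels : tuple of str
        Single-character prototype labels, distinct, in table order.
    angles : ndarray, shape (n, 8)
        Prototype dihedral windows in degrees, each value in (-180, 180].
    """

    labels: tuple
    angles: np.ndarray = field(repr=False)

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != angles.shape[0]:
            raise ValueError("label count does not match angle rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("prototype labels must be distinct")
        if UNDEFINED_LABEL in self.labels:
            raise ValueError(f"{UNDEFINED_LABEL!r} is reserved for undefined windows")
        if angles.ndim != 2 or angles.shape[1] != 2 * (WINDOW_SIZE - 1):
            raise ValueError("each prototype needs 8 dihedral angles")
        if not np.all(np.isfinite(angles)):
            raise ValueError("prototype angles must be finite")
        if np.any(angles <= -180.0) or np.any(angles > 180.0):
            raise ValueError("prototype angles must lie in (-180, 180]")

    def __len__(self):
        return len(self.labels)

    @property
    def size(self) -> int:
        """Number of prototypes (16 for the canonical PB alphabet)."""
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def from_text(cls, text: str) -> "PBPrototypeTable":
        """Parse a table from plain text: one ``label a1 ... a8`` row per line.

        Lines that are blank or start with ``#`` are ignored.
        """
        labels, rows = [], []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 9:
                raise ValueError(f"line {lineno}: expected 'label + 8 angles'")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        if not labels:
            raise ValueError("no prototype rows found")
        return cls(labels=tuple(labels), angles=np.array(rows))

    @classmethod
    def default(cls) -> "PBPrototypeTable":
        """The canonical 16-prototype PB table shipped with the package."""
        text = (
            resources.files("pbneq").joinpath("data/pb_prototypes.dat").read_text()
        )
        table = cls.from_text(text)
        if table.labels != _PB_LABELS:
            raise ValueError("packaged PB table is corrupted")
        return table


def _as_window(window) -> np.ndarray:
    """Coerce a window to an 8-vector of floats, NaN marking undefined angles."""
    w = np.asarray(window, dtype=float)
    if w.shape != (2 * (WINDOW_SIZE - 1),):
        raise UndefinedWindowError("a dihedral window has exactly 8 angles")
    return w


def rmsda(window, prototype) -> float:
    """Root-mean-square deviation over the 8 angular differences, in degrees.

    Raises :class:`UndefinedWindowError` if the window contains undefined
    (non-finite) angles.
    """
    w = _as_window(window)
    if not np.all(np.isfinite(w)):
        raise UndefinedWindowError("window contains undefined dihedrals")
    p = _as_window(prototype)
    d = angular_distance(w, p)
    return float(np.sqrt(np.mean(np.square(d))))


def assign_pb(window, table: PBPrototypeTable) -> str:
    """Label of the prototype with minimal RMSDA to ``window``.

    An invalid window (wrong length handled as an error; any non-finite
    angle) yields the undefined label ``Z``.  Ties break to the
    alphabetically first label, making assignment deterministic.
    """
    w = _as_window(window)
    if not np.all(np.isfinite(w)):
        return UNDEFINED_LABEL
    d = angular_distance(w[np.newaxis, :], table.angles)
    cost = np.mean(np.square(d), axis=1)
    order = np.lexsort((np.array(table.labels), cost))
    return table.labels[order[0]]


def window_angles(phi: np.ndarray, psi: np.ndarray, i: int) -> np.ndarray:
    """The 8-dihedral window centred on 0-based position ``i``.

    ``phi`` and ``psi`` are per-residue arrays with NaN for undefined angles.
    Positions too close to either end raise :class:`UndefinedWindowError`.
    """
    L = len(phi)
    if i < 2 or i > L - 3:
        raise UndefinedWindowError("window extends past the chain end")
    vals = []
    for off, kind in WINDOW_COORDS:
        arr = phi if kind == "phi" else psi
        vals.append(arr[i + off])
    return np.asarray(vals, dtype=float)


def assign_sequence(phi, psi, table: PBPrototypeTable) -> np.ndarray:
    """Assign one PB label per residue from per-residue phi/psi arrays.

    Undefined dihedrals (chain ends, breaks, incomplete residues) are passed
    as NaN; every window touching one is labelled ``Z``, as are the first two
    and last two positions.  Returns an array of single-character labels the
    same length as the input.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be 1-D arrays of equal length")
    L = len(phi)
    labels = np.full(L, UNDEFINED_LABEL, dtype="<U1")
    if L < WINDOW_SIZE:
        return labels
    # stack all interior windows: (L-4) x 8
    cols = []
    for off, kind in WINDOW_COORDS:
        arr = phi if kind == "phi" else psi
        cols.append(arr[2 + off : L - 2 + off])
    W = np.stack(cols, axis=1)
    valid = np.all(np.isfinite(W), axis=1)
    if np.any(valid):
        Wn = normalize_angle(W[valid])
        d = np.abs(Wn[:, np.newaxis, :] - table.angles[np.newaxis, :, :]) % 360.0
        d = np.minimum(d, 360.0 - d)
        cost = np.mean(np.square(d), axis=2)
        # tie-break: alphabetical order = table order for the canonical table,
        # but sort explicitly so substituted tables behave identically
        lab_order = np.argsort(np.array(table.labels))
        best = lab_order[np.argmin(cost[:, lab_order], axis=1)]
        interior = np.full(L - 4, UNDEFINED_LABEL, dtype="<U1")
        interior[valid] = np.array(table.labels, dtype="<U1")[best]
        labels[2 : L - 2] = interior
    return labels


def separation_matrix(table: PBPrototypeTable) -> np.ndarray:
    """Pairwise RMSDA between prototypes (degrees), shape (n, n).

    The minimum off-diagonal entry measures how well-separated the alphabet
    is, and hence how much angular noise nearest-prototype assignment
    tolerates.
    """
    n = table.size
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rmsda(table.angles[i], table.angles[j])
    return out
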