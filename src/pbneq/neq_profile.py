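"""Per-position PB frequency profiles, the N_eq entropy index, and the
rigidity-flexibility-disorder continuum.

Across the models of a conformational ensemble, each position accumulates a
frequency distribution f_a..f_p over the 16 protein blocks.  The equivalent
number of blocks,

    N_eq = exp( - sum_x f_x ln f_x ),

is the exponential of the Shannon entropy (natural log) of that
distribution: 1 when a single block is ever observed (a locally rigid
position), 16 when all blocks are equally likely (maximal local
heterogeneity, i.e. disorder).  Positions are classified on the continuum by
configurable N_eq thresholds, by default rigid < 4 <= flexible < 6 <=
highly_flexible < 8 <= disordered.

Undefined cells (label Z: chain ends, breaks, missing atoms) are excluded
from the frequencies — the sum runs over the 16 blocks only — and positions
observed in fewer than ``min_models`` models (default 2) have undefined
N_eq; percentages in :func:`distribution_summary` are over defined positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from .pb_alphabet import UNDEFINED_LABEL, PBPrototypeTable

__all__ = [
    "DEFAULT_CLASS_THRESHOLDS",
    "DEFAULT_MIN_MODELS",
    "FLEXIBILITY_CLASSES",
    "InvalidProfileError",
    "EmptySummaryError",
    "EnsemblePBMatrix",
    "PBFrequencyProfile",
    "NeqProfile",
    "pb_frequencies",
    "neq",
    "classify",
    "neq_profile",
    "frequency_table",
    "distribution_summary",
]

#: Class boundaries (flexible, highly flexible, disordered); left-closed.
DEFAULT_CLASS_THRESHOLDS = (4.0, 6.0, 8.0)

#: Minimum valid (non-Z) observations for a position's N_eq to be defined.
DEFAULT_MIN_MODELS = 2

FLEXIBILITY_CLASSES = (
    "rigid",
    "flexible",
    "highly_flexible",
    "disordered",
    "undefined",
)


class InvalidProfileError(ValueError):
    """A frequency profile contained negative entries or did not normalise."""


class EmptySummaryError(ValueError):
    """No position has a defined N_eq."""


@dataclass
class EnsemblePBMatrix:
    """Positions x models grid of PB labels (``Z`` marks undefined cells)."""

    labels: np.ndarray = field(repr=False)  # (L, M) '<U1'
    positions: np.ndarray = None  # (L,) 1-based
    resnames: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.ndim != 2:
            raise ValueError("labels must be a positions x models grid")
        if self.positions is None:
            self.positions = np.arange(1, self.labels.shape[0] + 1)
        self.positions = np.asarray(self.positions, dtype=int)

    @property
    def n_positions(self) -> int:
        return self.labels.shape[0]

    @property
    def n_models(self) -> int:
        return self.labels.shape[1]

    @classmethod
    def from_dihedrals(cls, dihedrals, table: PBPrototypeTable) -> "EnsemblePBMatrix":
        """Assign every model of an :class:`~pbneq.ensemble_io.EnsembleDihedrals`."""
        from .pb_alphabet import assign_sequence

        rows = [
            assign_sequence(dihedrals.phi[k], dihedrals.psi[k], table)
            for k in range(dihedrals.n_models)
        ]
        return cls(
            labels=np.stack(rows, axis=1),
            positions=dihedrals.positions.copy(),
            resnames=dihedrals.resnames.copy(),
        )


@dataclass
class PBFrequencyProfile:
    """Per-position PB frequency vectors with observation counts.

    ``frequencies[i]`` sums to 1 over the alphabet for positions with
    ``valid_model_count[i] >= min_models`` and is NaN otherwise.
    """

    alphabet: tuple
    positions: np.ndarray
    frequencies: np.ndarray = field(repr=False)  # (L, n)
    valid_model_count: np.ndarray = None
    resnames: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.frequencies).all(axis=1)


@dataclass
class NeqProfile:
    """Per-position N_eq values (NaN = undefined) and flexibility classes."""

    positions: np.ndarray
    neq: np.ndarray
    classes: np.ndarray
    valid_model_count: np.ndarray | None = None
    resnames: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.neq)

    def to_frame(self) -> pd.DataFrame:
        data = {"position": self.positions}
        if self.resnames is not None:
            data["residue"] = self.resnames
        if self.valid_model_count is not None:
            data["valid_model_count"] = self.valid_model_count
        data["neq"] = self.neq
        data["class"] = self.classes
        return pd.DataFrame(data)


def pb_frequencies(
    matrix: EnsemblePBMatrix,
    table: PBPrototypeTable | None = None,
    min_models: int = DEFAULT_MIN_MODELS,
) -> PBFrequencyProfile:
    """Per-position frequencies f_x = count(x) / valid_model_count.

    Only non-Z cells count; positions observed in fewer than ``min_models``
    models get a NaN frequency row (undefined downstream N_eq).
    """
    if table is None:
        table = PBPrototypeTable.default()
    L, M = matrix.labels.shape
    if M < 1:
        raise ValueError("need at least one model")
    counts = np.zeros((L, table.size))
    for j, lab in enumerate(table.labels):
        counts[:, j] = np.sum(matrix.labels == lab, axis=1)
    known = counts.sum(axis=1) + np.sum(matrix.labels == UNDEFINED_LABEL, axis=1)
    if np.any(known != M):
        bad = np.nonzero(known != M)[0][0]
        raise ValueError(
            f"position {matrix.positions[bad]} has labels outside the alphabet"
        )
    valid = counts.sum(axis=1).astype(int)
    freqs = np.full((L, table.size), np.nan)
    ok = valid >= max(min_models, 1)
    freqs[ok] = counts[ok] / valid[ok, np.newaxis]
    return PBFrequencyProfile(
        alphabet=table.labels,
        positions=matrix.positions.copy(),
        frequencies=freqs,
        valid_model_count=valid,
        resnames=None if matrix.resnames is None else matrix.resnames.copy(),
    )


def neq(frequencies) -> float | np.ndarray:
    """Exponential Shannon entropy (natural log) of a PB frequency vector.

    Accepts a single frequency vector or an (L, n) array of rows; rows of
    NaN propagate to NaN.  0 * ln 0 is treated as 0.  Values lie in
    [1, n] for an n-letter alphabet.
    """
    f = np.asarray(frequencies, dtype=float)
    single = f.ndim == 1
    rows = f[np.newaxis, :] if single else f
    defined = np.isfinite(rows).all(axis=1)
    if np.any(rows[defined] < 0):
        raise InvalidProfileError("negative frequency")
    tot = rows[defined].sum(axis=1)
    if np.any(np.abs(tot - 1.0) > 1e-6):
        raise InvalidProfileError("frequencies must sum to 1")
    out = np.full(rows.shape[0], np.nan)
    # scipy's entropy renormalises; inputs are already validated as normalised
    out[defined] = np.exp(_shannon_entropy(rows[defined], axis=1))
    return float(out[0]) if single else out


def classify(
    neq_value,
    thresholds: tuple[float, float, float] = DEFAULT_CLASS_THRESHOLDS,
):
    """Flexibility class from N_eq: rigid / flexible / highly_flexible /
    disordered, with left-closed boundaries at the given thresholds
    (defaults 4, 6, 8).  NaN maps to ``undefined``.
    """
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError("thresholds must be strictly increasing")
    v = np.asarray(neq_value, dtype=float)
    single = v.ndim == 0
    v = np.atleast_1d(v)
    out = np.full(v.shape, "undefined", dtype="<U15")
    out[v < t1] = "rigid"
    out[(v >= t1) & (v < t2)] = "flexible"
    out[(v >= t2) & (v < t3)] = "highly_flexible"
    out[v >= t3] = "disordered"
    return str(out[0]) if single else out


def neq_profile(
    matrix: EnsemblePBMatrix,
    table: PBPrototypeTable | None = None,
    min_models: int = DEFAULT_MIN_MODELS,
    thresholds: tuple[float, float, float] = DEFAULT_CLASS_THRESHOLDS,
) -> NeqProfile:
    """Frequencies -> N_eq -> class, for every position of a PB matrix."""
    prof = pb_frequencies(matrix, table=table, min_models=min_models)
    values = neq(prof.frequencies)
    return NeqProfile(
        positions=prof.positions,
        neq=values,
        classes=classify(values, thresholds),
        valid_model_count=prof.valid_model_count,
        resnames=prof.resnames,
    )


def frequency_table(prof: PBFrequencyProfile, neqp: NeqProfile | None = None) -> pd.DataFrame:
    """Per-position CSV-ready table: position, residue, count, f_a..f_p
    (+ N_eq and class when a profile is supplied) — the data behind a
    per-position PB logo."""
    data = {"position": prof.positions}
    if prof.resnames is not None:
        data["residue"] = prof.resnames
    data["valid_model_count"] = prof.valid_model_count
    for j, lab in enumerate(prof.alphabet):
        data[f"f_{lab}"] = prof.frequencies[:, j]
    df = pd.DataFrame(data)
    if neqp is not None:
        df["neq"] = neqp.neq
        df["class"] = neqp.classes
    return df


def distribution_summary(profile: NeqProfile, bin_width: float = 0.5, atol: float = 1e-9) -> dict:
    """Ensemble-level N_eq distribution summary.

    Returns fractions of defined positions that are fully rigid
    (N_eq = 1 within ``atol``), heterogeneous (N_eq > 2), and essentially
    disordered (N_eq > 8), plus a histogram of defined N_eq values with the
    given bin width.
    """
    vals = profile.neq[profile.defined]
    if vals.size == 0:
        raise EmptySummaryError("no defined N_eq positions")
    edges = np.arange(1.0, 16.0 + bin_width, bin_width)
    hist, _ = np.histogram(vals, bins=edges)
    return {
        "n_defined": int(vals.size),
        "fraction_rigid": float(np.mean(np.abs(vals - 1.0) <= atol)),
        "fraction_gt_2": float(np.mean(vals > 2.0)),
        "fraction_gt_8": float(np.mean(vals > 8.0)),
        "histogram_edges": edges,
        "histogram_counts": hist,
    }
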