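"""Parsers for per-residue disorder-prediction outputs.

Sequence-based disorder predictors emit one score in [0, 1] per residue;
some also emit a two-state order/disorder call.  This module normalises the
output dialects of four widely used predictors into a uniform
:class:`ScoreTrack`:

* **Disopred3** — whitespace-separated ``index residue mark score`` lines,
  where the mark is ``*`` (disordered) or ``.`` (ordered); ``#`` comments.
* **PrDOS** — CSV rows ``residue,score[,state]`` where ``residue`` is an
  amino-acid letter optionally fused with its position (``M1``) and the
  optional state column is 1/0 or D/O.
* **IUPred2A / ANCHOR2** — tab- or space-separated ``position residue
  score`` lines with ``#`` headers; a combined IUPred+ANCHOR long output
  carries the ANCHOR score in the last column, which :func:`read_anchor`
  picks up.

Parsers are deliberately permissive about comment/header lines (server
formats drift) but strict about malformed data rows, and never reorder or
renumber residues.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrackParseError",
    "ScoreTrack",
    "read_disopred",
    "read_prdos",
    "read_iupred",
    "read_anchor",
    "binarize",
    "write_track_csv",
    "read_track_csv",
]

DISORDERED = "D"
ORDERED = "O"


class TrackParseError(ValueError):
    """A predictor output file could not be parsed."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


@dataclass
class ScoreTrack:
    """Uniform per-residue disorder score track from one predictor.

    ``states`` holds 'D'/'O' per residue, or None when the predictor gave no
    two-state call.  Positions are 1-based and strictly increasing; gaps in
    numbering are preserved (alignment is handled downstream).
    """

    predictor: str
    positions: np.ndarray  # (n,) int
    residues: np.ndarray  # (n,) '<U1'
    scores: np.ndarray  # (n,) float in [0, 1]
    states: np.ndarray | None = field(default=None)  # (n,) '<U1' or None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.residues = np.asarray(self.residues, dtype="<U1")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.states is not None:
            self.states = np.asarray(self.states, dtype="<U1")
        n = len(self.positions)
        if not (len(self.residues) == len(self.scores) == n):
            raise ValueError("track fields must have equal length")
        if n == 0:
            raise TrackParseError("empty track")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self):
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "residue": self.residues,
                "score": self.scores,
                "state": self.states if self.states is not None else [""] * len(self),
                "predictor": self.predictor,
            }
        )


def _data_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith(">"):
            continue
        yield lineno, line


def _score(tok: str, lineno: int) -> float:
    try:
        val = float(tok)
    except ValueError:
        raise TrackParseError(f"bad score {tok!r}", lineno) from None
    if not 0.0 <= val <= 1.0:
        raise TrackParseError(f"score {val} outside [0, 1]", lineno)
    return val


def _build(predictor, rows, states=None) -> ScoreTrack:
    if not rows:
        raise TrackParseError(f"no data rows in {predictor} input")
    pos, res, sco = zip(*rows)
    return ScoreTrack(
        predictor=predictor,
        positions=np.array(pos),
        residues=np.array(res),
        scores=np.array(sco),
        states=None if states is None else np.array(states),
    )


def read_disopred(text: str) -> ScoreTrack:
    """Parse Disopred3 per-residue output (``index residue mark score``)."""
    rows, states = [], []
    for lineno, line in _data_lines(text):
        parts = line.split()
        if len(parts) != 4:
            raise TrackParseError("expected 'index residue mark score'", lineno)
        idx, aa, mark, score = parts
        if mark not in ("*", "."):
            raise TrackParseError(f"bad state mark {mark!r}", lineno)
        try:
            pos = int(idx)
        except ValueError:
            raise TrackParseError(f"bad residue index {idx!r}", lineno) from None
        rows.append((pos, aa, _score(score, lineno)))
        states.append(DISORDERED if mark == "*" else ORDERED)
    return _build("Disopred3", rows, states)


_PRDOS_RES = re.compile(r"^([A-Za-z])\s*(\d*)$")


def read_prdos(text: str) -> ScoreTrack:
    """Parse PrDOS CSV (``residue,score[,state]``)."""
    rows, states, have_state = [], [], False
    seq = 0
    for lineno, line in _data_lines(text):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) not in (2, 3):
            raise TrackParseError("expected 'residue,score[,state]'", lineno)
        m = _PRDOS_RES.match(parts[0])
        if not m:
            # header row such as 'residue,score' is tolerated once
            if seq == 0 and not rows:
                continue
            raise TrackParseError(f"bad residue field {parts[0]!r}", lineno)
        aa, num = m.groups()
        seq += 1
        pos = int(num) if num else seq
        rows.append((pos, aa, _score(parts[1], lineno)))
        if len(parts) == 3:
            have_state = True
            tok = parts[2].upper()
            if tok in ("1", "D"):
                states.append(DISORDERED)
            elif tok in ("0", "O"):
                states.append(ORDERED)
            else:
                raise TrackParseError(f"bad state {parts[2]!r}", lineno)
        else:
            states.append("")
    if have_state and "" in states:
        raise TrackParseError("state column present on only some rows")
    return _build("PrDOS", rows, states if have_state else None)


def _read_tabular(text: str, predictor: str, column: int) -> ScoreTrack:
    rows = []
    for lineno, line in _data_lines(text):
        parts = line.split()
        if len(parts) < 3:
            raise TrackParseError("expected 'position residue score'", lineno)
        try:
            pos = int(parts[0])
        except ValueError:
            raise TrackParseError(f"bad position {parts[0]!r}", lineno) from None
        col = column if column < len(parts) else len(parts) - 1
        rows.append((pos, parts[1], _score(parts[col], lineno)))
    return _build(predictor, rows)


def read_iupred(text: str) -> ScoreTrack:
    """Parse IUPred2A tab-separated output (``position residue score``);
    in combined IUPred+ANCHOR output the IUPred score is column 3."""
    return _read_tabular(text, "IUPred2A", column=2)


def read_anchor(text: str) -> ScoreTrack:
    """Parse ANCHOR2 output; in combined IUPred+ANCHOR output the ANCHOR
    score is the last column."""
    return _read_tabular(text, "ANCHOR2", column=3)


def binarize(track: ScoreTrack, threshold: float = 0.5, override: bool = False) -> ScoreTrack:
    """Set two-state calls: disordered iff score >= threshold.

    Native states (e.g. Disopred3's marks) are preserved unless ``override``
    is requested.  Returns a new track.
    """
    if track.states is not None and not override:
        return replace(track)
    states = np.where(track.scores >= threshold, DISORDERED, ORDERED).astype("<U1")
    return replace(track, states=states)


def write_track_csv(track: ScoreTrack) -> str:
    """Serialise a track to the internal CSV dialect (round-trips exactly)."""
    buf = io.StringIO()
    track.to_frame().to_csv(buf, index=False, float_format="%.17g")
    return buf.getvalue()


def read_track_csv(text: str) -> ScoreTrack:
    """Read the internal track CSV written by :func:`write_track_csv`."""
    df = pd.read_csv(io.StringIO(text), keep_default_na=False)
    states = df["state"].astype(str).to_numpy()
    has_states = bool(np.all(np.isin(states, (DISORDERED, ORDERED))))
    return ScoreTrack(
        predictor=str(df["predictor"].iloc[0]),
        positions=df["position"].to_numpy(),
        residues=df["residue"].astype(str).to_numpy(),
        scores=df["score"].to_numpy(),
        states=states if has_states else None,
    )
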