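"""Synthetic ensembles with known PB mixtures and predictor-like tracks.

Real conformational ensembles of disordered proteins come with unknown
ground truth; this generator builds ensembles whose per-position PB
composition — and hence true N_eq — is known exactly, plus disorder-score
tracks with a controlled correlation to that truth, so every stage of the
pipeline can be tested end to end without external data.

Label sampling and backbone realisation
---------------------------------------
Each position carries a target mixture over the 16 PBs; labels are drawn
independently per model.  Realising an arbitrary label sequence as one
continuous backbone is impossible, because adjacent five-residue PB windows
share six of their eight dihedrals: only a repetitive block could coexist
with itself, and independent neighbours destroy nearest-prototype recovery
(measured at ~18% for mixed positions).  The generator instead realises
each sampled label as a self-contained five-residue fragment: the eight
window dihedrals are exactly the internal coordinates needed to build a
five-residue backbone (N-CA 1.46 A, CA-C 1.52 A, C-N 1.33 A, standard bond
angles, omega = 180), so the fragment's central residue reproduces the
prototype window exactly (plus the requested angular noise).  Fragments are
translated far apart, so the C-N > 2.5 A chain-break rule invalidates every
window that would straddle two fragments.

Probe offsets rotate across models (model k realises positions
p = first + (k mod 5), p + 5, ...), so over M models every interior
position accumulates about M/5 valid observations drawn from its own
mixture.  Bookkeeping records exactly which label was realised where; the
empirical mixture over realised cells is the oracle for recovery and N_eq
tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .pb_alphabet import (
    UNDEFINED_LABEL,
    WINDOW_SIZE,
    PBPrototypeTable,
    normalize_angle,
)
from .neq_profile import EnsemblePBMatrix, NeqProfile, classify, neq
from .predictor_io import ScoreTrack

__all__ = [
    "PositionSpec",
    "EnsembleSpec",
    "SimulatedEnsemble",
    "ped_like_spec",
    "sample_pb_matrix",
    "build_backbone",
    "simulate_ensemble",
    "synth_score_track",
    "write_disopred_text",
    "write_prdos_csv",
    "write_iupred_text",
]

#: Backbone bond lengths (Angstrom) and angles (degrees) for chain building.
BOND_LENGTHS = {"N-CA": 1.46, "CA-C": 1.52, "C-N": 1.33}
BOND_ANGLES = {"N-CA-C": 111.0, "CA-C-N": 117.2, "C-N-CA": 121.7}
OMEGA = 180.0

#: Spacing between probe positions within one model (the PB window size).
PROBE_SPACING = WINDOW_SIZE

#: Spatial separation between consecutive fragments (Angstrom); far beyond
#: the 2.5 A break cutoff so inter-fragment windows are always invalid.
FRAGMENT_SPACING = 50.0

DEFAULT_SIGMA = 5.0


class SpecError(ValueError):
    """An ensemble or position specification is invalid."""


@dataclass
class PositionSpec:
    """Target PB mixture at one position.

    ``mixture`` maps PB labels to fractions summing to 1;  ``sigma`` is the
    s.d. (degrees) of the wrapped Gaussian noise added to each window
    dihedral when the position is realised in a backbone.
    """

    position: int
    mixture: dict
    sigma: float = DEFAULT_SIGMA

    def validate(self, table: PBPrototypeTable):
        if self.sigma < 0:
            raise SpecError("sigma must be >= 0")
        tot = 0.0
        for lab, f in self.mixture.items():
            if lab not in table.labels:
                raise SpecError(f"unknown PB label {lab!r}")
            if f < 0:
                raise SpecError("mixture fractions must be >= 0")
            tot += f
        if abs(tot - 1.0) > 1e-9:
            raise SpecError(f"mixture at position {self.position} sums to {tot}")

    def probabilities(self, table: PBPrototypeTable) -> np.ndarray:
        p = np.zeros(table.size)
        for lab, f in self.mixture.items():
            p[table.index(lab)] = f
        return p

    def analytic_neq(self) -> float:
        f = np.array(list(self.mixture.values()), dtype=float)
        f = f[f > 0]
        return float(np.exp(-(f * np.log(f)).sum()))


@dataclass
class EnsembleSpec:
    """Blueprint of a synthetic ensemble.

    ``positions`` lists the interior positions that carry a mixture; any
    interior position not listed stays undefined.  ``length`` must be >= 7
    so at least one complete interior window exists.
    """

    length: int
    n_models: int
    positions: list  # list[PositionSpec]
    seed: int = 0

    def validate(self, table: PBPrototypeTable):
        if self.length < 7:
            raise SpecError("length must be >= 7")
        if self.n_models < 2:
            raise SpecError("need at least 2 models")
        seen = set()
        for ps in self.positions:
            if not (3 <= ps.position <= self.length - 2):
                raise SpecError(
                    f"position {ps.position} has no complete window in a "
                    f"chain of length {self.length}"
                )
            if ps.position in seen:
                raise SpecError(f"duplicate position {ps.position}")
            seen.add(ps.position)
            ps.validate(table)


def ped_like_spec(
    length: int = 60,
    n_models: int = 200,
    seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
    rigid_fraction: float = 0.58,
    gt2_fraction: float = 0.36,
    gt8_fraction: float = 0.15,
    table: PBPrototypeTable | None = None,
) -> EnsembleSpec:
    """Default study conditions: a disordered-ensemble-like N_eq continuum.

    Interior positions are assigned mixtures so that about 58% are fully
    rigid (one PB, N_eq = 1), 36% have N_eq > 2 of which 15% exceed 8
    (near-uniform usage), and the small remainder sits in (1, 2] — the
    distribution shape characteristic of ensembles of disordered proteins,
    where entirely rigid positions coexist with a long flexibility tail.
    Mixtures are built from k equally weighted blocks (N_eq = k exactly)
    with k drawn per category, plus two-block mixtures for the (1, 2] band.
    """
    if table is None:
        table = PBPrototypeTable.default()
    if not 0 <= rigid_fraction <= 1 or gt2_fraction + rigid_fraction > 1:
        raise SpecError("inconsistent category fractions")
    rng = np.random.default_rng(seed)
    interior = list(range(3, length - 1))
    specs = []
    mid_fraction = gt2_fraction - gt8_fraction  # N_eq in (2, 8]
    if mid_fraction < 0:
        raise SpecError("gt8_fraction cannot exceed gt2_fraction")
    for pos in interior:
        u = rng.random()
        if u < rigid_fraction:
            labs = [table.labels[rng.integers(table.size)]]
            weights = [1.0]
        elif u < rigid_fraction + gt8_fraction:
            k = int(rng.integers(9, table.size + 1))
            labs = list(rng.choice(table.labels, size=k, replace=False))
            weights = [1.0 / k] * k
        elif u < rigid_fraction + gt8_fraction + mid_fraction:
            k = int(rng.integers(3, 9))
            labs = list(rng.choice(table.labels, size=k, replace=False))
            weights = [1.0 / k] * k
        else:  # N_eq in (1, 2]
            labs = list(rng.choice(table.labels, size=2, replace=False))
            w = float(rng.uniform(0.5, 0.9))
            weights = [w, 1.0 - w]
        specs.append(
            PositionSpec(position=pos, mixture=dict(zip(labs, weights)), sigma=sigma)
        )
    return EnsembleSpec(
        length=length, n_models=n_models, positions=specs, seed=int(seed)
    )


@dataclass
class SampledMatrix:
    """A sampled PB matrix plus the generator's truth bookkeeping."""

    matrix: EnsemblePBMatrix
    empirical_frequencies: np.ndarray = field(repr=False)  # (L, 16)
    empirical_neq: np.ndarray = None  # (L,)
    target_neq: np.ndarray = None  # (L,)


def _empirical(labels: np.ndarray, table: PBPrototypeTable):
    """Empirical per-position frequencies and N_eq over non-Z cells."""
    L = labels.shape[0]
    freqs = np.full((L, table.size), np.nan)
    nq = np.full(L, np.nan)
    for i in range(L):
        cells = labels[i][labels[i] != UNDEFINED_LABEL]
        if cells.size == 0:
            continue
        counts = np.array([(cells == lab).sum() for lab in table.labels], float)
        freqs[i] = counts / counts.sum()
        nq[i] = neq(freqs[i])
    return freqs, nq


def sample_pb_matrix(
    spec: EnsembleSpec, table: PBPrototypeTable | None = None
) -> SampledMatrix:
    """Draw a PB label per (position, model) from each position's mixture.

    Cells at unspecified positions are ``Z``.  Bookkeeping records the
    empirical mixtures (the oracle for downstream N_eq checks) and each
    position's analytic target N_eq.
    """
    if table is None:
        table = PBPrototypeTable.default()
    spec.validate(table)
    rng = np.random.default_rng(spec.seed)
    labels = np.full((spec.length, spec.n_models), UNDEFINED_LABEL, dtype="<U1")
    target = np.full(spec.length, np.nan)
    lab_arr = np.array(table.labels, dtype="<U1")
    for ps in spec.positions:
        p = ps.probabilities(table)
        draws = rng.choice(table.size, size=spec.n_models, p=p)
        labels[ps.position - 1] = lab_arr[draws]
        target[ps.position - 1] = ps.analytic_neq()
    freqs, nq = _empirical(labels, table)
    return SampledMatrix(
        matrix=EnsemblePBMatrix(labels=labels),
        empirical_frequencies=freqs,
        empirical_neq=nq,
        target_neq=target,
    )


# ---------------------------------------------------------------------------
# internal-to-Cartesian backbone construction (NeRF)
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d given three predecessors, bond c-d, angle b-c-d and
    torsion a-b-c-d (natural extension of reference frame)."""
    ang = np.deg2rad(180.0 - angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def _fragment_coords(window: np.ndarray) -> np.ndarray:
    """Build the 15 backbone atoms (N, CA, C per residue) of a five-residue
    fragment from its 8 window dihedrals (psi1, phi2, psi2, ..., phi5).

    The window layout of a PB prototype is exactly the set of internal
    torsions needed: after seeding the first residue, each subsequent atom
    consumes psi(i) (places N(i+1)), omega (places CA(i+1)) or phi(i+1)
    (places C(i+1)).
    """
    nca, cac, cn = BOND_LENGTHS["N-CA"], BOND_LENGTHS["CA-C"], BOND_LENGTHS["C-N"]
    a_ncac = BOND_ANGLES["N-CA-C"]
    a_cacn = BOND_ANGLES["CA-C-N"]
    a_cnca = BOND_ANGLES["C-N-CA"]
    atoms = np.empty((3 * WINDOW_SIZE, 3))
    # seed residue 1: N at origin, CA on x, C in the xy-plane
    atoms[0] = (0.0, 0.0, 0.0)
    atoms[1] = (nca, 0.0, 0.0)
    ang = np.deg2rad(180.0 - a_ncac)
    atoms[2] = atoms[1] + cac * np.array([np.cos(ang), np.sin(ang), 0.0])
    torsions = iter(window)
    k = 3
    for res in range(1, WINDOW_SIZE):
        psi = next(torsions)
        atoms[k] = _place_atom(atoms[k - 3], atoms[k - 2], atoms[k - 1], cn, a_cacn, psi)
        atoms[k + 1] = _place_atom(atoms[k - 2], atoms[k - 1], atoms[k], nca, a_cnca, OMEGA)
        phi = next(torsions)
        atoms[k + 2] = _place_atom(atoms[k - 1], atoms[k], atoms[k + 1], cac, a_ncac, phi)
        k += 3
    return atoms


_PDB_ATOM = (
    "ATOM  {serial:>5d}  {name:<3s}{resname:>4s} {chain}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def build_backbone(
    labels_per_model: list,
    table: PBPrototypeTable | None = None,
    sigma: float = DEFAULT_SIGMA,
    rng: np.random.Generator | None = None,
    length: int | None = None,
    chain_id: str = "A",
) -> str:
    """Emit a multi-model PDB realising per-model probe labels as fragments.

    ``labels_per_model`` is a list (one entry per model) of mappings
    ``{position: label}``; positions within one model must be at least 5
    apart so their five-residue fragments do not overlap.  Each fragment is
    built from the label's prototype window plus wrapped Gaussian noise of
    s.d. ``sigma`` and translated to its own location in space, so windows
    between fragments are invalid under the chain-break rule.  All residues
    are emitted as ALA (assignment uses backbone atoms only).
    """
    if table is None:
        table = PBPrototypeTable.default()
    if rng is None:
        rng = np.random.default_rng()
    out = io.StringIO()
    out.write("REMARK synthetic PB-fragment ensemble\n")
    for k, probes in enumerate(labels_per_model, start=1):
        positions = sorted(probes)
        if any(b - a < PROBE_SPACING for a, b in zip(positions, positions[1:])):
            raise SpecError("probe positions within one model must be >= 5 apart")
        if positions and positions[0] - 2 < 1:
            raise SpecError("probe fragment extends before residue 1")
        if length is not None and positions and positions[-1] + 2 > length:
            raise SpecError("probe fragment extends past the chain length")
        out.write(f"MODEL     {k:>4d}\n")
        serial = 1
        for frag_idx, pos in enumerate(positions):
            proto = table.angles[table.index(probes[pos])]
            window = normalize_angle(proto + rng.normal(0.0, sigma, size=proto.shape))
            coords = _fragment_coords(window)
            coords = coords + np.array([frag_idx * FRAGMENT_SPACING, 0.0, 0.0])
            for r in range(WINDOW_SIZE):
                resseq = pos - 2 + r
                for j, name in enumerate(("N", "CA", "C")):
                    x, y, z = coords[3 * r + j]
                    out.write(
                        _PDB_ATOM.format(
                            serial=serial,
                            name=name,
                            resname="ALA",
                            chain=chain_id,
                            resseq=resseq,
                            x=x,
                            y=y,
                            z=z,
                            occ=1.0,
                            b=0.0,
                            element=name[0],
                        )
                    )
                    serial += 1
        out.write("ENDMDL\n")
    out.write("END\n")
    return out.getvalue()


@dataclass
class SimulatedEnsemble:
    """A generated ensemble with full ground truth.

    ``truth_labels`` holds the realised label at every (position, model)
    cell that appears in the PDB, ``Z`` elsewhere; ``empirical_frequencies``
    and ``empirical_neq`` summarise those realised cells and are the oracle
    against which the recomputed pipeline output is compared.
    """

    spec: EnsembleSpec
    pdb_text: str = field(repr=False)
    truth_labels: np.ndarray = field(repr=False)  # (L, M)
    empirical_frequencies: np.ndarray = field(repr=False)
    empirical_neq: np.ndarray = None
    target_neq: np.ndarray = None

    def truth_profile(self) -> NeqProfile:
        return NeqProfile(
            positions=np.arange(1, self.spec.length + 1),
            neq=self.empirical_neq,
            classes=classify(self.empirical_neq),
            valid_model_count=np.sum(self.truth_labels != UNDEFINED_LABEL, axis=1),
        )


def simulate_ensemble(
    spec: EnsembleSpec, table: PBPrototypeTable | None = None
) -> SimulatedEnsemble:
    """Full generator: sample labels, realise them, emit PDB + truth tables.

    Model k realises the specified positions congruent to ``first + k mod
    5`` (rotating probe offsets), so every specified position is realised in
    about one model in five and all positions accumulate observations.
    """
    if table is None:
        table = PBPrototypeTable.default()
    spec.validate(table)
    rng = np.random.default_rng(spec.seed)
    by_pos = {ps.position: ps for ps in spec.positions}
    first = min(by_pos) if by_pos else 3
    L, M = spec.length, spec.n_models
    truth = np.full((L, M), UNDEFINED_LABEL, dtype="<U1")
    lab_arr = np.array(table.labels, dtype="<U1")
    labels_per_model = []
    for k in range(M):
        offset = k % PROBE_SPACING
        probes = {}
        for pos in range(first + offset, L - 1, PROBE_SPACING):
            ps = by_pos.get(pos)
            if ps is None:
                continue
            p = ps.probabilities(table)
            lab = lab_arr[rng.choice(table.size, p=p)]
            probes[pos] = str(lab)
            truth[pos - 1, k] = lab
        labels_per_model.append(probes)
    sigmas = {ps.sigma for ps in spec.positions}
    sigma = sigmas.pop() if len(sigmas) == 1 else DEFAULT_SIGMA
    pdb_text = build_backbone(
        labels_per_model, table=table, sigma=sigma, rng=rng, length=L
    )
    freqs, nq = _empirical(truth, table)
    target = np.full(L, np.nan)
    for ps in spec.positions:
        target[ps.position - 1] = ps.analytic_neq()
    return SimulatedEnsemble(
        spec=spec,
        pdb_text=pdb_text,
        truth_labels=truth,
        empirical_frequencies=freqs,
        empirical_neq=nq,
        target_neq=target,
    )


# ---------------------------------------------------------------------------
# synthetic predictor tracks
# ---------------------------------------------------------------------------

def synth_score_track(
    neq_values,
    target_correlation: float,
    seed: int = 0,
    predictor: str = "synthetic",
    positions=None,
    center: float = 0.5,
    scale: float = 0.15,
) -> ScoreTrack:
    """A score track correlated with an N_eq profile at a chosen level.

    Scores are ``clamp_[0,1](center + scale * (rho * z + sqrt(1-rho^2) *
    eps))`` with ``z`` the standardised N_eq and ``eps`` standard normal
    noise.  With the default affine map, clamping affects well under 1% of
    positions, so the measured Pearson correlation converges to ``rho`` as
    the track length grows.  Positions with undefined N_eq are skipped.
    """
    rho = float(target_correlation)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    vals = np.asarray(neq_values, dtype=float)
    if positions is None:
        positions = np.arange(1, len(vals) + 1)
    positions = np.asarray(positions, dtype=int)
    ok = np.isfinite(vals)
    vals, positions = vals[ok], positions[ok]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("need at least two distinct defined N_eq values")
    rng = np.random.default_rng(seed)
    z = (vals - vals.mean()) / vals.std()
    eps = rng.standard_normal(vals.size)
    raw = center + scale * (rho * z + np.sqrt(1.0 - rho**2) * eps)
    scores = np.clip(raw, 0.0, 1.0)
    return ScoreTrack(
        predictor=predictor,
        positions=positions,
        residues=np.full(vals.size, "A"),
        scores=scores,
    )


def write_disopred_text(track: ScoreTrack, threshold: float = 0.5) -> str:
    """Serialise a track in the Disopred3 per-residue dialect."""
    lines = ["#         ----- DISOPRED version 3.1 -----"]
    states = track.states
    for i in range(len(track)):
        if states is not None:
            mark = "*" if states[i] == "D" else "."
        else:
            mark = "*" if track.scores[i] >= threshold else "."
        lines.append(
            f"{track.positions[i]:>5d} {track.residues[i]} {mark} {track.scores[i]:4.2f}"
        )
    return "\n".join(lines) + "\n"


def write_prdos_csv(track: ScoreTrack) -> str:
    """Serialise a track in the PrDOS CSV dialect (residue,score[,state])."""
    lines = []
    for i in range(len(track)):
        row = f"{track.residues[i]}{track.positions[i]},{track.scores[i]:.3f}"
        if track.states is not None:
            row += f",{1 if track.states[i] == 'D' else 0}"
        lines.append(row)
    return "\n".join(lines) + "\n"


def write_iupred_text(track: ScoreTrack) -> str:
    """Serialise a track in the IUPred2A tab-separated dialect."""
    lines = ["# POS\tRES\tIUPRED2"]
    for i in range(len(track)):
        lines.append(
            f"{track.positions[i]}\t{track.residues[i]}\t{track.scores[i]:.4f}"
        )
    return "\n".join(lines) + "\n"
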