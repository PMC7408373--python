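"""Multi-model PDB ensembles: backbone extraction and phi/psi dihedrals.

Conformational ensembles (NMR, ensemble-restrained MD, SAXS-refined models,
as deposited e.g. in the Protein Ensemble Database) arrive as multi-model PDB
files.  This module reads one chain across all models, keeps only the
backbone atoms N/CA/C needed for dihedral work, and computes per-residue
phi/psi angles with NaN wherever an angle is undefined: chain termini,
residues missing backbone atoms, and chain breaks (non-consecutive residue
numbering or a C(i)-N(i+1) distance above 2.5 A — missing residues are the
typical crystallographic signature of disorder and must not generate
spurious dihedrals across the gap).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .pb_alphabet import normalize_angle

__all__ = [
    "EmptyEnsembleError",
    "BackboneModel",
    "EnsembleDihedrals",
    "CHAIN_BREAK_CN_CUTOFF",
    "BACKBONE_ATOMS",
    "read_ensemble",
    "dihedral",
    "compute_dihedrals",
]

logger = logging.getLogger(__name__)

#: Maximum peptide-bond C(i)-N(i+1) distance (Angstrom); beyond it the chain
#: is treated as broken.
CHAIN_BREAK_CN_CUTOFF = 2.5

BACKBONE_ATOMS = ("N", "CA", "C")


class EmptyEnsembleError(ValueError):
    """No parsable ATOM records / no models found in the input."""


@dataclass
class BackboneModel:
    """Backbone of one chain in one ensemble model.

    ``coords`` is an (L, 3, 3) array: residue x atom (N, CA, C) x (x, y, z),
    NaN for atoms absent in this model.  ``complete`` flags residues with all
    three backbone atoms present.  Residue order follows the shared ensemble
    numbering (union over models); residues absent from this model are rows
    of NaN with ``present`` False.
    """

    model_id: int
    chain_id: str
    resids: np.ndarray  # (L,) int author residue numbers
    resnames: np.ndarray  # (L,) 3-letter codes
    coords: np.ndarray = field(repr=False)  # (L, 3, 3)
    present: np.ndarray = field(repr=False)  # (L,) bool, residue in this model
    complete: np.ndarray = field(repr=False)  # (L,) bool, N+CA+C all present

    def __len__(self):
        return len(self.resids)


@dataclass
class EnsembleDihedrals:
    """Per-model phi/psi tracks over a shared residue index.

    ``phi`` and ``psi`` are (M, L) arrays in degrees, NaN where undefined.
    ``positions`` is the shared 1-based sequential index used to align with
    per-residue predictor tracks; ``resids`` keeps the author numbering.
    """

    positions: np.ndarray  # (L,) 1-based sequential
    resids: np.ndarray  # (L,)
    resnames: np.ndarray  # (L,)
    phi: np.ndarray = field(repr=False)  # (M, L)
    psi: np.ndarray = field(repr=False)  # (M, L)

    @property
    def n_models(self) -> int:
        return self.phi.shape[0]

    def __len__(self):
        return self.phi.shape[1]


def _residue_key(res):
    # order insertion codes after their base number
    _, resseq, icode = res.id
    return (resseq, icode)


def read_ensemble(pdb_text: str, chain: str | None = None) -> list[BackboneModel]:
    """Parse a multi-model PDB into per-model backbones of one chain.

    Parameters
    ----------
    pdb_text : str
        PDB file content (MODEL/ENDMDL blocks, or a single implicit model).
    chain : str, optional
        Chain identifier; by default the first chain of the first model.

    Notes
    -----
    Only ATOM-style amino-acid records contribute (waters and ligands are
    skipped; non-standard residues are kept when they carry N/CA/C).
    Alternate locations resolve to the highest-occupancy conformer.  Models
    with differing residue sets are reconciled to the union, with per-model
    gaps; a warning is logged when that happens.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("ensemble", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise EmptyEnsembleError("no models found in PDB input")

    if chain is None:
        chains = [c.id for c in models[0]]
        if not chains:
            raise EmptyEnsembleError("first model contains no chains")
        chain = chains[0]

    def usable(res):
        het = res.id[0]
        if het == " ":
            return True
        if het == "W" or not het.startswith("H_"):
            return False
        return all(res.has_id(a) for a in BACKBONE_ATOMS)

    per_model: list[tuple[int, dict]] = []
    keys_per_model = []
    for m in models:
        if chain not in [c.id for c in m]:
            continue
        residues = {}
        for res in m[chain]:
            if not usable(res):
                continue
            residues[_residue_key(res)] = res
        if residues:
            per_model.append((m.id, residues))
            keys_per_model.append(set(residues))
    if not per_model:
        raise EmptyEnsembleError(f"no parsable ATOM records for chain {chain!r}")

    union = sorted(set().union(*keys_per_model))
    if any(k != set(union) for k in keys_per_model):
        logger.warning(
            "models cover different residue ranges; reconciled to the union "
            "(%d residues) with per-model gaps", len(union)
        )

    resids = np.array([k[0] for k in union], dtype=int)
    out = []
    for model_id, residues in per_model:
        L = len(union)
        coords = np.full((L, 3, 3), np.nan)
        present = np.zeros(L, dtype=bool)
        complete = np.zeros(L, dtype=bool)
        resnames = np.array(["UNK"] * L, dtype="<U3")
        for i, key in enumerate(union):
            res = residues.get(key)
            if res is None:
                continue
            present[i] = True
            resnames[i] = res.get_resname()
            have = True
            for j, name in enumerate(BACKBONE_ATOMS):
                if res.has_id(name):
                    # Biopython resolves altlocs to the highest-occupancy atom
                    coords[i, j] = res[name].get_coord()
                else:
                    have = False
            complete[i] = have
        out.append(
            BackboneModel(
                model_id=model_id,
                chain_id=chain,
                resids=resids,
                resnames=resnames,
                coords=coords,
                present=present,
                complete=complete,
            )
        )
    return out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, in (-180, 180]) defined by four points.

    Standard atan2 construction on the two plane normals.  Degenerate
    geometry (zero-length or exactly collinear difference vectors) yields
    NaN, which downstream code treats as an undefined angle.
    """
    return float(_dihedral_batch(*(np.asarray(p, float)[np.newaxis] for p in (p1, p2, p3, p4)))[0])


def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized torsion over (..., 3) point arrays; NaN where degenerate."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., np.newaxis]), axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    bad = (
        (np.linalg.norm(n1, axis=-1) < 1e-9)
        | (np.linalg.norm(n2, axis=-1) < 1e-9)
        | (b2n < 1e-9)
    )
    ang = np.where(bad, np.nan, ang)
    return normalize_angle(ang)


def _break_after(model: BackboneModel) -> np.ndarray:
    """Boolean (L-1,) array: break between residue i and i+1 of this model."""
    resids = model.resids
    nonconsec = np.diff(resids) != 1
    c_i = model.coords[:-1, 2]  # C of residue i
    n_next = model.coords[1:, 0]  # N of residue i+1
    with np.errstate(invalid="ignore"):
        dist = np.linalg.norm(n_next - c_i, axis=-1)
    geom_break = ~np.isfinite(dist) | (dist > CHAIN_BREAK_CN_CUTOFF)
    return nonconsec | geom_break


def compute_dihedrals(models: list[BackboneModel]) -> EnsembleDihedrals:
    """phi/psi per residue per model, NaN at termini, gaps and chain breaks.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1).  An angle is undefined when any contributing residue is
    incomplete or the peptide bond it crosses is broken.
    """
    if not models:
        raise EmptyEnsembleError("compute_dihedrals needs at least one model")
    L = len(models[0])
    M = len(models)
    phi = np.full((M, L), np.nan)
    psi = np.full((M, L), np.nan)
    for k, model in enumerate(models):
        if len(model) != L:
            raise ValueError("models must share the reconciled residue index")
        ok = model.complete
        brk = _break_after(model)
        N, CA, C = model.coords[:, 0], model.coords[:, 1], model.coords[:, 2]
        # phi over residues 1..L-1 (0-based)
        good = ok[:-1] & ok[1:] & ~brk
        idx = np.nonzero(good)[0]
        if idx.size:
            phi[k, idx + 1] = _dihedral_batch(C[idx], N[idx + 1], CA[idx + 1], C[idx + 1])
        # psi over residues 0..L-2
        if idx.size:
            psi[k, idx] = _dihedral_batch(N[idx], CA[idx], C[idx], N[idx + 1])
    first = models[0]
    resnames = first.resnames.copy()
    for model in models[1:]:
        missing = resnames == "UNK"
        if not missing.any():
            break
        resnames[missing] = model.resnames[missing]
    return EnsembleDihedrals(
        positions=np.arange(1, L + 1),
        resids=first.resids.copy(),
        resnames=resnames,
        phi=phi,
        psi=psi,
    )
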