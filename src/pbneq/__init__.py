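"""pbneq: protein-block entropy (N_eq) analysis of conformational ensembles.

Assigns the 16-letter protein-block structural alphabet to every model of a
multi-model PDB ensemble, computes the per-position N_eq entropy index
(exp of the Shannon entropy of PB usage: 1 = rigid, 16 = maximally
heterogeneous), classifies positions on the rigid-flexible-disordered
continuum, and compares the resulting profile with per-residue disorder
predictions (Disopred3, PrDOS, IUPred2A, ANCHOR2 output dialects).
"""

from .pb_alphabet import (
    PBPrototypeTable,
    angular_distance,
    assign_pb,
    assign_sequence,
    rmsda,
    separation_matrix,
    UNDEFINED_LABEL,
)
from .ensemble_io import (
    BackboneModel,
    EnsembleDihedrals,
    compute_dihedrals,
    dihedral,
    read_ensemble,
)
from .neq_profile import (
    EnsemblePBMatrix,
    NeqProfile,
    PBFrequencyProfile,
    classify,
    distribution_summary,
    frequency_table,
    neq,
    neq_profile,
    pb_frequencies,
)
from .predictor_io import (
    ScoreTrack,
    binarize,
    read_anchor,
    read_disopred,
    read_iupred,
    read_prdos,
    read_track_csv,
    write_track_csv,
)
from .comparison import (
    ComparisonReport,
    PairedSeries,
    class_binned_averages,
    compare,
    correlation,
    pair,
    prediction_rate_sweep,
    stratified_means,
    two_state_overlap,
)
from .synthetic import (
    EnsembleSpec,
    PositionSpec,
    build_backbone,
    ped_like_spec,
    sample_pb_matrix,
    simulate_ensemble,
    synth_score_track,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def assign_ensemble(pdb_text: str, chain: str | None = None, table=None) -> EnsemblePBMatrix:
    """Convenience: PDB text -> per-model PB label matrix."""
    if table is None:
        table = PBPrototypeTable.default()
    models = read_ensemble(pdb_text, chain=chain)
    dih = compute_dihedrals(models)
    return EnsemblePBMatrix.from_dihedrals(dih, table)
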