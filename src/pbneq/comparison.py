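"""Comparing ensemble-derived N_eq with disorder-prediction score tracks.

The flexibility index N_eq and a predictor's per-residue score measure
related but distinct things; this module implements the comparison battery:

* continuous Pearson correlation between paired N_eq and score series
  (and between two score tracks);
* mean predictor score stratified by N_eq regime (< 4, 4-8, > 8);
* class-binned averages over twelve N_eq classes [1,2), [2,3), ...,
  [11,12), [12,16], with the correlation recomputed at class level
  (aggregation suppresses per-position noise, so class-level correlations
  exceed pair-level ones for a noisy monotone relationship);
* two-state agreement between predictors, decomposed into common-disorder
  and common-order fractions;
* a prediction-rate sweep: for each N_eq threshold t in 1..12, the "true"
  state of a position is disordered iff N_eq > t, and the rate is the
  fraction of positions where the predictor's two-state call matches that
  truth.  A position with N_eq exactly t counts as ordered, so at t = 1 all
  fully rigid positions (N_eq = 1) are ordered.

All statistics use only positions where both members are defined; dropped
positions are counted and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .neq_profile import NeqProfile
from .predictor_io import DISORDERED, ScoreTrack

__all__ = [
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "AlignmentError",
    "PairedSeries",
    "ComparisonReport",
    "pair",
    "align_tracks",
    "correlation",
    "stratified_means",
    "class_binned_averages",
    "two_state_overlap",
    "prediction_rate_sweep",
    "compare",
    "DEFAULT_SWEEP_THRESHOLDS",
    "NEQ_CLASS_EDGES",
]

#: N_eq thresholds for the prediction-rate sweep (Figure-4-style evaluation).
DEFAULT_SWEEP_THRESHOLDS = tuple(float(t) for t in range(1, 13))

#: Bin edges of the twelve N_eq classes: [1,2), ..., [11,12), [12,16].
NEQ_CLASS_EDGES = tuple(float(t) for t in range(1, 13)) + (16.0,)


class InsufficientDataError(ValueError):
    """Too few paired observations for the requested statistic."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (a constant series)."""


class AlignmentError(ValueError):
    """Two tracks could not be aligned position-wise."""


@dataclass
class PairedSeries:
    """Positionally paired (N_eq, score) observations."""

    positions: np.ndarray
    neq: np.ndarray
    scores: np.ndarray
    n_dropped: int = 0
    predictor: str = ""

    def __len__(self):
        return len(self.positions)


def pair(neqp: NeqProfile, track: ScoreTrack, offset: int = 0) -> PairedSeries:
    """Pair N_eq with predictor scores at shared positions.

    ``offset`` is added to track positions before matching (for tracks
    numbered relative to a different construct start).  Positions where
    either member is undefined are dropped and counted.
    """
    pos_n = neqp.positions[neqp.defined]
    val_n = neqp.neq[neqp.defined]
    pos_t = track.positions + offset
    common, ia, ib = np.intersect1d(pos_n, pos_t, return_indices=True)
    n_total = len(np.union1d(neqp.positions, pos_t))
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} paired positions (need >= 3)"
        )
    return PairedSeries(
        positions=common,
        neq=val_n[ia],
        scores=track.scores[ib],
        n_dropped=int(n_total - len(common)),
        predictor=track.predictor,
    )


def correlation(series: PairedSeries | tuple) -> float:
    """Pearson product-moment correlation of the two continuous series."""
    if isinstance(series, PairedSeries):
        x, y = series.neq, series.scores
    else:
        x, y = (np.asarray(v, dtype=float) for v in series)
    if len(x) < 3:
        raise InsufficientDataError("correlation needs >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant series")
    return float(sps.pearsonr(x, y).statistic)


def stratified_means(
    series: PairedSeries, cutpoints: tuple[float, float] = (4.0, 8.0)
) -> pd.DataFrame:
    """Mean predictor score in the rigid (< c1), intermediate ([c1, c2]) and
    disordered (> c2) N_eq strata; empty strata get count 0 and NaN mean."""
    c1, c2 = cutpoints
    if not c1 < c2:
        raise ValueError("cutpoints must be increasing")
    masks = {
        f"neq<{c1:g}": series.neq < c1,
        f"{c1:g}<=neq<={c2:g}": (series.neq >= c1) & (series.neq <= c2),
        f"neq>{c2:g}": series.neq > c2,
    }
    rows = [
        {
            "stratum": name,
            "count": int(m.sum()),
            "mean_score": float(series.scores[m].mean()) if m.any() else np.nan,
        }
        for name, m in masks.items()
    ]
    return pd.DataFrame(rows)


def class_binned_averages(series: PairedSeries) -> tuple[pd.DataFrame, float]:
    """Average score per N_eq class, plus the class-level correlation.

    N_eq values are binned into the twelve classes of
    :data:`NEQ_CLASS_EDGES`; the correlation is the Pearson correlation
    between the class lower bound and the class mean score over populated
    classes (at least 3 required).
    """
    edges = np.array(NEQ_CLASS_EDGES)
    lowers = edges[:-1]
    idx = np.digitize(series.neq, edges[1:-1], right=False)  # 0..11
    rows = []
    for k, lo in enumerate(lowers):
        m = idx == k
        rows.append(
            {
                "class_lower": float(lo),
                "count": int(m.sum()),
                "mean_score": float(series.scores[m].mean()) if m.any() else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    pop = df["count"] > 0
    if pop.sum() < 3:
        raise InsufficientDataError("fewer than 3 populated N_eq classes")
    r = correlation((df.loc[pop, "class_lower"], df.loc[pop, "mean_score"]))
    return df, r


def align_tracks(a: ScoreTrack, b: ScoreTrack) -> np.ndarray:
    """Indices (ia, ib) of positions shared by two tracks."""
    common, ia, ib = np.intersect1d(a.positions, b.positions, return_indices=True)
    if len(common) == 0:
        raise AlignmentError("tracks share no positions")
    return ia, ib


def two_state_overlap(a: ScoreTrack, b: ScoreTrack) -> dict:
    """Agreement decomposition of two binary-state tracks.

    Returns fractions (over shared positions) of common-disorder calls,
    common-order calls, their sum (total agreement), and each track's own
    disorder fraction.
    """
    if a.states is None or b.states is None:
        raise AlignmentError("both tracks need two-state calls (binarize first)")
    ia, ib = align_tracks(a, b)
    sa = a.states[ia] == DISORDERED
    sb = b.states[ib] == DISORDERED
    n = len(ia)
    dd = float(np.mean(sa & sb))
    oo = float(np.mean(~sa & ~sb))
    return {
        "n": n,
        "common_disorder": dd,
        "common_order": oo,
        "total_agreement": dd + oo,
        f"disorder_fraction_{a.predictor}": float(np.mean(sa)),
        f"disorder_fraction_{b.predictor}": float(np.mean(sb)),
    }


def prediction_rate_sweep(
    neqp: NeqProfile,
    track: ScoreTrack,
    thresholds=DEFAULT_SWEEP_THRESHOLDS,
    offset: int = 0,
) -> pd.DataFrame:
    """Prediction rate against N_eq-defined truth, per threshold.

    For each threshold t, a position is truly disordered iff N_eq > t
    (equality counts as ordered).  The rate is the fraction of aligned
    positions whose predicted state equals that truth; the truth-class
    balance (fractions of disordered/ordered truth) is reported alongside.
    """
    if track.states is None:
        raise AlignmentError("track needs two-state calls (binarize first)")
    pos_n = neqp.positions[neqp.defined]
    val_n = neqp.neq[neqp.defined]
    common, ia, ib = np.intersect1d(pos_n, track.positions + offset, return_indices=True)
    if len(common) == 0:
        raise AlignmentError("no aligned positions with defined N_eq")
    pred_dis = track.states[ib] == DISORDERED
    rows = []
    for t in thresholds:
        truth_dis = val_n[ia] > t
        rows.append(
            {
                "threshold": float(t),
                "n": len(common),
                "prediction_rate": float(np.mean(pred_dis == truth_dis)),
                "true_disorder_fraction": float(np.mean(truth_dis)),
                "true_order_fraction": float(np.mean(~truth_dis)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Bundle of all comparison outputs for one ensemble + a set of tracks."""

    correlations: pd.DataFrame
    strata: pd.DataFrame
    class_averages: pd.DataFrame
    class_correlations: pd.DataFrame
    overlaps: pd.DataFrame
    sweeps: pd.DataFrame
    summary: dict = field(default_factory=dict)


def compare(
    neqp: NeqProfile,
    tracks: list[ScoreTrack],
    binarize_threshold: float = 0.5,
    sweep_thresholds=DEFAULT_SWEEP_THRESHOLDS,
    offset: int = 0,
) -> ComparisonReport:
    """Run the full comparison battery for one N_eq profile and >= 1 tracks.

    Tracks without native two-state calls are binarized at
    ``binarize_threshold``.  Track-vs-track statistics (correlation,
    two-state overlap) are computed for every unordered pair of tracks.
    """
    from .predictor_io import binarize

    if not tracks:
        raise InsufficientDataError("need at least one score track")
    with_states = [binarize(t, binarize_threshold) for t in tracks]

    corr_rows, strata_frames, class_frames, ccorr_rows, sweep_frames = [], [], [], [], []
    summary = {}
    for t, tb in zip(tracks, with_states):
        series = pair(neqp, t, offset=offset)
        r = correlation(series)
        corr_rows.append(
            {"x": "neq", "y": t.predictor, "pearson_r": r, "n": len(series)}
        )
        summary[f"correlation_neq_{t.predictor}"] = r
        sm = stratified_means(series)
        sm.insert(0, "predictor", t.predictor)
        strata_frames.append(sm)
        try:
            cls_df, cls_r = class_binned_averages(series)
        except InsufficientDataError:
            cls_df, cls_r = None, np.nan
        if cls_df is not None:
            cls_df.insert(0, "predictor", t.predictor)
            class_frames.append(cls_df)
        ccorr_rows.append({"predictor": t.predictor, "class_pearson_r": cls_r})
        summary[f"class_correlation_{t.predictor}"] = cls_r
        sw = prediction_rate_sweep(neqp, tb, thresholds=sweep_thresholds, offset=offset)
        sw.insert(0, "predictor", t.predictor)
        sweep_frames.append(sw)

    overlap_rows = []
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            a, b = tracks[i], tracks[j]
            ia, ib = align_tracks(a, b)
            corr_rows.append(
                {
                    "x": a.predictor,
                    "y": b.predictor,
                    "pearson_r": correlation((a.scores[ia], b.scores[ib])),
                    "n": len(ia),
                }
            )
            ov = two_state_overlap(with_states[i], with_states[j])
            ov = {"a": a.predictor, "b": b.predictor, **ov}
            overlap_rows.append(ov)
            summary[f"total_agreement_{a.predictor}_{b.predictor}"] = ov[
                "total_agreement"
            ]

    return ComparisonReport(
        correlations=pd.DataFrame(corr_rows),
        strata=pd.concat(strata_frames, ignore_index=True),
        class_averages=(
            pd.concat(class_frames, ignore_index=True) if class_frames else pd.DataFrame()
        ),
        class_correlations=pd.DataFrame(ccorr_rows),
        overlaps=pd.DataFrame(overlap_rows),
        sweeps=pd.concat(sweep_frames, ignore_index=True),
        summary=summary,
    )
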