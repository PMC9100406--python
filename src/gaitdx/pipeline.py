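"""End-to-end plumbing: recordings -> preprocessed stance segments -> per-channel
feature tables -> prune/rank -> cross-validated evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, selection
from .errors import ParameterError
from .features_emg import EmgFeatureConfig, emg_feature_vector
from .features_grf import grf_feature_vector
from .preprocess import (
    GaitCycleSegment,
    normalize_by_abs_mean,
    normalize_by_mean,
    preprocess_emg,
    preprocess_grf,
    quality_screen,
    segment_gait_cycles,
)
from .synthdata import EMG_CHANNELS, GRF_CHANNELS, GaitRecording

META_COLUMNS = ("subject_id", "label", "cycle_index")


def _normalize(channel: str, segment: np.ndarray, trial: np.ndarray) -> np.ndarray:
    # EMG is normalized by the rectified mean of the whole trial (the standard
    # amplitude normalization in gait EMG; it preserves how much activity falls
    # inside the stance window). GRFz is single-signed with a solid mean and is
    # normalized by its segment mean; the bipolar GRF shear components use the
    # segment's rectified mean.
    if channel in EMG_CHANNELS:
        scale = np.abs(trial).mean()
        if scale == 0.0:
            return normalize_by_abs_mean(segment, channel)
        return segment / scale
    if channel == "GRFz":
        return normalize_by_mean(segment, channel)
    return normalize_by_abs_mean(segment, channel)


def extract_feature_tables(
    recordings: list[GaitRecording],
    channels: tuple[str, ...] | None = None,
    feature_config: EmgFeatureConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Build one feature table per channel: preprocess, segment on the vertical
    GRF, quality-screen, normalize, extract the channel's feature bank.

    Each accepted recording contributes one row per table; rows carry
    ``subject_id``, ``label`` and ``cycle_index`` provenance columns and are
    aligned across channels.
    """
    channels = tuple(channels) if channels else EMG_CHANNELS + GRF_CHANNELS
    rows: dict[str, list[dict]] = {ch: [] for ch in channels}
    cycle_counter: dict[str, int] = {}
    for rec in recordings:
        cycle_index = cycle_counter.get(rec.subject_id, 0)
        cycle_counter[rec.subject_id] = cycle_index + 1
        vgrf = preprocess_grf(rec.channels["GRFz"], rec.fs)
        intervals = segment_gait_cycles(vgrf, rec.fs)
        intervals = [
            iv for iv in intervals if quality_screen(iv, rec.fs, vgrf).accepted
        ]
        if not intervals:
            continue
        # one stance per synthetic recording; keep the longest if noise splits it
        start, end = max(intervals, key=lambda iv: iv[1] - iv[0])
        for ch in channels:
            raw = rec.channels[ch]
            if ch in EMG_CHANNELS:
                filtered = preprocess_emg(raw, rec.fs)
            else:
                filtered = preprocess_grf(raw, rec.fs)
            seg = GaitCycleSegment(
                subject_id=rec.subject_id,
                label=rec.label,
                channel_name=ch,
                samples=_normalize(ch, filtered[start:end], filtered),
                span=(start, end),
            )
            if ch in EMG_CHANNELS:
                vec = emg_feature_vector(seg.samples, ch, feature_config)
            else:
                vec = grf_feature_vector(seg.samples, rec.fs, ch, config=feature_config)
            row = {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "cycle_index": cycle_index,
            }
            row.update(vec.as_dict())
            rows[ch].append(row)
    return {ch: pd.DataFrame(rows[ch]) for ch in channels}


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def combine_channels(
    tables: dict[str, pd.DataFrame], combo: tuple[str, ...]
) -> pd.DataFrame:
    """Column-concatenate the feature tables of a channel combination, joining on
    (subject_id, cycle_index)."""
    merged: pd.DataFrame | None = None
    for ch in combo:
        if ch not in tables:
            raise ParameterError(f"missing feature table for channel {ch!r}")
        t = tables[ch]
        if merged is None:
            merged = t.copy()
        else:
            merged = merged.merge(
                t.drop(columns=["label"]), on=["subject_id", "cycle_index"], how="inner"
            )
    assert merged is not None
    return merged


def prune_and_rank(
    table: pd.DataFrame,
    labels,
    method: str,
    threshold: float = 0.9,
    prune_first: bool = True,
    **ranker_kwargs,
) -> tuple[pd.DataFrame, selection.RankedFeatureList]:
    """Correlation pruning plus one ranking technique.

    ``prune_first=True`` (default) removes highly correlated features before
    ranking so the pruning cannot bias the ranker; the reverse order is available
    for reproduction experiments. Returns the feature-only pruned table and the
    ranking over its columns.
    """
    X = table[feature_columns(table)]
    if prune_first:
        pruned, _ = selection.drop_correlated(X, threshold)
        ranked = selection.rank_features(method, pruned, labels, **ranker_kwargs)
        return pruned, ranked
    ranked_full = selection.rank_features(method, X, labels, **ranker_kwargs)
    pruned, dropped = selection.drop_correlated(X, threshold)
    kept = [n for n in ranked_full.names if n not in dropped]
    keep_scores = ranked_full.scores[[ranked_full.names.index(n) for n in kept]]
    return pruned, selection.RankedFeatureList(method, kept, keep_scores)


def run_config(
    tables: dict[str, pd.DataFrame],
    combo: tuple[str, ...],
    ranker: str,
    n_folds: int = 5,
    seed: int = 0,
    knn_config: classify.KnnConfig | None = None,
    max_k: int | None = None,
    prune_first: bool = True,
) -> classify.FeatureSearchResult:
    """Full pipeline for one (channel combo, ranker): prune -> rank -> subject-wise
    folds -> incremental top-k search with the tuned KNN."""
    table = combine_channels(tables, combo)
    labels = table["label"].to_numpy()
    subject_ids = table["subject_id"].to_numpy()
    pruned, ranked = prune_and_rank(table, labels, ranker, prune_first=prune_first)
    folds = classify.subject_wise_folds(
        dict(zip(subject_ids.tolist(), labels.tolist())), n_folds, seed
    )
    record_folds = folds.record_folds(subject_ids)
    return classify.incremental_feature_search(
        ranked,
        pruned,
        labels,
        record_folds,
        knn_config or classify.KnnConfig(),
        seed,
        subject_ids,
        max_k=max_k,
    )


def evaluate_config(
    tables: dict[str, pd.DataFrame],
    combo: tuple[str, ...],
    ranker: str,
    n_folds: int = 5,
    seed: int = 0,
    knn_config: classify.KnnConfig | None = None,
    max_k: int | None = None,
) -> "classify._evaluate.EvalReport":
    """Unbiased pipeline evaluation: run the incremental search on one
    subject-wise split, then measure the selected top-k configuration on a fresh
    subject-wise split of the same cohort.

    Reporting the search's own maximum re-uses the folds that chose k and is
    optimistically biased (visible on null cohorts); re-splitting removes that
    selection optimism while keeping the full prune -> rank -> search -> KNN
    pipeline intact.
    """
    cfg = knn_config or classify.KnnConfig()
    search = run_config(tables, combo, ranker, n_folds, seed, cfg, max_k)
    table = combine_channels(tables, combo)
    labels = table["label"].to_numpy()
    subject_ids = table["subject_id"].to_numpy()
    pruned, ranked = prune_and_rank(table, labels, ranker)
    eval_folds = classify.subject_wise_folds(
        dict(zip(subject_ids.tolist(), labels.tolist())), n_folds, seed + 104729
    )
    record_folds = eval_folds.record_folds(subject_ids)
    report = classify.cross_validated_run(
        pruned[ranked.names[: search.best_k]],
        labels,
        record_folds,
        cfg,
        seed,
        subject_ids,
    )
    report.provenance.update(
        {"channels": list(combo), "ranker": ranker, "top_k": search.best_k}
    )
    return report
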