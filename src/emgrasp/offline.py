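"""Offline classification study: training conditions, transient/steady-state
error, and the window-length x available-grasps grid.

Two analyses mirror the offline protocol:

* **Grasp selection** — an N+2-class classifier evaluated on *transient*
  EMG: training uses windows whose trailing edge lies within the first
  L+100 ms of each collection, testing uses windows ending within the first
  600 ms of static-wrist trials in the held-out fold (500 ms window by
  default).
* **Grasp maintenance** — a 3-class classifier (grasps remapped to
  hand-close) evaluated on *steady-state* EMG: windows starting at or after
  300 ms (trailing edge >= 300+L ms), on both static and dynamic trials
  (200 ms window by default).

Both use two-fold cross-validation split by repetition: repetitions
alternate into folds in collection order.  The twelve training conditions
cross electrode placement (extrinsic_only / intrinsic_only / both) with
wrist training data (neutral / variable / dynamic / all).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import ClassSet, remap_maintenance
from .features import FEATURES_PER_CHANNEL, FeatureConfig, sliding_window_features
from .lda import classification_error, predict_batch, train_lda

ELECTRODE_PLACEMENTS = ("extrinsic_only", "intrinsic_only", "both")
WRIST_TRAININGS = ("neutral", "variable", "dynamic", "all")

WINDOW_LENGTHS_MS = (100, 200, 300, 400, 500)
GRASP_COUNTS = (2, 4, 6)

SELECTION_WINDOW_MS = 500
MAINTENANCE_WINDOW_MS = 200
TRANSIENT_TEST_END_MS = 600
STEADY_START_MS = 300
TRAIN_MARGIN_MS = 100  # selection training uses the first L+100 ms


@dataclass(frozen=True)
class TrainingCondition:
    electrodes: str
    wrist_training: str

    def __post_init__(self) -> None:
        if self.electrodes not in ELECTRODE_PLACEMENTS:
            raise ValueError(f"electrodes must be one of {ELECTRODE_PLACEMENTS}")
        if self.wrist_training not in WRIST_TRAININGS:
            raise ValueError(f"wrist_training must be one of {WRIST_TRAININGS}")

    @classmethod
    def all_conditions(cls) -> list["TrainingCondition"]:
        """The 12 electrode x wrist-training combinations."""
        return [cls(e, w) for e in ELECTRODE_PLACEMENTS for w in WRIST_TRAININGS]


def grid_cells() -> list[tuple[int, int]]:
    """The 15 (window_ms, n_grasps) cells of the grid analysis."""
    return [(L, n) for L in WINDOW_LENGTHS_MS for n in GRASP_COUNTS]


def _matches_wrist_training(tag: str, wrist_training: str) -> bool:
    if wrist_training == "neutral":
        return tag == "static:neutral"
    if wrist_training == "variable":
        return tag.startswith("static:")
    if wrist_training == "dynamic":
        return tag.startswith("dynamic:")
    return tag.startswith(("static:", "dynamic:"))


def build_condition(recordings, condition: TrainingCondition):
    """Training recordings and channel indices for one condition.

    Returns ``(selected_recordings, channel_indices)``; repetition metadata
    is preserved on the recordings.  Raises if the dataset lacks the
    protocol data the condition needs.
    """
    selected = [r for r in recordings
                if _matches_wrist_training(r.wrist_condition, condition.wrist_training)]
    if not selected:
        raise ValueError(
            f"dataset contains no recordings for wrist_training={condition.wrist_training!r}"
        )
    channels = selected[0].channel_indices(condition.electrodes)
    return selected, channels


def _feature_columns(channels: np.ndarray) -> np.ndarray:
    blocks = [np.arange(FEATURES_PER_CHANNEL) + c * FEATURES_PER_CHANNEL for c in channels]
    return np.concatenate(blocks)


class OfflineStudy:
    """Feature cache and analysis driver over an offline protocol dataset.

    Features are extracted once per window length over all 12 channels;
    every condition then selects rows (recordings) and columns (channels) of
    the cached tables, keeping the two-fold repetition structure intact.
    """

    def __init__(self, recordings, increment_ms: int = 25, ar_order: int = 6,
                 shrinkage: float = 1e-2):
        self.recordings = list(recordings)
        self.increment_ms = increment_ms
        self.ar_order = ar_order
        self.shrinkage = shrinkage
        self._transient: dict[int, dict] = {}
        self._steady: dict[int, dict] = {}

    # -- feature tables ----------------------------------------------------
    def _extract(self, window_ms: int, end_min, end_max) -> dict:
        cfg = FeatureConfig(window_ms=window_ms, increment_ms=self.increment_ms,
                            ar_order=self.ar_order)
        Xs, meta = [], []
        for i, rec in enumerate(self.recordings):
            lo = end_min(window_ms)
            hi = end_max(window_ms) if end_max is not None else None
            if rec.n_samples < (lo if lo is not None else window_ms):
                warnings.warn(
                    f"recording {i} ({rec.duration_ms} ms) too short for this analysis; skipped",
                    stacklevel=2,
                )
                continue
            X, ends, labs = sliding_window_features(rec, cfg, end_min_ms=lo, end_max_ms=hi)
            if X.shape[0] == 0:
                continue
            Xs.append(X)
            rep = int(rec.meta.get("rep", 1))
            tag = rec.wrist_condition
            meta.append(pd.DataFrame({
                "recording": i,
                "label": labs,
                "end_ms": ends,
                "rep": rep,
                "fold": (rep - 1) % 2,
                "wrist": tag,
                "is_static": tag.startswith("static:"),
            }))
        if not Xs:
            n_feat = self.recordings[0].n_channels * FEATURES_PER_CHANNEL if self.recordings else 0
            empty = pd.DataFrame(columns=["recording", "label", "end_ms", "rep",
                                          "fold", "wrist", "is_static"])
            return {"X": np.empty((0, n_feat)), "meta": empty}
        return {"X": np.concatenate(Xs, axis=0), "meta": pd.concat(meta, ignore_index=True)}

    def transient_features(self, window_ms: int) -> dict:
        """Windows ending within the first 600 ms (onset transients)."""
        if window_ms > TRANSIENT_TEST_END_MS:
            raise ValueError(
                f"window of {window_ms} ms exceeds the {TRANSIENT_TEST_END_MS} ms transient "
                "test region; no complete test window fits"
            )
        if window_ms not in self._transient:
            self._transient[window_ms] = self._extract(
                window_ms, end_min=lambda L: None, end_max=lambda L: TRANSIENT_TEST_END_MS)
        return self._transient[window_ms]

    def steady_features(self, window_ms: int) -> dict:
        """Windows lying entirely after the first 300 ms (steady state)."""
        if window_ms not in self._steady:
            self._steady[window_ms] = self._extract(
                window_ms, end_min=lambda L: STEADY_START_MS + L, end_max=None)
        return self._steady[window_ms]

    # -- analyses ----------------------------------------------------------
    def _condition_masks(self, meta: pd.DataFrame, condition: TrainingCondition):
        rec_tags = meta["wrist"]
        train_rows = rec_tags.map(
            lambda t: _matches_wrist_training(t, condition.wrist_training)).to_numpy()
        channels = self.recordings[0].channel_indices(condition.electrodes)
        return train_rows, _feature_columns(channels)

    def grasp_selection_error(self, condition: TrainingCondition,
                              window_ms: int = SELECTION_WINDOW_MS,
                              n_grasps: int = 6) -> float:
        """Two-fold mean N+2-class error on transient windows of static trials."""
        tbl = self.transient_features(window_ms)
        X, meta = tbl["X"], tbl["meta"]
        classes = ClassSet.most_used(n_grasps).selection_classes
        in_classes = meta["label"].isin(classes).to_numpy()
        train_rows, cols = self._condition_masks(meta, condition)
        train_region = (meta["end_ms"] <= window_ms + TRAIN_MARGIN_MS).to_numpy()
        test_rows = meta["is_static"].to_numpy()
        errs = []
        for fold in (0, 1):
            tr = train_rows & in_classes & train_region & (meta["fold"] == fold).to_numpy()
            te = test_rows & in_classes & (meta["fold"] == 1 - fold).to_numpy()
            model = train_lda(X[np.ix_(tr, cols)], meta["label"].to_numpy()[tr],
                              shrinkage=self.shrinkage, classes=classes)
            pred = predict_batch(model, X[np.ix_(te, cols)])
            errs.append(classification_error(pred, meta["label"].to_numpy()[te]))
        return float(np.mean(errs))

    def grasp_maintenance_error(self, condition: TrainingCondition,
                                window_ms: int = MAINTENANCE_WINDOW_MS,
                                n_grasps: int = 6,
                                three_class: bool = True) -> float:
        """Two-fold mean 3-class (remapped) error on steady-state windows.

        Tested against both static and dynamic trials.  ``three_class=False``
        keeps the N+2-class alphabet instead of remapping.
        """
        tbl = self.steady_features(window_ms)
        X, meta = tbl["X"], tbl["meta"]
        cset = ClassSet.most_used(n_grasps)
        in_classes = meta["label"].isin(cset.selection_classes).to_numpy()
        labels = meta["label"].to_numpy()
        if three_class:
            labels = np.asarray(remap_maintenance(labels), dtype=object)
            classes = cset.maintenance_classes
        else:
            classes = cset.selection_classes
        train_rows, cols = self._condition_masks(meta, condition)
        errs = []
        for fold in (0, 1):
            tr = train_rows & in_classes & (meta["fold"] == fold).to_numpy()
            te = in_classes & (meta["fold"] == 1 - fold).to_numpy()
            model = train_lda(X[np.ix_(tr, cols)], labels[tr],
                              shrinkage=self.shrinkage, classes=classes)
            pred = predict_batch(model, X[np.ix_(te, cols)])
            errs.append(classification_error(pred, labels[te]))
        return float(np.mean(errs))

    def condition_table(self, selection_window_ms: int = SELECTION_WINDOW_MS,
                        maintenance_window_ms: int = MAINTENANCE_WINDOW_MS,
                        n_grasps: int = 6) -> pd.DataFrame:
        """Selection and maintenance error for all 12 training conditions."""
        rows = []
        for cond in TrainingCondition.all_conditions():
            rows.append({
                "electrodes": cond.electrodes,
                "wrist_training": cond.wrist_training,
                "n_grasps": n_grasps,
                "error_selection": self.grasp_selection_error(
                    cond, selection_window_ms, n_grasps),
                "error_maintenance": self.grasp_maintenance_error(
                    cond, maintenance_window_ms, n_grasps),
            })
        return pd.DataFrame(rows)

    def window_grasp_grid(self) -> pd.DataFrame:
        """The 15-cell grid, under the both-electrodes / all-wrist condition."""
        cond = TrainingCondition("both", "all")
        rows = []
        for L, n in grid_cells():
            rows.append({
                "window_ms": L,
                "n_grasps": n,
                "error_selection": self.grasp_selection_error(cond, L, n),
                "error_maintenance": self.grasp_maintenance_error(cond, L, n),
            })
        return pd.DataFrame(rows)
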