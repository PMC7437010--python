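"""Diversity and similarity tracking for mutant pools over time.

Richness is operationalized as the number of mutants detected at or above a
count threshold; "mass extinction" windows are the consecutive-timepoint
intervals with the largest loss of detected mutants; sample similarity is the
Pearson correlation of raw barcode counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcode_quant import CountTable

DEFAULT_THRESHOLDS = (1, 5, 10, 20)


@dataclass(frozen=True)
class DetectionProfile:
    sample_id: str
    threshold: int
    n_detected: int
    n_not_detected: int
    detected_genes: frozenset[str]


@dataclass(frozen=True)
class LossWindow:
    """Detection-state transitions between two consecutive timepoints.

    ``n_lost`` counts genes detected at ``window[0]`` but not at
    ``window[1]``; ``n_gained`` counts the reverse transition (re-appearance
    near the threshold is sampling noise, not resurrection, so gains are
    tracked rather than forbidden). ``fraction_lost`` is relative to the
    number detected at the window start.
    """

    condition: str
    window: tuple[float, float]
    n_lost: int
    n_gained: int
    fraction_lost: float
    threshold: int


@dataclass
class CorrelationMatrix:
    sample_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        finite = np.isfinite(r)
        if not np.allclose(
            np.where(finite, r, 0.0), np.where(finite.T, r.T, 0.0), atol=1e-12
        ):
            raise ValueError("correlation matrix must be symmetric")
        self.r = r

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.sample_ids, columns=self.sample_ids)


def detection_profile(
    table: CountTable, sample_id: str, threshold: int = 10
) -> DetectionProfile:
    """Genes detected (count >= threshold) in one sample; inclusive boundary."""
    if sample_id not in table.counts.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    row = table.counts.loc[sample_id]
    detected = frozenset(row.index[row >= threshold])
    return DetectionProfile(
        sample_id=sample_id,
        threshold=threshold,
        n_detected=len(detected),
        n_not_detected=table.n_genes - len(detected),
        detected_genes=detected,
    )


def loss_windows(
    table: CountTable,
    condition: str,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> tuple[list[LossWindow], dict[int, LossWindow]]:
    """Per-threshold series of detection losses between consecutive timepoints.

    Returns all windows plus, per threshold, the window of maximal loss (ties
    broken by the earliest window). Samples are ordered by time; at least two
    samples of the condition are required.
    """
    meta = table.samples_for(condition)
    if len(meta) < 2:
        raise ValueError(
            f"condition {condition!r} needs >=2 timepoints, has {len(meta)}"
        )
    sample_ids = list(meta.index)
    times = meta["time_h"].to_list()
    windows: list[LossWindow] = []
    argmax: dict[int, LossWindow] = {}
    for threshold in thresholds:
        detected = [
            detection_profile(table, sid, threshold).detected_genes
            for sid in sample_ids
        ]
        best: LossWindow | None = None
        for i in range(len(sample_ids) - 1):
            lost = detected[i] - detected[i + 1]
            gained = detected[i + 1] - detected[i]
            frac = len(lost) / len(detected[i]) if detected[i] else 0.0
            win = LossWindow(
                condition=condition,
                window=(float(times[i]), float(times[i + 1])),
                n_lost=len(lost),
                n_gained=len(gained),
                fraction_lost=frac,
                threshold=threshold,
            )
            windows.append(win)
            if best is None or win.n_lost > best.n_lost:
                best = win
        assert best is not None
        argmax[threshold] = best
    return windows, argmax


def loss_windows_frame(windows: list[LossWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [w.condition for w in windows],
            "t_start_h": [w.window[0] for w in windows],
            "t_end_h": [w.window[1] for w in windows],
            "threshold": [w.threshold for w in windows],
            "n_lost": [w.n_lost for w in windows],
            "n_gained": [w.n_gained for w in windows],
            "fraction_lost": [w.fraction_lost for w in windows],
        }
    )


def pearson_matrix(table: CountTable, on: str = "counts") -> CorrelationMatrix:
    """Pairwise Pearson correlation of samples over the shared gene universe.

    Correlations are computed on RAW counts by default, matching how pooled
    fitness studies typically visualize population similarity; pass
    ``on="abundance"`` to correlate pseudocount-free relative abundances
    instead. Zero-variance samples yield NaN rows/columns and a warning.
    """
    if table.n_samples < 2 or table.n_genes < 2:
        raise ValueError("pearson_matrix needs >=2 samples and >=2 genes")
    X = table.counts.to_numpy(dtype=float)
    if on == "abundance":
        X = X / X.sum(axis=1, keepdims=True)
    elif on != "counts":
        raise ValueError(f"unknown mode {on!r}")
    variances = X.var(axis=1)
    degenerate = variances == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    if degenerate.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance sample(s) {bad}: correlation undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    good = ~degenerate
    r[np.ix_(good, good)] = np.clip(r[np.ix_(good, good)], -1.0, 1.0)
    np.fill_diagonal(r, np.where(good, 1.0, np.nan))
    r = (r + r.T) / 2.0 if np.isfinite(r).all() else r
    return CorrelationMatrix(sample_ids=table.sample_ids, r=r)
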