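"""Artifact detection and rejection on epoched data.

Three detectors are provided, all evaluated inside a rejection window
running from the start of the baseline period to the end of the measurement
window:

* simple voltage threshold (SVT): any sample's |v| strictly above a μV
  threshold in any included channel;
* moving-window peak-to-peak (MWP): a 200 ms window slides across the
  rejection window; the statistic is the maximum over placements of
  (max − min) within the placement, compared to the same μV threshold;
* statistical threshold: single-sample voltages pooled across the whole
  study (all participants, included channels, window samples) define a mean
  and SD; epochs containing any sample beyond k·SD from the pooled mean are
  flagged.

The absolute-threshold approach ORs SVT and MWP at a common threshold.  A
matched random-removal mask provides the control for "does rejection beat
removing the same number of random trials".  Detection never deletes data:
:func:`apply_mask` only clears the keep-mask.

Conventions (fixed, testable): strict inequality at the threshold; window
endpoints inclusive with nearest-sample mapping; included channels default
to the scalp set (the infra-orbital EOG channel is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synth import EpochSet

__all__ = [
    "RejectionWindow",
    "EpochDiagnostics",
    "RejectionMask",
    "rejection_window_for",
    "svt_mask",
    "mwp_mask",
    "abs_threshold_mask",
    "stat_threshold_mask",
    "random_removal_mask",
    "apply_mask",
]


@dataclass(frozen=True)
class RejectionWindow:
    """Time range (ms, inclusive) over which artifacts are detected."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    def sample_slice(self, times: np.ndarray) -> slice:
        """Inclusive sample range; endpoints map to the nearest sample."""
        t = np.asarray(times)
        if self.start < t[0] - 1e-9 or self.end > t[-1] + 1e-9:
            raise ValueError("rejection window outside the epoch time range")
        i0 = int(np.argmin(np.abs(t - self.start)))
        i1 = int(np.argmin(np.abs(t - self.end)))
        return slice(i0, i1 + 1)


def rejection_window_for(preset) -> RejectionWindow:
    """Baseline start through measurement end, the study's rejection range."""
    return RejectionWindow(preset.baseline_window[0], preset.measurement_window[1])


@dataclass
class EpochDiagnostics:
    """Per-epoch detector statistics (μV)."""

    max_abs: np.ndarray  # max |v| over channels and window samples
    max_p2p: np.ndarray  # max windowed peak-to-peak over channels


@dataclass
class RejectionMask:
    """Boolean per-epoch flags plus bookkeeping."""

    flags: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    diagnostics: EpochDiagnostics | None = None

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def pct_flagged(self) -> float:
        return 100.0 * self.n_flagged / len(self.flags) if len(self.flags) else 0.0


def _included_channels(epochs: EpochSet, channels) -> np.ndarray:
    if channels is None:
        return epochs.montage.scalp_indices
    return np.asarray(channels, dtype=int)


def svt_mask(
    epochs: EpochSet,
    threshold: float,
    window: RejectionWindow,
    channels=None,
) -> RejectionMask:
    """Flag epochs whose absolute voltage strictly exceeds ``threshold`` at
    any included channel/sample in the window."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ch = _included_channels(epochs, channels)
    sl = window.sample_slice(epochs.times)
    seg = epochs.data[:, ch, sl]
    max_abs = np.abs(seg).max(axis=(1, 2)) if seg.size else np.zeros(epochs.n_epochs)
    return RejectionMask(
        flags=max_abs > threshold,
        method="svt",
        params={"threshold": threshold, "window": (window.start, window.end)},
        diagnostics=EpochDiagnostics(max_abs=max_abs, max_p2p=np.zeros_like(max_abs)),
    )


def mwp_statistic(
    epochs: EpochSet,
    window: RejectionWindow,
    win_len: float = 200.0,
    step: int = 1,
    channels=None,
) -> np.ndarray:
    """Per-epoch moving-window peak-to-peak statistic (μV): max over window
    placements and included channels of (max − min) within the placement."""
    ch = _included_channels(epochs, channels)
    sl = window.sample_slice(epochs.times)
    seg = epochs.data[:, ch, sl]
    L = int(round(win_len * epochs.srate / 1000.0))
    L = max(L, 2)
    if L > seg.shape[-1]:
        raise ValueError("moving window longer than the rejection window")
    views = sliding_window_view(seg, L, axis=-1)[:, :, ::step, :]
    p2p = views.max(axis=-1) - views.min(axis=-1)
    return p2p.max(axis=(1, 2))


def mwp_mask(
    epochs: EpochSet,
    threshold: float,
    window: RejectionWindow,
    win_len: float = 200.0,
    step: int = 1,
    channels=None,
) -> RejectionMask:
    """Flag epochs whose MWP statistic strictly exceeds ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    stat = mwp_statistic(epochs, window, win_len=win_len, step=step, channels=channels)
    return RejectionMask(
        flags=stat > threshold,
        method="mwp",
        params={
            "threshold": threshold,
            "win_len": win_len,
            "step": step,
            "window": (window.start, window.end),
        },
        diagnostics=EpochDiagnostics(max_abs=np.zeros_like(stat), max_p2p=stat),
    )


def abs_threshold_mask(
    epochs: EpochSet,
    threshold: float,
    window: RejectionWindow,
    win_len: float = 200.0,
    channels=None,
) -> RejectionMask:
    """SVT OR MWP at the same threshold (the absolute-threshold approach)."""
    svt = svt_mask(epochs, threshold, window, channels=channels)
    mwp = mwp_mask(epochs, threshold, window, win_len=win_len, channels=channels)
    return RejectionMask(
        flags=svt.flags | mwp.flags,
        method="abs",
        params={"threshold": threshold, "window": (window.start, window.end)},
        diagnostics=EpochDiagnostics(
            max_abs=svt.diagnostics.max_abs, max_p2p=mwp.diagnostics.max_p2p
        ),
    )


def stat_threshold_mask(
    study: list[EpochSet],
    k: float,
    window: RejectionWindow,
    channels=None,
) -> list[RejectionMask]:
    """Statistical-threshold masks, one per participant.

    Pools the single-sample voltages of every participant's kept epochs
    (included channels, window samples) into one distribution; each epoch is
    flagged iff any of its samples lies more than ``k`` pooled SDs from the
    pooled mean.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not study:
        raise ValueError("empty study")
    segs = []
    for es in study:
        ch = _included_channels(es, channels)
        sl = window.sample_slice(es.times)
        segs.append(es.data[:, ch, sl])
    pool = np.concatenate([s[es.keep].ravel() for s, es in zip(segs, study)])
    if pool.size == 0:
        raise ValueError("no kept samples to pool")
    mu, sd = float(pool.mean()), float(pool.std())
    masks = []
    for s in segs:
        dev = np.abs(s - mu).max(axis=(1, 2))
        masks.append(
            RejectionMask(
                flags=dev > k * sd,
                method="stat",
                params={
                    "k": k,
                    "pool_mean": mu,
                    "pool_sd": sd,
                    "window": (window.start, window.end),
                },
            )
        )
    return masks


def random_removal_mask(n_epochs: int, n_remove: int, seed: int) -> RejectionMask:
    """Flag exactly ``n_remove`` epochs uniformly at random (the matched
    random-removal control)."""
    if not 0 <= n_remove <= n_epochs:
        raise ValueError("n_remove must lie in [0, n_epochs]")
    rng = np.random.default_rng(seed)
    flags = np.zeros(n_epochs, dtype=bool)
    flags[rng.choice(n_epochs, size=n_remove, replace=False)] = True
    return RejectionMask(
        flags=flags, method="random", params={"n_remove": n_remove, "seed": seed}
    )


def apply_mask(epochs: EpochSet, mask: RejectionMask) -> EpochSet:
    """Exclude flagged epochs via the keep-mask; the data are untouched."""
    if len(mask.flags) != epochs.n_epochs:
        raise ValueError("mask length does not match epoch count")
    out = epochs.copy()
    out.keep &= ~mask.flags
    out.log.append(
        f"reject(method={mask.method}, params={mask.params}, "
        f"pct_flagged={mask.pct_flagged:.2f})"
    )
    return out
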