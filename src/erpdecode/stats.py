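"""Group-level summaries: within-subject effect size vs chance, its
bootstrap standard error, paired comparisons against the baseline approach,
and the RMS-of-SEM noise metric for epoched data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .synth import EpochSet

__all__ = [
    "GroupResult",
    "cohens_dz",
    "bootstrap_se_dz",
    "paired_t",
    "rms_sem_noise",
    "group_result",
]


class DegenerateSampleError(ValueError):
    """Zero-variance sample where a spread-normalized statistic is needed."""


@dataclass
class GroupResult:
    """Group summary of per-participant window accuracies."""

    values: np.ndarray
    chance: float
    mean: float
    sd: float
    dz: float
    dz_se: float
    n_boot: int
    t_vs_baseline: float | None = None
    p_vs_baseline: float | None = None


def cohens_dz(values, chance: float) -> float:
    """Within-subject effect size: (mean − chance) / sample SD (n−1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 participants")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero across-participant SD")
    return float((v.mean() - chance) / sd)


def bootstrap_se_dz(
    values, chance: float, n_boot: int = 10_000, seed: int = 0
) -> float:
    """Bootstrap (resampling participants with replacement) SE of dz.

    Zero-variance resamples, where dz is undefined, are skipped.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    samples = v[idx]
    sd = samples.std(axis=1, ddof=1)
    ok = sd > 0
    dz = (samples.mean(axis=1)[ok] - chance) / sd[ok]
    if dz.size < 2:
        raise DegenerateSampleError("all bootstrap resamples degenerate")
    return float(dz.std(ddof=1))


def paired_t(a, b) -> tuple[float, float]:
    """Paired t statistic and two-sided p for same-participant values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    if np.allclose(a, b):
        return 0.0, 1.0
    if np.std(a - b, ddof=1) == 0:
        raise DegenerateSampleError("zero-variance paired difference")
    t, p = sp_stats.ttest_rel(a, b)
    return float(t), float(p)


def rms_sem_noise(epochs: EpochSet, condition_labels=None) -> float:
    """RMS over (condition, channel, timepoint) of the across-trial SEM, μV.

    The SEM of the averaged ERP (SD across kept trials / sqrt(n)) is the
    per-cell noise measure; the root mean square over all cells summarizes a
    participant in one number.
    """
    labels = (
        np.asarray(condition_labels) if condition_labels is not None else epochs.labels
    )
    sems = []
    for cond in np.unique(labels):
        trials = epochs.data[epochs.keep & (labels == cond)]
        n = trials.shape[0]
        if n < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 kept trials")
        sems.append(trials.std(axis=0, ddof=1) / np.sqrt(n))
    cells = np.concatenate([s.ravel() for s in sems])
    return float(np.sqrt(np.mean(cells**2)))


def group_result(
    values,
    chance: float,
    baseline_values=None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> GroupResult:
    """Bundle the group summaries for one (approach, parameter, classifier)."""
    v = np.asarray(values, dtype=float)
    dz = cohens_dz(v, chance)
    se = bootstrap_se_dz(v, chance, n_boot=n_boot, seed=seed)
    t = p = None
    if baseline_values is not None:
        t, p = paired_t(v, baseline_values)
    return GroupResult(
        values=v,
        chance=chance,
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        dz=dz,
        dz_se=se,
        n_boot=n_boot,
        t_vs_baseline=t,
        p_vs_baseline=p,
    )
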