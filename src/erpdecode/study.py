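"""Orchestration of the artifact-minimization comparison.

Four approaches are compared on a simulated study, always in the fixed
pipeline order (optional lowpass) → baseline correction → (ICA blink
correction) → (rejection) → averaged-ERP decoding → window accuracy:

* ``baseline`` — no correction, no rejection;
* ``ica_only`` — ICA blink correction, no rejection;
* ``ica_abs`` — ICA plus absolute-threshold rejection (SVT OR MWP) over a
  grid of μV thresholds;
* ``ica_stat`` — ICA plus statistical-threshold rejection over a grid of
  pooled-SD multiples;
* ``random_control`` — ICA plus removal of the same per-participant number
  of randomly chosen trials as a matched rejection run.

Group rows report mean window accuracy, Cohen's dz vs chance with bootstrap
SE, a paired t-test against the baseline approach, and the mean percentage
of rejected trials.  Participants whose surviving trial counts cannot fill
the folds are reported as infeasible rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decode import (
    ClassifierSpec,
    DecodingInfeasibleError,
    decode_timecourse,
    window_mean,
)
from .preprocess import baseline_correct, ica_correct, lowpass
from .reject import (
    RejectionWindow,
    abs_threshold_mask,
    apply_mask,
    random_removal_mask,
    rejection_window_for,
    stat_threshold_mask,
)
from .stats import group_result, paired_t
from .synth import EpochSet, SimulationConfig, get_paradigm_preset, simulate_study

__all__ = [
    "ApproachSpec",
    "StudyConfig",
    "prepare_study",
    "run_approach",
    "run_study",
    "confound_experiment",
    "null_chance_study",
]

#: the printed absolute-threshold grids (μV) per dataset family
ABS_THRESHOLDS = {
    "erp_core": (50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 200.0, 400.0),
    "orientations": (70.0, 80.0, 90.0, 100.0, 200.0, 400.0),
    "community": (150.0, 200.0, 250.0, 300.0, 400.0, 500.0),
}

#: the printed statistical-threshold grid (pooled-SD multiples)
STAT_KSDS = (2.0, 3.0, 4.0, 5.0, 6.0)

APPROACH_NAMES = ("baseline", "ica_only", "ica_abs", "ica_stat", "random_control")


@dataclass(frozen=True)
class ApproachSpec:
    """One artifact-minimization approach and its parameter grid."""

    name: str
    thresholds: tuple[float, ...] = ()  # μV, ica_abs
    ksds: tuple[float, ...] = ()  # SD multiples, ica_stat
    match_to: "ApproachSpec | None" = None  # random_control

    def __post_init__(self) -> None:
        if self.name not in APPROACH_NAMES:
            raise ValueError(f"unknown approach {self.name!r}")
        if self.name == "ica_abs" and not self.thresholds:
            raise ValueError("ica_abs needs a threshold grid")
        if self.name == "ica_stat" and not self.ksds:
            raise ValueError("ica_stat needs a k grid")
        if self.name == "random_control" and self.match_to is None:
            raise ValueError("random_control needs a match_to approach")

    @property
    def params(self) -> tuple:
        if self.name == "ica_abs":
            return self.thresholds
        if self.name == "ica_stat":
            return self.ksds
        if self.name == "random_control":
            return self.match_to.params
        return (None,)


@dataclass(frozen=True)
class StudyConfig:
    """Full study definition: simulation, approaches, decoding settings."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    approaches: tuple[ApproachSpec, ...] = (
        ApproachSpec("baseline"),
        ApproachSpec("ica_only"),
        ApproachSpec("ica_abs", thresholds=ABS_THRESHOLDS["erp_core"]),
        ApproachSpec("ica_stat", ksds=STAT_KSDS),
    )
    classifiers: tuple[ClassifierSpec, ...] = (ClassifierSpec("svm"),)
    lowpass_hz: float | None = 30.0
    n_iterations: int = 100
    decim: int = 1
    n_boot: int = 10_000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not any(a.name == "baseline" for a in self.approaches):
            raise ValueError("the baseline approach must be present")

    @property
    def preset(self):
        return get_paradigm_preset(self.simulation.preset)

    @property
    def rejection_window(self) -> RejectionWindow:
        return rejection_window_for(self.preset)


@dataclass
class PreparedStudy:
    """Preprocessed per-participant data shared across approaches."""

    base: list[EpochSet]  # (lowpass) + baseline-corrected
    corrected: list[EpochSet] | None  # base + ICA blink correction
    truths: list


def _decode_seed(master_seed: int, participant: int) -> int:
    return int(np.random.SeedSequence([master_seed, participant]).generate_state(1)[0] % (2**31))


def prepare_study(cfg: StudyConfig, need_ica: bool = True) -> PreparedStudy:
    """Simulate and preprocess every participant once.

    The ICA decomposition (fit on the heavily-filtered parallel copy of each
    participant's data) is shared by all ICA-based approaches.
    """
    sims = simulate_study(cfg.simulation)
    preset = cfg.preset
    base, corrected, truths = [], [], []
    for p, (raw, truth) in enumerate(sims):
        es = lowpass(raw, cfg.lowpass_hz) if cfg.lowpass_hz else raw.copy()
        es = baseline_correct(es, preset.baseline_window)
        base.append(es)
        truths.append(truth)
        if need_ica:
            corr, _, _ = ica_correct(es, seed=cfg.master_seed + p)
            corrected.append(corr)
    return PreparedStudy(base=base, corrected=corrected if need_ica else None, truths=truths)


def _approach_masks(
    prep: PreparedStudy, approach: ApproachSpec, param, cfg: StudyConfig
):
    """Per-participant (EpochSet to decode, RejectionMask or None)."""
    window = cfg.rejection_window
    if approach.name == "baseline":
        return [(es, None) for es in prep.base]
    data = prep.corrected
    if data is None:
        raise ValueError("approach requires ICA-corrected data; prepare with need_ica")
    if approach.name == "ica_only":
        return [(es, None) for es in data]
    if approach.name == "ica_abs":
        return [(es, abs_threshold_mask(es, float(param), window)) for es in data]
    if approach.name == "ica_stat":
        masks = stat_threshold_mask(data, float(param), window)
        return list(zip(data, masks))
    # random_control: remove the same per-participant counts as the matched run
    matched = _approach_masks(prep, approach.match_to, param, cfg)
    out = []
    for p, (es, mask) in enumerate(matched):
        n_remove = mask.n_flagged if mask is not None else 0
        rnd = random_removal_mask(
            es.n_epochs, n_remove, seed=_decode_seed(cfg.master_seed + 1, p)
        )
        out.append((es, rnd))
    return out


def run_approach(
    study_data: "PreparedStudy | list[EpochSet]",
    approach: ApproachSpec,
    param,
    cfg: StudyConfig,
    classifier: ClassifierSpec | None = None,
) -> pd.DataFrame:
    """Run one (approach, parameter) cell for every participant.

    Returns a per-participant frame with columns ``participant``,
    ``accuracy`` (NaN when decoding was infeasible), ``pct_rejected``, and
    ``feasible``.  ``study_data`` may be raw simulated EpochSets or an
    already-:func:`prepare_study`-ed study.
    """
    if isinstance(study_data, PreparedStudy):
        prep = study_data
    else:
        raise TypeError("pass a PreparedStudy from prepare_study()")
    classifier = classifier or cfg.classifiers[0]
    preset = cfg.preset
    rows = []
    for p, (es, mask) in enumerate(_approach_masks(prep, approach, param, cfg)):
        pct = mask.pct_flagged if mask is not None else 0.0
        decoded = apply_mask(es, mask) if mask is not None else es
        try:
            run = decode_timecourse(
                decoded,
                classifier,
                n_iterations=cfg.n_iterations,
                seed=_decode_seed(cfg.master_seed, p),
                window=preset.measurement_window,
                decim=cfg.decim,
            )
            acc = window_mean(run, preset.measurement_window)
            feasible = True
        except DecodingInfeasibleError:
            acc, feasible = np.nan, False
        rows.append(
            {
                "participant": es.participant_id,
                "accuracy": acc,
                "pct_rejected": pct,
                "feasible": feasible,
            }
        )
    return pd.DataFrame(rows)


def run_study(
    cfg: StudyConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every (approach, parameter, classifier) cell and summarize.

    Returns ``(summary, per_participant)`` frames; optionally writes
    ``summary.csv``, ``per_participant.csv`` and a run manifest under
    ``out_dir``.  Deterministic under ``cfg.master_seed``.
    """
    need_ica = any(a.name != "baseline" for a in cfg.approaches)
    prep = prepare_study(cfg, need_ica=need_ica)
    chance = 1.0 / (cfg.simulation.resolved().M)

    per_rows, summary_rows = [], []
    for clf in cfg.classifiers:
        clf_label = clf.kind if clf.gamma is None else f"{clf.kind}(gamma={clf.gamma:g})"
        baselines: pd.DataFrame | None = None
        for approach in cfg.approaches:
            for param in approach.params:
                cell = run_approach(prep, approach, param, cfg, classifier=clf)
                cell.insert(0, "classifier", clf_label)
                cell.insert(1, "approach", approach.name)
                cell.insert(2, "param", param if param is not None else np.nan)
                per_rows.append(cell)
                if approach.name == "baseline":
                    baselines = cell
                ok = cell["feasible"] & cell["accuracy"].notna()
                vals = cell.loc[ok, "accuracy"].to_numpy()
                row = {
                    "classifier": clf_label,
                    "approach": approach.name,
                    "param": param if param is not None else np.nan,
                    "n_included": int(ok.sum()),
                    "n_infeasible": int((~cell["feasible"]).sum()),
                    "mean_accuracy": float(vals.mean()) if len(vals) else np.nan,
                    "mean_pct_rejected": float(cell["pct_rejected"].mean()),
                }
                try:
                    gr = group_result(
                        vals,
                        chance,
                        baseline_values=(
                            baselines.loc[ok, "accuracy"].to_numpy()
                            if approach.name != "baseline" and baselines is not None
                            else None
                        ),
                        n_boot=cfg.n_boot,
                        seed=cfg.master_seed,
                    )
                    row.update(
                        dz=gr.dz, dz_se=gr.dz_se,
                        t_vs_baseline=gr.t_vs_baseline, p_vs_baseline=gr.p_vs_baseline,
                    )
                except (ValueError, DecodingInfeasibleError):
                    row.update(dz=np.nan, dz_se=np.nan,
                               t_vs_baseline=np.nan, p_vs_baseline=np.nan)
                summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    per_participant = pd.concat(per_rows, ignore_index=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        per_participant.to_csv(out / "per_participant.csv", index=False)
        manifest = {
            "master_seed": cfg.master_seed,
            "preset": cfg.simulation.preset,
            "n_participants": cfg.simulation.n_participants,
            "n_iterations": cfg.n_iterations,
            "lowpass_hz": cfg.lowpass_hz,
            "approaches": [a.name for a in cfg.approaches],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary, per_participant


# --------------------------------------------------------------------------
# Headline scenarios
# --------------------------------------------------------------------------

def confound_experiment(
    cfg: StudyConfig | None = None,
    blink_probs: tuple[float, float] = (0.5, 0.1),
    n_participants: int = 20,
    n_iterations: int = 25,
    seed: int = 0,
) -> dict:
    """Ocular-confound scenario: class-dependent blink probability, zero
    neural effect.

    Blinks carry class information in the raw voltages, so baseline decoding
    runs above chance even though no neural signal differs between classes;
    ICA blink correction should pull accuracy back toward chance.  Reports
    both group tests.
    """
    if cfg is None:
        sim = SimulationConfig(
            preset="P3b",
            n_participants=n_participants,
            effect_amplitude=0.0,
            blink_prob_per_class=blink_probs,
            master_seed=seed,
        )
        cfg = StudyConfig(
            simulation=sim,
            approaches=(ApproachSpec("baseline"), ApproachSpec("ica_only")),
            n_iterations=n_iterations,
            master_seed=seed,
        )
    sim = cfg.simulation.resolved()
    if sim.effect_amplitude != 0:
        raise ValueError("confound scenario requires effect_amplitude = 0")
    if len(set(sim.blink_prob_per_class)) < 2:
        raise ValueError("confound scenario requires unequal blink probabilities")
    chance = 1.0 / sim.M
    prep = prepare_study(cfg, need_ica=True)
    base = run_approach(prep, ApproachSpec("baseline"), None, cfg)
    ica = run_approach(prep, ApproachSpec("ica_only"), None, cfg)
    from scipy import stats as sp_stats

    b_acc = base["accuracy"].to_numpy()
    i_acc = ica["accuracy"].to_numpy()
    t_base, p_base = sp_stats.ttest_1samp(b_acc, chance)
    t_pair, p_pair = paired_t(b_acc, i_acc)
    return {
        "chance": chance,
        "baseline_accuracy": float(b_acc.mean()),
        "ica_accuracy": float(i_acc.mean()),
        "t_baseline_vs_chance": float(t_base),
        "p_baseline_vs_chance": float(p_base),
        "t_baseline_vs_ica": float(t_pair),
        "p_baseline_vs_ica": float(p_pair),
        "per_participant_baseline": b_acc,
        "per_participant_ica": i_acc,
    }


def null_chance_study(
    preset: str,
    classifier: ClassifierSpec,
    n_participants: int,
    trials_per_class: int,
    n_iterations: int = 25,
    decim: int = 1,
    seed: int = 0,
    window: tuple[float, float] | None = None,
) -> dict:
    """Chance-calibration scenario: no class-dependent signal or artifacts.

    Simulates a null study (zero effect amplitude, equal blink
    probabilities), runs the baseline decoding pipeline, and returns the
    group mean window accuracy with its Monte-Carlo standard error across
    participants, against the 1/M chance level.
    """
    sim = SimulationConfig(
        preset=preset,
        n_participants=n_participants,
        trials_per_class=trials_per_class,
        effect_amplitude=0.0,
        master_seed=seed,
    )
    cfg = StudyConfig(
        simulation=sim,
        approaches=(ApproachSpec("baseline"),),
        classifiers=(classifier,),
        n_iterations=n_iterations,
        decim=decim,
        master_seed=seed,
    )
    prep = prepare_study(cfg, need_ica=False)
    preset_obj = cfg.preset
    meas = window or preset_obj.measurement_window
    accs = []
    for p, es in enumerate(prep.base):
        run = decode_timecourse(
            es,
            classifier,
            n_iterations=n_iterations,
            seed=_decode_seed(seed, p),
            window=meas,
            decim=decim,
        )
        accs.append(window_mean(run, meas))
    accs = np.asarray(accs)
    M = sim.resolved().M
    return {
        "chance": 1.0 / M,
        "mean_accuracy": float(accs.mean()),
        "sem": float(accs.std(ddof=1) / np.sqrt(len(accs))),
        "per_participant": accs,
        "n": n_participants,
    }
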