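"""Full synthetic replication: cohort -> trials -> fits -> hypotheses.

Re-exports the study-design bookkeeping (see :mod:`revspeech.studydesign`)
and orchestrates the end-to-end in-silico experiment: generate a
synthetic cohort, simulate word-scoring trials, fit individual
psychometric functions, derive RAU scores at the optimal and
benefit-maximizing SNRs, and run the hypothesis battery of Bayesian
ANOVAs and t-tests (H1, H1-1, H1-2, H2, H3-1, H3-2-a/b).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes as bz
from . import cohort as ch
from . import psychofit as pf
from .studydesign import (  # noqa: F401  (re-exported bookkeeping API)
    APPLICATIONS,
    DEFAULT_SNR_GRID,
    MATRIX_VOCABULARY,
    MODULATIONS,
    Cell,
    Combo,
    Design,
    MatrixVocabulary,
    build_sentence_list,
    default_design,
    enumerate_combos,
    enumerate_conditions,
    estimate_session_time,
)

__all__ = [
    "ReplicationConfig",
    "run_replication",
    "fit_all_listeners",
    "rau_scores_at",
    "benefit_maximizing_snr",
    "Design",
    "MatrixVocabulary",
    "build_sentence_list",
    "default_design",
    "enumerate_combos",
    "enumerate_conditions",
    "estimate_session_time",
]


@dataclass(frozen=True)
class ReplicationConfig:
    """Configuration of one synthetic replication run."""

    n_per_group: int = 16
    rng_seed: int = 0
    effect_config: ch.EffectConfig = field(default_factory=ch.EffectConfig)
    design: Design = field(default_factory=default_design)
    anova_method: str = "laplace"      # "laplace", "laplace_mc" or "bic"
    floor_ceiling_bounds: tuple[float, float] = (0.15, 0.95)


def fit_all_listeners(trials: pd.DataFrame) -> pd.DataFrame:
    """Fit one psychometric function per listener x condition combo.

    Returns a tidy frame with the fitted parameters and convergence flag.
    """
    rows = []
    group_cols = ["listener", "group", "application", "rt", "modulation"]
    for keys, sub in trials.groupby(group_cols):
        agg = sub.groupby("snr")[["n_words", "n_correct"]].sum()
        fit = pf.fit_psychometric(agg.index.to_numpy(),
                                  agg["n_words"].to_numpy(),
                                  agg["n_correct"].to_numpy())
        rows.append(dict(zip(group_cols, keys)) | {
            "m": fit.m, "w": fit.w, "gamma": fit.gamma, "lam": fit.lam,
            "loglik": fit.loglik, "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def _fit_of(row) -> pf.PsychometricFit:
    return pf.PsychometricFit(m=row.m, w=row.w, gamma=row.gamma,
                              lam=row.lam, converged=bool(row.converged))


def rau_scores_at(fits: pd.DataFrame, snr: float) -> pd.DataFrame:
    """Per listener x combo RAU score of the fitted curve at ``snr``."""
    out = fits.copy()
    out["score"] = [
        pf.rau(_fit_of(r)(snr)) for r in fits.itertuples()
    ]
    return out[["listener", "group", "application", "rt", "modulation",
                "score", "converged"]]


def _app_subset(fits: pd.DataFrame, application: str) -> pd.DataFrame:
    """Rows of one application plus the shared reference-RT rows."""
    return fits[(fits.application == application)
                | (fits.application == "reference")]


def benefit_maximizing_snr(fits: pd.DataFrame, group: str,
                           snr_grid) -> float:
    """Grid SNR maximizing the group's mean dip benefit.

    The benefit is evaluated on the fitted curves of the reference
    (lowest-RT) condition: RAU(modulated) - RAU(stationary).
    """
    ref = fits[(fits.application == "reference") & (fits.group == group)]
    mod = ref[ref.modulation == "modulated"].set_index("listener")
    stat = ref[ref.modulation == "stationary"].set_index("listener")
    common = mod.index.intersection(stat.index)
    if len(common) == 0:
        raise ValueError(f"no reference fits for group {group}")
    best_snr, best_val = None, -np.inf
    for snr in snr_grid:
        benefits = [
            pf.dip_benefit(_fit_of(mod.loc[l]), _fit_of(stat.loc[l]),
                           float(snr))
            for l in common
        ]
        val = float(np.mean(benefits))
        if val > best_val + 1e-12:
            best_snr, best_val = float(snr), val
    return best_snr


def _anova_table(fits: pd.DataFrame, application: str,
                 snr: float) -> pd.DataFrame:
    scores = rau_scores_at(_app_subset(fits, application), snr)
    table = scores.rename(columns={"listener": "subject",
                                   "modulation": "noise"})
    table["rt"] = table["rt"].astype(str)
    return table[["subject", "group", "rt", "noise", "score"]]


def _pct_inside(fits: pd.DataFrame, application: str, snr: float,
                bounds: tuple[float, float]) -> float:
    sub = _app_subset(fits, application)
    inside = [
        bounds[0] < _fit_of(r)(snr) < bounds[1]
        for r in sub.itertuples()
    ]
    return 100.0 * float(np.mean(inside))


def _bf_entry(result: bz.BayesResult, snr: float, pct: float) -> dict:
    return {
        "bf10": result.bf10,
        "category": result.category,
        "snr": snr,
        "pct_inside_bounds": round(pct, 1),
        "method": result.method,
        "prior_scale": result.prior_scale,
        "mc_error": result.mc_error,
    }


def run_replication(config: ReplicationConfig,
                    out_dir: str | Path | None = None) -> dict:
    """Run the whole in-silico study and return (and optionally write)
    the report.

    Stages: cohort generation, trial simulation, per-listener fitting,
    optimal-SNR selection per application, benefit-maximizing SNR per
    group, then the hypothesis battery.  Identical config and seed give
    a byte-identical JSON report.
    """
    rng = np.random.default_rng(config.rng_seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("cohort", "trials")}

    stage = "cohort"
    try:
        cohort = ch.generate_cohort(config.n_per_group, seeds["cohort"],
                                    config.effect_config, config.design)
        stage = "trials"
        trials = ch.simulate_trials(cohort, config.design, seeds["trials"])
        stage = "fits"
        fits = fit_all_listeners(trials)
        stage = "analysis"
        report = _analyse(fits, config)
    except Exception as e:
        raise RuntimeError(f"replication failed at stage {stage!r}: {e}") \
            from e

    report["provenance"] = {
        "seed": config.rng_seed,
        "stage_seeds": seeds,
        "n_per_group": config.n_per_group,
        "anova_method": config.anova_method,
        "design_cells": len(enumerate_conditions(config.design)),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False)
        fits.to_csv(out / "fits.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def _analyse(fits: pd.DataFrame, config: ReplicationConfig) -> dict:
    grid = config.design.snr_grid
    bounds = config.floor_ceiling_bounds
    method = config.anova_method

    def optimal(application: str) -> float:
        sub = _app_subset(fits, application)
        all_fits = [_fit_of(r) for r in sub.itertuples()]
        return pf.optimal_snr(all_fits, grid, bounds)

    opt = {app: optimal(app) for app in
           ("speech_only", "noise_only", "both")}
    bmax = {g: benefit_maximizing_snr(fits, g, grid) for g in ("NH", "HI")}
    # comparisons across groups use the SNR maximizing the HI benefit
    bmax_common = bmax["HI"]

    def anova(app, snr, target):
        table = _anova_table(fits, app, snr)
        res = bz.mixed_anova_bf(table, target, method=method)
        return _bf_entry(res, snr, _pct_inside(fits, app, snr, bounds))

    def anova_single_group(app, snr, group, target):
        table = _anova_table(fits, app, snr)
        table = table[table.group == group].drop(columns=["group"])
        res = bz.mixed_anova_bf(table, target, method=method)
        return _bf_entry(res, snr, _pct_inside(fits, app, snr, bounds))

    hypotheses: dict[str, dict] = {}
    hypotheses["H1"] = anova("speech_only", opt["speech_only"], "rt:group")
    hypotheses["H2"] = {
        "optimal": anova("noise_only", opt["noise_only"],
                         "group:noise:rt"),
        "benefit_max": anova("noise_only", bmax_common, "group:noise:rt"),
    }
    hypotheses["H3-1"] = {
        "optimal": anova("both", opt["both"], "rt:group"),
        "benefit_max": anova("both", bmax_common, "rt:group"),
    }
    for name, group, snr_b in (("H3-2-a", "NH", bmax["NH"]),
                               ("H3-2-b", "HI", bmax["HI"])):
        hypotheses[name] = {
            "optimal": anova_single_group("both", opt["both"], group,
                                          "noise:rt"),
            "benefit_max": anova_single_group("both", snr_b, group,
                                              "noise:rt"),
        }

    # H1-1: paired t-tests, reference RT vs each higher RT, per group and
    # modulation, at the speech-only optimal SNR
    snr1 = opt["speech_only"]
    scores1 = rau_scores_at(_app_subset(fits, "speech_only"), snr1)
    h11: dict[str, dict] = {}
    rts = sorted(r for r in scores1.rt.unique()
                 if r != config.design.reference_rt)
    for group in ("NH", "HI"):
        for mod in ("stationary", "modulated"):
            ref = scores1[(scores1.group == group)
                          & (scores1.modulation == mod)
                          & (scores1.application == "reference")]
            ref = ref.set_index("listener")["score"]
            for rt in rts:
                test = scores1[(scores1.group == group)
                               & (scores1.modulation == mod)
                               & (scores1.rt == rt)]
                test = test.set_index("listener")["score"]
                common = ref.index.intersection(test.index)
                res = bz.jzs_paired_bf(
                    (ref.loc[common] - test.loc[common]).to_numpy())
                h11[f"{group}:{mod}:rt={rt}"] = {
                    "bf10": res.bf10, "category": res.category,
                    "snr": snr1,
                }
    hypotheses["H1-1"] = h11

    # H1-2: score drop (reference - highest RT) compared across groups
    rt_hi = max(scores1.rt)
    drops = {}
    for group in ("NH", "HI"):
        for mod in ("stationary",):
            ref = scores1[(scores1.group == group)
                          & (scores1.modulation == mod)
                          & (scores1.application == "reference")]
            test = scores1[(scores1.group == group)
                           & (scores1.modulation == mod)
                           & (scores1.rt == rt_hi)]
            merged = ref.set_index("listener")["score"] \
                - test.set_index("listener")["score"]
            drops[group] = merged.dropna().to_numpy()
    res12 = bz.jzs_independent_bf(drops["HI"], drops["NH"])
    hypotheses["H1-2"] = {"bf10": res12.bf10, "category": res12.category,
                          "snr": snr1}

    return {
        "optimal_snr": opt,
        "benefit_maximizing_snr": bmax,
        "hypotheses": hypotheses,
        "n_converged_fits": int(fits.converged.sum()),
        "n_fits": int(len(fits)),
    }


def plot_group_curves(fits: pd.DataFrame, application: str,
                      out_path: str | Path,
                      snr_range: tuple[float, float] = (-20.0, 4.0)):
    """Group-mean RAU curves per condition of one application."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = _app_subset(fits, application)
    x = np.linspace(*snr_range, 200)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, group in zip(axes, ("HI", "NH")):
        gsub = sub[sub.group == group]
        for (rt, mod), cell in gsub.groupby(["rt", "modulation"]):
            mean = pf.mean_group_curve(
                [_fit_of(r) for r in cell.itertuples()])
            ax.plot(x, pf.rau(np.clip(mean(x), 0, 1)),
                    label=f"RT={rt}s {mod}")
        ax.set_title(group)
        ax.set_xlabel("SNR (dB)")
        ax.grid(alpha=0.3)
    axes[0].set_ylabel("score (RAU)")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
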