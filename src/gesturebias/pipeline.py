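"""End-to-end analyses tying simulation, metrics, resampling and models
together.

``analyze_exp1`` reproduces the preference-experiment analysis chain:
exclusions, per-condition chance tests on the forced choice, the
condition-effect logistic, slider OLS models, the instruction-order
check, and the comparison with typology.

``analyze_exp2`` reproduces the learning-experiment chain: per-participant
entropy/MI metrics, bootstrap CIs for condition means and between-condition
differences, the Monte-Carlo experiment null with z-scores, and the
deviation-coded random-intercept logistic models with likelihood-ratio
model comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import EXP2_CONDITIONS, MeaningType, natural_order
from .metrics import participant_metrics
from .models import (
    MEANING_TYPE_CODES,
    SeparationError,
    fit_logistic,
    fit_logistic_intercept,
    fit_logit_glmm,
    fit_ols_rating,
    likelihood_ratio_test,
)
from .resampling import (
    bootstrap_diff_ci,
    bootstrap_mean_ci,
    simulate_null,
    z_score,
)
from .simulate import apply_exclusions, transform_rating
from .typology import experiment_vs_typology

__all__ = ["analyze_exp1", "analyze_exp2"]


def _ci_dict(res) -> dict:
    return {
        "mean": res.point_estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "covers_zero": res.covers_zero,
    }


def analyze_exp1(
    trials: pd.DataFrame, n_boot: int = 10_000, seed: int = 0, method: str = "percentile"
) -> dict:
    """Full preference-experiment analysis; returns a JSON-serializable
    report dict."""
    clean, log = apply_exclusions(trials)
    choice = clean[clean["phase"] == "test"]
    slider = clean[clean["phase"] == "slider"].set_index("participant_id")
    report: dict = {"exclusions": log.to_dict(), "conditions": {}}
    postnominal_props: dict[str, float] = {}
    for meaning in MeaningType:
        rows = choice[choice["meaning_type"] == meaning.value]
        if rows.empty:
            continue
        predicted = natural_order(meaning)
        k = int((rows["order"] == predicted.value).sum())
        n = int(len(rows))
        cond_report: dict = {"n": n, "k_predicted": k, "prop_predicted": k / n}
        try:
            fit = fit_logistic_intercept(k, n)
            cond_report["chance_test"] = fit["intercept"]
        except SeparationError:
            cond_report["chance_test"] = {"error": "separation"}
        # slider OLS: does choosing the predicted order go with stronger ratings?
        sl = slider.loc[rows["participant_id"]]
        ratings = sl["slider_raw"].map(transform_rating).to_numpy()
        predicted_flag = (rows["order"] == predicted.value).astype(float).to_numpy()
        ols = fit_ols_rating(ratings, predicted_flag)
        cond_report["slider_model"] = ols["predicted_order"]
        # instruction-order check (item-first as the coded level)
        instr = (rows["instruction_order"] == "item-first").astype(float).to_numpy()
        if 0 < instr.mean() < 1:
            ifit = fit_logistic(predicted_flag, instr, names=("intercept", "instruction_order"))
            cond_report["instruction_order_model"] = ifit["instruction_order"]
        post_rows = int((rows["order"] == "postnominal").sum())
        postnominal_props[meaning.value] = post_rows / n
        report["conditions"][meaning.value] = cond_report
    # condition effect on predicted-order choice (possessive = +0.5)
    if len(report["conditions"]) == 2:
        predicted_all = np.concatenate(
            [
                (
                    choice[choice["meaning_type"] == m.value]["order"]
                    == natural_order(m).value
                ).astype(float)
                for m in MeaningType
            ]
        )
        cond_codes = np.concatenate(
            [
                np.full(
                    (choice["meaning_type"] == m.value).sum(),
                    MEANING_TYPE_CODES.codes[m.value],
                )
                for m in MeaningType
            ]
        )
        cfit = fit_logistic(predicted_all, cond_codes, names=("intercept", "condition"))
        report["condition_effect"] = cfit["condition"]
        # slider OLS with condition and interaction
        ratings_all, pred_all, codes_all = [], [], []
        for m in MeaningType:
            rows = choice[choice["meaning_type"] == m.value]
            sl = slider.loc[rows["participant_id"]]
            ratings_all.append(sl["slider_raw"].map(transform_rating).to_numpy())
            pred_all.append((rows["order"] == natural_order(m).value).astype(float).to_numpy())
            codes_all.append(np.full(len(rows), MEANING_TYPE_CODES.codes[m.value]))
        ols_full = fit_ols_rating(
            np.concatenate(ratings_all),
            np.concatenate(pred_all),
            np.concatenate(codes_all),
            interaction=True,
        )
        report["slider_condition_model"] = {
            n: ols_full[n] for n in ols_full.names if n != "intercept"
        }
    report["typology_comparison"] = experiment_vs_typology(postnominal_props).to_dict(
        orient="records"
    )
    return report


def _glmm_block(trials: pd.DataFrame, outcome: str, quad_nodes: int) -> dict:
    null = fit_logit_glmm(trials, outcome, fixed=(), quad_nodes=quad_nodes)
    m_nat = fit_logit_glmm(trials, outcome, fixed=("majority_natural",), quad_nodes=quad_nodes)
    m_mean = fit_logit_glmm(trials, outcome, fixed=("meaning_type",), quad_nodes=quad_nodes)
    m_mains = fit_logit_glmm(
        trials, outcome, fixed=("majority_natural", "meaning_type"), quad_nodes=quad_nodes
    )
    m_full = fit_logit_glmm(
        trials,
        outcome,
        fixed=("majority_natural", "meaning_type", "interaction"),
        quad_nodes=quad_nodes,
    )
    lrt = {
        "majority_natural": likelihood_ratio_test(null, m_nat),
        "meaning_type": likelihood_ratio_test(null, m_mean),
        "interaction": likelihood_ratio_test(m_mains, m_full),
    }
    intercept = null["intercept"]
    ci = (
        intercept["coef"] - 1.96 * intercept["se"],
        intercept["coef"] + 1.96 * intercept["se"],
    )
    return {
        "intercept": intercept,
        "intercept_ci": ci,
        "intercept_ci_covers_zero": ci[0] <= 0.0 <= ci[1],
        "random_effect_sd": null.extra["random_effect_sd"],
        "majority_natural_effect": m_nat["majority_natural"],
        "lrt": {k: {"chi2": v[0], "df": v[1], "p": v[2]} for k, v in lrt.items()},
    }


def analyze_exp2(
    trials: pd.DataFrame,
    n_runs: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "percentile",
    quad_nodes: int = 10,
) -> tuple[dict, pd.DataFrame]:
    """Full learning-experiment analysis.

    Returns (report dict, per-participant metrics frame).
    """
    metrics = participant_metrics(trials)
    sample_sizes = metrics.groupby("condition").size().to_dict()
    rng = np.random.default_rng(seed)
    report: dict = {"n_participants": int(len(metrics)), "sample_sizes": sample_sizes}
    labels = [c.label for c in EXP2_CONDITIONS if c.label in sample_sizes]
    for stat_key, col in (("delta_h", "delta_h"), ("delta_mi", "delta_mi")):
        null = simulate_null(
            sample_sizes=sample_sizes,
            statistic=stat_key,
            n_runs=n_runs,
            seed=int(rng.integers(2**31)),
        )
        block: dict = {"simulated": null.summary()}
        overall = metrics[col].to_numpy()
        boot = bootstrap_mean_ci(overall, n_boot, int(rng.integers(2**31)), method)
        block["overall"] = _ci_dict(boot) | {"z": z_score(overall.mean(), null)}
        block["conditions"] = {}
        for label in labels:
            vals = metrics.loc[metrics["condition"] == label, col].to_numpy()
            cb = bootstrap_mean_ci(vals, n_boot, int(rng.integers(2**31)), method)
            cond_null_means = null.condition_run_means[label]
            sd = cond_null_means.std(ddof=1)
            block["conditions"][label] = _ci_dict(cb) | {
                "z": float((vals.mean() - cond_null_means.mean()) / sd)
            }
        diffs = {}
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                va = metrics.loc[metrics["condition"] == la, col].to_numpy()
                vb = metrics.loc[metrics["condition"] == lb, col].to_numpy()
                db = bootstrap_diff_ci(va, vb, n_boot, int(rng.integers(2**31)), method)
                diffs[f"{la} - {lb}"] = _ci_dict(db)
        block["condition_differences"] = diffs
        report[stat_key] = block
    report["learning_model"] = _glmm_block(trials, "majority_order", quad_nodes)
    report["naturalness_model"] = _glmm_block(trials, "natural_order", quad_nodes)
    report["naturalness_preference"] = (
        "no reliable naturalness preference (intercept CI covers 0)"
        if report["naturalness_model"]["intercept_ci_covers_zero"]
        else "reliable naturalness preference (intercept CI excludes 0)"
    )
    return report, metrics


def render_report(report: dict) -> str:
    """Plain-text rendering of an analyze-exp2 report (means, 95% CIs,
    simulation z-scores, model summaries)."""
    lines: list[str] = []
    for stat_key, title in (("delta_h", "Change in entropy"), ("delta_mi", "Change in MI")):
        if stat_key not in report:
            continue
        block = report[stat_key]
        lines.append(f"== {title} ==")
        sim = block["simulated"]
        lines.append(
            f"simulated null: mean {sim['sim_mean']:.4f}, sd {sim['sim_sd']:.4f} "
            f"({sim['n_runs']} runs)"
        )
        o = block["overall"]
        lines.append(
            f"overall: mean {o['mean']:.4f} [{o['ci_low']:.4f}, {o['ci_high']:.4f}], "
            f"z = {o['z']:.2f}"
        )
        for label, c in block["conditions"].items():
            lines.append(
                f"  {label}: {c['mean']:.4f} [{c['ci_low']:.4f}, {c['ci_high']:.4f}], "
                f"z = {c['z']:.2f}"
            )
        lines.append("condition differences (95% bootstrap CIs):")
        for pair, d in block["condition_differences"].items():
            flag = "crosses 0" if d["covers_zero"] else "excludes 0"
            lines.append(
                f"  {pair}: {d['mean']:.3f} [{d['ci_low']:.3f}, {d['ci_high']:.3f}] ({flag})"
            )
        lines.append("")
    for key, title in (
        ("learning_model", "Learning model (majority order)"),
        ("naturalness_model", "Naturalness model (natural order)"),
    ):
        if key not in report:
            continue
        m = report[key]
        i = m["intercept"]
        lines.append(f"== {title} ==")
        lines.append(
            f"intercept: beta = {i['coef']:.3f}, SE = {i['se']:.3f}, "
            f"z = {i['z']:.2f}, p = {i['p']:.3g}"
        )
        lines.append(f"random-intercept SD: {m['random_effect_sd']:.3f}")
        for term, l in m["lrt"].items():
            lines.append(
                f"LRT {term}: chi2({l['df']}) = {l['chi2']:.3f}, p = {l['p']:.3g}"
            )
        lines.append("")
    if "naturalness_preference" in report:
        lines.append(report["naturalness_preference"])
    return "\n".join(lines) + "\n"
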