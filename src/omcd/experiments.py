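"""Monte-Carlo simulation studies of the stopping controller.

Scripted harnesses comparing the reactive controller against its
prospective variant, a retrospective oracle, scenario-specific ideal
controllers and a chosen-value benefit variant, plus the behavioral
signatures (effort, confidence, choice consistency versus the hidden
value difference) the model predicts.

Parameter-sampling ranges for the random-settings sweeps are this
package's documented defaults (log-uniform costs and efficacies around
the reference regime); they are deliberately overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import MCDParams
from .processes import (
    AttributeParams,
    DenoisingParams,
    controller_params_attributes,
    controller_params_denoising,
    ideal_policy_attributes,
    ideal_policy_denoising,
    simulate_attributes_batch,
    simulate_denoising_batch,
    simulate_generic_batch,
)
from .solver import (
    build_grid,
    max_value_benefit,
    solve_optimal_stopping,
    stationary_kernel,
)
from .trials import OnlinePolicy, OraclePolicy, ProspectivePolicy, run_batch

__all__ = [
    "SweepSpec",
    "DEFAULT_RANGES",
    "sample_random_settings",
    "solve_online_policy",
    "compare_policies",
    "random_settings_comparison",
    "difficulty_sweep",
    "scenario_comparison",
    "benefit_comparison",
    "behavioral_signatures",
    "logistic_slope",
]

#: default sampling ranges for random decision-parameter settings.
#: alpha/beta/gamma log-uniform, nu uniform; R and kappa held fixed
#: (R trades off exactly against alpha, so it is redundant to sample).
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "alpha": (0.05, 1.0),
    "beta": (0.5, 8.0),
    "gamma": (0.5, 8.0),
    "nu": (0.25, 2.0),
}


@dataclass
class SweepSpec:
    """Specification of a random-settings sweep."""

    n_settings: int = 200
    n_trials: int = 500
    seed: int = 0
    ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    kappa: float = 0.01
    R: float = 1.0
    n_points: int = 257

    def __post_init__(self):
        if self.n_settings < 1 or self.n_trials < 1:
            raise ValueError("n_settings and n_trials must be >= 1")


def sample_random_settings(spec: SweepSpec, seed: Optional[int] = None) -> List[MCDParams]:
    """Reproducible random decision-parameter settings.

    alpha, beta, gamma are log-uniform on their ranges; nu is uniform.
    All draws satisfy the parameter invariants (in particular alpha > 0
    and gamma > 0, so stopping thresholds exist at all times).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out = []
    for _ in range(spec.n_settings):
        kw = {}
        for name, (lo, hi) in spec.ranges.items():
            if name in ("alpha", "beta", "gamma"):
                kw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                kw[name] = float(rng.uniform(lo, hi))
        out.append(MCDParams(R=spec.R, kappa=spec.kappa, **kw))
    return out


def solve_online_policy(
    params: MCDParams, n_points: int = 513, width_mult: float = 6.0, benefit=None
) -> OnlinePolicy:
    """Solve the stopping thresholds and wrap them as a batch policy."""
    grid = build_grid(params, n_points=n_points, width_mult=width_mult)
    kernel = stationary_kernel(grid, params.gamma, params.kappa)
    return OnlinePolicy(solve_optimal_stopping(params, kernel, benefit))


def _summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-policy mean and SD of investment, confidence and net benefit."""
    g = records.groupby("policy_label", sort=False)
    out = g.agg(
        n=("trial", "size"),
        mean_z=("z_invested", "mean"),
        sd_z=("z_invested", "std"),
        mean_confidence=("confidence_at_stop", "mean"),
        sd_confidence=("confidence_at_stop", "std"),
        mean_net_benefit=("net_benefit", "mean"),
        sd_net_benefit=("net_benefit", "std"),
        se_net_benefit=("net_benefit", "sem"),
    ).reset_index()
    return out


def _decile_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Mean confidence per resource-investment decile, per policy."""
    rows = []
    for label, sub in records.groupby("policy_label", sort=False):
        try:
            dec = pd.qcut(sub["z_invested"], 10, labels=False, duplicates="drop")
        except ValueError:  # constant investment (e.g. prospective policy)
            dec = pd.Series(0, index=sub.index)
        g = sub.groupby(dec)
        rows.append(
            pd.DataFrame(
                {
                    "policy_label": label,
                    "decile": g.size().index,
                    "mean_z": g["z_invested"].mean().values,
                    "mean_confidence": g["confidence_at_stop"].mean().values,
                    "sd_confidence": g["confidence_at_stop"].std().values,
                    "n": g.size().values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def compare_policies(
    params: Optional[MCDParams] = None,
    n_trials: int = 500,
    seed: int = 0,
    n_points: int = 513,
) -> Dict[str, object]:
    """Reactive vs prospective vs oracle policies on shared paths.

    Defaults to the reference decision parameters.  Returns the trial
    records, a per-policy summary (mean/SD of investment, confidence,
    net benefit) and the confidence-by-investment-decile curves.
    """
    params = params or MCDParams()
    online = solve_online_policy(params, n_points=n_points)
    policies = [online, ProspectivePolicy(params), OraclePolicy()]
    records = run_batch(("generic", params), policies, params, n_trials, seed)
    return {
        "records": records,
        "summary": _summary(records),
        "deciles": _decile_curve(records),
        "policy": online.policy,
    }


def random_settings_comparison(spec: SweepSpec) -> Dict[str, object]:
    """Reactive vs prospective controllers across random settings.

    For each sampled setting, both policies run on the same simulated
    paths; the output reports per-setting means and, across settings,
    the correlation between the two policies' outputs, a sign test on
    the net-benefit improvement and the fraction of settings where the
    reactive controller invests no more than the prospective one.
    """
    settings = sample_random_settings(spec)
    rows = []
    for i, params in enumerate(settings):
        online = solve_online_policy(params, n_points=spec.n_points)
        rec = run_batch(
            ("generic", params),
            [online, ProspectivePolicy(params)],
            params,
            spec.n_trials,
            spec.seed + 1000 + i,
        )
        s = _summary(rec).set_index("policy_label")
        rows.append(
            {
                "setting": i,
                "alpha": params.alpha,
                "beta": params.beta,
                "gamma": params.gamma,
                "nu": params.nu,
                "z_omcd": s.loc["omcd", "mean_z"],
                "z_prospective": s.loc["prospective", "mean_z"],
                "conf_omcd": s.loc["omcd", "mean_confidence"],
                "conf_prospective": s.loc["prospective", "mean_confidence"],
                "nb_omcd": s.loc["omcd", "mean_net_benefit"],
                "nb_prospective": s.loc["prospective", "mean_net_benefit"],
            }
        )
    df = pd.DataFrame(rows)
    diff = df["nb_omcd"] - df["nb_prospective"]
    n_pos = int((diff > 0).sum())
    sign_p = stats.binomtest(n_pos, len(diff), 0.5, alternative="greater").pvalue
    out = {
        "settings": df,
        "corr_z": float(df["z_omcd"].corr(df["z_prospective"])),
        "corr_confidence": float(df["conf_omcd"].corr(df["conf_prospective"])),
        "corr_net_benefit": float(df["nb_omcd"].corr(df["nb_prospective"])),
        "mean_net_benefit_gain": float(diff.mean()),
        "sign_test_p": float(sign_p),
        "frac_fewer_resources": float((df["z_omcd"] <= df["z_prospective"]).mean()),
    }
    return out


def difficulty_sweep(
    betas: Sequence[float] = tuple(range(2, 9)),
    other: float = 4.0,
    n_trials: int = 500,
    seed: int = 0,
    kappa: float = 0.01,
    sigma0: Optional[float] = None,
    n_points: int = 513,
) -> Dict[str, object]:
    """Difficulty manipulation: sweep type-1 efficacy, all else fixed.

    Lower beta means value precision improves more slowly -- a harder
    decision.  All other decision parameters (R, alpha, gamma, nu and,
    unless overridden, the prior variance sigma0) take the common value
    ``other``; the prior modes are symmetric (mu0 = 0).  Reports
    per-beta summaries and within-beta confidence-by-investment decile
    curves for the reactive policy.
    """
    if sigma0 is None:
        sigma0 = other
    per_beta = []
    deciles = []
    for i, beta in enumerate(betas):
        params = MCDParams(
            R=other,
            alpha=other,
            nu=other,
            beta=float(beta),
            gamma=other,
            kappa=kappa,
            mu0=(0.0, 0.0),
            sigma0=(sigma0, sigma0),
        )
        online = solve_online_policy(params, n_points=n_points)
        rec = run_batch(
            ("generic", params),
            [online, ProspectivePolicy(params)],
            params,
            n_trials,
            seed + i,
        )
        s = _summary(rec).set_index("policy_label")
        per_beta.append(
            {
                "beta": float(beta),
                "mean_z_omcd": s.loc["omcd", "mean_z"],
                "sd_z_omcd": s.loc["omcd", "sd_z"],
                "mean_conf_omcd": s.loc["omcd", "mean_confidence"],
                "sd_conf_omcd": s.loc["omcd", "sd_confidence"],
                "z_prospective": s.loc["prospective", "mean_z"],
                "conf_prospective": s.loc["prospective", "mean_confidence"],
            }
        )
        d = _decile_curve(rec[rec.policy_label == "omcd"])
        d.insert(0, "beta", float(beta))
        deciles.append(d)
    return {"per_beta": pd.DataFrame(per_beta), "deciles": pd.concat(deciles, ignore_index=True)}


# ---------------------------------------------------------------------
# ideal-policy and alternative-benefit comparisons


def _policy_metrics(batch, stops, params) -> Dict[str, float]:
    idx = np.arange(batch.n)
    conf = batch.confidence_matrix()[idx, stops]
    nb = params.R * conf - np.asarray(params.cost(stops))
    return {
        "mean_z": float(np.mean(params.kappa * stops)),
        "mean_confidence": float(np.mean(conf)),
        "mean_net_benefit": float(np.mean(nb)),
        "se_net_benefit": float(np.std(nb, ddof=1) / np.sqrt(len(nb))),
    }


def scenario_comparison(
    scenario: str,
    n_settings: int = 200,
    n_trials: int = 500,
    seed: int = 0,
    k: int = 10,
    n_points: int = 257,
) -> Dict[str, object]:
    """Calibrated controller vs scenario-specific ideal policy.

    For each random setting of the scenario's parameters, the agnostic
    controller (analytic beta/gamma calibration, stationary kernel) and
    the ideal policy (true transition statistics) run on the same
    simulated paths.  Reports per-setting means and the across-settings
    association of the two policies' outcomes.
    """
    if scenario not in ("denoising", "attributes"):
        raise ValueError("scenario must be 'denoising' or 'attributes'")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_settings):
        if scenario == "denoising":
            dp = DenoisingParams(
                mu0=0.0,
                sigma0=float(np.exp(rng.uniform(np.log(3.0), np.log(30.0)))),
                Sigma=float(np.exp(rng.uniform(np.log(30.0), np.log(300.0)))),
                kappa=0.01,
            )
            alpha = float(np.exp(rng.uniform(np.log(0.02), np.log(0.5))))
            nu = float(rng.uniform(1.0, 3.0))
            params = controller_params_denoising(dp, R=1.0, alpha=alpha, nu=nu)
            online = solve_online_policy(params, n_points=n_points)
            ideal = OnlinePolicy(
                ideal_policy_denoising(dp, R=1.0, alpha=alpha, nu=nu, n_points=n_points),
                label="ideal",
            )
            batch = simulate_denoising_batch(
                dp, n_trials, np.random.default_rng(seed + 7000 + i)
            )
        else:
            ap = AttributeParams(
                k=k,
                eta=rng.uniform(0.0, 2.0, size=k),
                varsigma=np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=k)),
                w=rng.uniform(0.2, 1.0, size=k),
            )
            alpha = float(np.exp(rng.uniform(np.log(0.5), np.log(5.0))))
            nu = float(rng.uniform(1.0, 4.0))
            params = controller_params_attributes(ap, R=1.0, alpha=alpha, nu=nu)
            online = solve_online_policy(params, n_points=n_points)
            ideal = ideal_policy_attributes(
                ap, R=1.0, alpha=alpha, nu=nu, n_points=min(n_points, 161)
            )
            batch = simulate_attributes_batch(
                ap, n_trials, np.random.default_rng(seed + 7000 + i)
            )
        m_omcd = _policy_metrics(batch, online.stop_times(batch, params), params)
        m_ideal = _policy_metrics(batch, np.asarray(ideal.stop_times(batch, params)), params)
        row = {"setting": i, "alpha": params.alpha, "nu": params.nu,
               "beta": params.beta, "gamma": params.gamma}
        row.update({f"{k_}_omcd": v for k_, v in m_omcd.items()})
        row.update({f"{k_}_ideal": v for k_, v in m_ideal.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    return {
        "settings": df,
        "corr_z": float(df["mean_z_omcd"].corr(df["mean_z_ideal"])),
        "corr_confidence": float(
            df["mean_confidence_omcd"].corr(df["mean_confidence_ideal"])
        ),
        "corr_net_benefit": float(
            df["mean_net_benefit_omcd"].corr(df["mean_net_benefit_ideal"])
        ),
    }


def benefit_comparison(
    n_settings: int = 200,
    n_trials: int = 500,
    seed: int = 0,
    n_points: int = 257,
) -> Dict[str, object]:
    """Confidence-benefit controller vs chosen-value benefit controller.

    Both stopping rules are solved for each random setting and applied
    to the same generic trajectories; each trial is scored under both
    benefit definitions (R*confidence - cost and R*E[chosen value] -
    cost).
    """
    spec = SweepSpec(n_settings=n_settings, n_trials=n_trials, seed=seed)
    settings = sample_random_settings(spec)
    rows = []
    for i, params in enumerate(settings):
        online = solve_online_policy(params, n_points=n_points)
        maxval = solve_online_policy(
            params, n_points=n_points, benefit=max_value_benefit(params)
        )
        maxval.label = "maxval"
        batch = simulate_generic_batch(
            params, n_trials, np.random.default_rng(seed + 3000 + i)
        )
        mu_bar0 = 0.5 * (params.mu0[0] + params.mu0[1])
        row = {"setting": i, "alpha": params.alpha, "beta": params.beta,
               "gamma": params.gamma, "nu": params.nu}
        for pol, tag in ((online, "omcd"), (maxval, "maxval")):
            stops = pol.stop_times(batch, params)
            idx = np.arange(batch.n)
            conf = batch.confidence_matrix()[idx, stops]
            dmu = np.abs(batch.delta_mu[idx, stops])
            cost = np.asarray(params.cost(stops))
            row[f"mean_z_{tag}"] = float(np.mean(params.kappa * stops))
            row[f"mean_confidence_{tag}"] = float(np.mean(conf))
            row[f"nb_mcd_{tag}"] = float(np.mean(params.R * conf - cost))
            row[f"nb_maxval_{tag}"] = float(
                np.mean(params.R * (mu_bar0 + 0.5 * dmu) - cost)
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return {
        "settings": df,
        "mean_mcd_benefit_edge": float((df["nb_mcd_omcd"] - df["nb_mcd_maxval"]).mean()),
        "mean_maxval_benefit_edge": float(
            (df["nb_maxval_maxval"] - df["nb_maxval_omcd"]).mean()
        ),
        "frac_fewer_resources": float((df["mean_z_omcd"] <= df["mean_z_maxval"]).mean()),
    }


# ---------------------------------------------------------------------
# behavioral signatures


#: cap on logistic slopes under (quasi-)separation
SLOPE_CAP = 50.0


def logistic_slope(x: np.ndarray, y: np.ndarray) -> Dict[str, float]:
    """Max-likelihood slope of P(y=1) = s(b0 + b1*x) with its SE.

    Fitted by iteratively reweighted least squares (statsmodels GLM).
    Under (quasi-)separation the slope diverges; it is capped at
    +/-SLOPE_CAP and flagged.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(x)
    capped = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        slope = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(slope) or not np.isfinite(se) or abs(slope) > SLOPE_CAP:
            capped = True
    except Exception:
        capped = True
        slope, se = np.nan, np.nan
    if capped:
        sign = np.sign(np.corrcoef(x, y)[0, 1]) if len(x) > 1 else 1.0
        slope = float(sign * SLOPE_CAP) if not np.isfinite(slope) else float(
            np.clip(slope, -SLOPE_CAP, SLOPE_CAP)
        )
        se = np.nan
    return {"slope": slope, "se": se, "capped": capped}


def _corr_row(stat, subset, x, y) -> Dict[str, object]:
    n = len(x)
    if n < 3:
        return {"statistic": stat, "subset": subset, "value": np.nan,
                "p": np.nan, "n": n}
    r, p = stats.pearsonr(x, y)
    return {"statistic": stat, "subset": subset, "value": float(r),
            "p": float(p), "n": n}


def behavioral_signatures(
    scenario: str = "denoising",
    n_trials: int = 10_000,
    seed: int = 0,
    dp: Optional[DenoisingParams] = None,
    ap: Optional[AttributeParams] = None,
    R: float = 1.0,
    alpha: Optional[float] = None,
    nu: Optional[float] = None,
    n_points: int = 513,
) -> pd.DataFrame:
    """Simulated signatures relating effort, confidence and hidden value.

    Defaults reproduce the canonical regimes: denoising with R=1,
    alpha=0.1, nu=2, sigma0=10, mu0=0, Sigma=100; attribute integration
    with R=1, alpha=3, nu=4, k=20, unit attribute moments.  Computes
    (a) the correlation of invested resources with |hidden value
    difference| overall and within high/low-confidence halves,
    (b) logistic choice-vs-value slopes overall and per confidence half,
    (c) the correlation of confidence with |hidden value difference|
    overall and within value-consistent/inconsistent trials, and
    (d) the mean confidence gap between consistent and inconsistent
    trials (Welch t-test).  Returns a tidy statistics table.
    """
    if scenario == "denoising":
        dp = dp or DenoisingParams(mu0=0.0, sigma0=10.0, Sigma=100.0, kappa=0.01)
        alpha = 0.1 if alpha is None else alpha
        nu = 2.0 if nu is None else nu
        params = controller_params_denoising(dp, R=R, alpha=alpha, nu=nu)
        batch = simulate_denoising_batch(dp, n_trials, np.random.default_rng(seed))
    elif scenario == "attributes":
        ap = ap or AttributeParams(k=20, eta=1.0, varsigma=1.0, w=1.0)
        alpha = 3.0 if alpha is None else alpha
        nu = 4.0 if nu is None else nu
        params = controller_params_attributes(ap, R=R, alpha=alpha, nu=nu)
        batch = simulate_attributes_batch(ap, n_trials, np.random.default_rng(seed))
    else:
        raise ValueError("scenario must be 'denoising' or 'attributes'")

    online = solve_online_policy(params, n_points=n_points)
    rec = run_batch(batch, [online], params, n_trials, seed + 1)
    z = rec["z_invested"].to_numpy()
    conf = rec["confidence_at_stop"].to_numpy()
    choice01 = (rec["choice"].to_numpy() > 0).astype(float)
    dv = rec["hidden_value_diff"].to_numpy()
    absdv = np.abs(dv)
    consistent = rec["value_consistent"].to_numpy().astype(bool)

    med = np.median(conf)
    high = conf > med
    low = ~high

    rows: List[Dict[str, object]] = []
    rows.append(_corr_row("corr_z_absdv", "all", z, absdv))
    rows.append(_corr_row("corr_z_absdv", "high_confidence", z[high], absdv[high]))
    rows.append(_corr_row("corr_z_absdv", "low_confidence", z[low], absdv[low]))

    for subset, m in (("all", slice(None)), ("high_confidence", high), ("low_confidence", low)):
        if np.size(choice01[m]) == 0:
            rows.append({"statistic": "logistic_slope", "subset": subset,
                         "value": np.nan, "p": np.nan, "n": 0})
            continue
        fit = logistic_slope(dv[m], choice01[m])
        p = (
            np.nan
            if not np.isfinite(fit["se"])
            else 2 * stats.norm.sf(abs(fit["slope"] / fit["se"]))
        )
        rows.append({"statistic": "logistic_slope", "subset": subset,
                     "value": fit["slope"], "p": p, "n": int(np.sum(np.ones_like(choice01[m])))})

    fit_h = logistic_slope(dv[high], choice01[high]) if high.any() else None
    fit_l = logistic_slope(dv[low], choice01[low]) if low.any() else None
    if (
        fit_h is not None
        and fit_l is not None
        and np.isfinite(fit_h["se"])
        and np.isfinite(fit_l["se"])
    ):
        diff = fit_h["slope"] - fit_l["slope"]
        se = np.sqrt(fit_h["se"] ** 2 + fit_l["se"] ** 2)
        p = float(stats.norm.sf(diff / se))  # one-sided: high > low
        rows.append({"statistic": "logistic_slope_diff", "subset": "high_minus_low",
                     "value": float(diff), "p": p, "n": int(high.sum() + low.sum())})
    else:
        rows.append({"statistic": "logistic_slope_diff", "subset": "high_minus_low",
                     "value": np.nan, "p": np.nan, "n": int(high.sum() + low.sum())})

    rows.append(_corr_row("corr_conf_absdv", "all", conf, absdv))
    rows.append(_corr_row("corr_conf_absdv", "consistent", conf[consistent], absdv[consistent]))
    rows.append(
        _corr_row("corr_conf_absdv", "inconsistent", conf[~consistent], absdv[~consistent])
    )

    if consistent.all() or (~consistent).all():
        rows.append({"statistic": "conf_consistency_gap", "subset": "all",
                     "value": np.nan, "p": np.nan,
                     "n": int(min(consistent.sum(), (~consistent).sum()))})
    else:
        tt = stats.ttest_ind(conf[consistent], conf[~consistent], equal_var=False)
        rows.append({"statistic": "conf_consistency_gap", "subset": "all",
                     "value": float(conf[consistent].mean() - conf[~consistent].mean()),
                     "p": float(tt.pvalue), "n": len(conf)})
    return pd.DataFrame(rows, columns=["statistic", "subset", "value", "p", "n"])
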