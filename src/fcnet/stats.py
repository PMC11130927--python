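"""Group × Movie mixed factorial inference on network metrics.

Each metric at each scope is modelled as

    value ~ group + movie + group:movie  (+ per-subject random intercept)

with treatment coding (control, 2D as reference levels), fit by REML.  The
group coefficient ``beta_tbi`` — the mTBI-minus-control offset — is the
primary readout; its sign and significance are what the planted-effect
recovery tests check.  With two within-subject levels the random-intercept
model coincides with the classical two-way mixed ANOVA in the balanced
case.  Wald two-sided p-values are reported per coefficient, and the
``beta_tbi`` p-values are Benjamini–Hochberg adjusted within families of
scopes (streams per metric; regions), while global-scope tests are
reported unadjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

log = logging.getLogger(__name__)

GROUP_PATIENT = "mTBI"
GROUP_CONTROL = "control"


class SingleGroupError(ValueError):
    """Raised when the design lacks one of the two groups."""


@dataclass
class EffectResult:
    metric: str
    scope: str
    beta_tbi: float
    se_tbi: float
    p_raw: float
    beta_movie: float
    se_movie: float
    p_movie: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    n_subjects: int
    p_adjusted: float = np.nan
    degenerate: bool = False
    model_result: object = field(default=None, repr=False, compare=False)


def aggregate_clips(table: pd.DataFrame, clip_handling: str = "average") -> pd.DataFrame:
    """Collapse clips within subject × condition × scope × metric.

    ``average`` takes the mean across clips (the clip column is dropped);
    ``replicate`` keeps clips as repeated observations.  Subjects missing a
    condition entirely are dropped with a warning — the within-subject
    contrast is undefined for them.
    """
    if clip_handling == "replicate":
        out = table.copy()
    elif clip_handling == "average":
        keys = ["subject_id", "group", "condition", "scope", "metric"]
        out = table.groupby(keys, as_index=False, sort=False)["value"].mean()
    else:
        raise ValueError("clip_handling must be 'average' or 'replicate'")
    conds = out.groupby("subject_id", sort=False)["condition"].nunique()
    expected = table["condition"].nunique()
    incomplete = conds.index[conds < expected]
    if len(incomplete):
        log.warning("dropping %d subject(s) missing a condition: %s",
                    len(incomplete), ", ".join(map(str, incomplete[:5])))
        out = out[~out["subject_id"].isin(incomplete)]
    return out.reset_index(drop=True)


def fit_group_model(
    table: pd.DataFrame,
    metric: str,
    scope: str,
    clip_handling: str = "average",
    polish: bool = True,
) -> EffectResult:
    """Fit the mixed factorial model for one metric at one scope.

    Expects a long-format table (subject_id, group, condition, clip, scope,
    metric, value).  A zero-variance response cannot support inference: the
    fit is flagged degenerate with zero effects and p = 1.  ``polish``
    adds a second, tightly-converged REML pass from the warm start; large
    simulation studies that only need signs and approximate p-values can
    disable it.
    """
    df = table[(table["metric"] == metric) & (table["scope"] == scope)]
    if df.empty:
        raise ValueError(f"no rows for metric={metric!r} scope={scope!r}")
    df = aggregate_clips(df, clip_handling)
    groups_present = set(df["group"].unique())
    if not {GROUP_PATIENT, GROUP_CONTROL} <= groups_present:
        raise SingleGroupError(
            f"need both {GROUP_PATIENT!r} and {GROUP_CONTROL!r} groups, "
            f"got {sorted(groups_present)}"
        )
    for g in (GROUP_PATIENT, GROUP_CONTROL):
        if df.loc[df["group"] == g, "subject_id"].nunique() < 2:
            raise SingleGroupError(f"need >= 2 subjects in group {g!r}")
    n_subjects = df["subject_id"].nunique()

    work = pd.DataFrame(
        {
            "value": df["value"].to_numpy(dtype=float),
            "tbi": (df["group"] == GROUP_PATIENT).astype(float).to_numpy(),
            "movie3d": (df["condition"] == "3D").astype(float).to_numpy(),
            "subject_id": df["subject_id"].to_numpy(),
        }
    )
    if np.ptp(work["value"].to_numpy()) == 0.0:
        log.warning("degenerate fit for %s @ %s: zero-variance response", metric, scope)
        return EffectResult(metric, scope, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0,
                            0.0, 0.0, 1.0, n_subjects, degenerate=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            model = smf.mixedlm("value ~ tbi * movie3d", work, groups=work["subject_id"])
            res = model.fit(reml=True)
            # polish to tight REML convergence (cheap from the warm start);
            # in the balanced case this recovers classical mixed-ANOVA F
            # statistics to near machine precision
            if polish:
                from statsmodels.regression.mixed_linear_model import (
                    MixedLMParams,
                )

                try:
                    start = MixedLMParams.from_components(
                        fe_params=np.asarray(res.fe_params),
                        cov_re=np.asarray(res.cov_re) / res.scale,
                    )
                    res = model.fit(reml=True, start_params=start,
                                    method="bfgs", gtol=1e-13)
                except (np.linalg.LinAlgError, ValueError):
                    pass
            params, bses, pvals = res.fe_params, res.bse_fe, res.pvalues
        except np.linalg.LinAlgError:
            # Near-zero between-subject variance can defeat the mixed fit;
            # the fixed-effect estimates then coincide with OLS.
            log.warning("mixed fit failed for %s @ %s; falling back to OLS",
                        metric, scope)
            res = smf.ols("value ~ tbi * movie3d", work).fit()
            params, bses, pvals = res.params, res.bse, res.pvalues

    def pick(name):
        return float(params[name]), float(bses[name]), float(pvals[name])

    b_t, se_t, p_t = pick("tbi")
    b_m, se_m, p_m = pick("movie3d")
    b_i, se_i, p_i = pick("tbi:movie3d")
    return EffectResult(metric, scope, b_t, se_t, p_t, b_m, se_m, p_m,
                        b_i, se_i, p_i, n_subjects, model_result=res)


def adjust_across_scopes(results: list[EffectResult], family: str = "streams") -> list[EffectResult]:
    """Benjamini–Hochberg adjust the ``beta_tbi`` p-values within one family.

    A family is one multiplicity unit — e.g. the four stream scopes of one
    metric, or the set of region-efficiency scopes.  Adjusted p-values are
    written back onto the results (returned for convenience).
    """
    if not results:
        raise ValueError(f"empty family {family!r}")
    p_raw = np.array([r.p_raw for r in results], dtype=float)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    for r, p in zip(results, p_adj):
        r.p_adjusted = float(p)
    return results


def run_group_models(
    table: pd.DataFrame,
    clip_handling: str = "average",
) -> pd.DataFrame:
    """Fit every metric × scope model present in a metric table.

    Families for adjustment: per metric, its ``stream:*`` scopes form one
    family; all ``region:*`` efficiency scopes form another; ``global``
    scopes are reported with ``p_adjusted = p_raw`` (a single unadjusted
    test per metric, as in a primary whole-graph analysis).
    """
    groups_present = set(table["group"].unique())
    if not {GROUP_PATIENT, GROUP_CONTROL} <= groups_present:
        raise SingleGroupError(
            f"need both {GROUP_PATIENT!r} and {GROUP_CONTROL!r} groups, "
            f"got {sorted(groups_present)}"
        )
    results: list[EffectResult] = []
    combos = table[["metric", "scope"]].drop_duplicates()
    by_metric_stream: dict[str, list[EffectResult]] = {}
    region_family: list[EffectResult] = []
    for metric, scope in combos.itertuples(index=False):
        try:
            res = fit_group_model(table, metric, scope, clip_handling)
        except SingleGroupError as exc:
            # a scope can lose subjects when its rows are undefined for some
            # recordings (e.g. modularity of an edgeless subgraph)
            log.warning("skipping %s @ %s: %s", metric, scope, exc)
            continue
        results.append(res)
        if scope.startswith("stream:"):
            by_metric_stream.setdefault(metric, []).append(res)
        elif scope.startswith("region:"):
            region_family.append(res)
        else:
            res.p_adjusted = res.p_raw
    for metric, fam in by_metric_stream.items():
        adjust_across_scopes(fam, family=f"streams/{metric}")
    if region_family:
        adjust_across_scopes(region_family, family="regions")

    rows = [
        {
            "metric": r.metric, "scope": r.scope,
            "beta_tbi": r.beta_tbi, "se": r.se_tbi,
            "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
            "beta_movie": r.beta_movie, "beta_interaction": r.beta_interaction,
            "n_subjects": r.n_subjects, "degenerate": r.degenerate,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
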