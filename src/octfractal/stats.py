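"""Group comparison and discrimination statistics for eye-level features.

Two analyses per feature (layer thickness, fractal dimension, normalized
reflectivity):

* one-way ANOVA followed by the Newman-Keuls step-down studentized-range
  post-hoc procedure, with significance declared at a fixed p < 0.001;
* an ROC analysis with a *fixed* orientation — lower values call disease
  unless stated otherwise — so the AUROC is deliberately not folded to
  >= 0.5 (a feature that rises with disease simply scores below 0.5 under
  this orientation).  The AUROC is the Mann-Whitney concordance
  (midranks give tied pairs weight 1/2); its standard error uses the
  Hanley-McNeil formula and the 95% CI is the asymptotic A +- 1.96 SE.

The operating cutoff follows either the Youden rule (maximize
sensitivity + specificity - 1, ties resolved toward higher specificity) or
the healthy-reference rule: mean - 2 SD of the healthy group for features
lowered by disease (+ 2 SD for raised ones).  The positive likelihood
ratio is sensitivity / (1 - specificity), flagged infinite when
specificity is 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layers import LAYERS
from .oct_io import FEATURES, GROUP_DISEASED, GROUP_HEALTHY, feature_column

DEFAULT_ALPHA = 0.001  # the study's fixed significance threshold


@dataclasses.dataclass
class GroupData:
    """One feature's eye-level values split by group."""

    feature: str
    values: list[np.ndarray]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if len(self.values) != len(self.labels):
            raise ValueError("one label per group required")
        if len(self.values) < 2:
            raise ValueError("need at least 2 groups")
        if any(len(v) < 2 for v in self.values):
            raise ValueError("each group needs at least 2 values")


@dataclasses.dataclass
class RocResult:
    """Discrimination summary of one feature for a two-group contrast."""

    auroc: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    cutoff_rule: str
    sensitivity: float
    specificity: float
    plr: float               # inf when specificity == 1
    direction: str           # 'low': low values call disease; 'high': reverse
    plr_infinite: bool = False
    degenerate_sd: bool = False


# ---------------------------------------------------------------------------
# ANOVA and Newman-Keuls
# ---------------------------------------------------------------------------


def anova_oneway(data: GroupData) -> tuple[float, float]:
    """Classical one-way F statistic and p value across the groups.

    With zero within-group variance but unequal means the p value
    degenerates to 0 (below machine floor).
    """
    f, p = sps.f_oneway(*data.values)
    if np.isnan(f):  # zero within-group variance
        means = [v.mean() for v in data.values]
        if np.ptp(means) > 0:
            return float("inf"), 0.0
        return 0.0, 1.0
    return float(f), float(p)


def newman_keuls(data: GroupData, alpha: float = 0.05) -> pd.DataFrame:
    """Step-down studentized-range (Newman-Keuls) pairwise comparisons.

    Groups are ordered by mean; each pair is tested at the critical value
    of the studentized range for its span r (number of means enclosed),
    and a pair is declared significant only if every enclosing span was
    significant (step-down blocking).  Unequal group sizes use the
    harmonic mean n (flagged in the output).

    Returns a table with one row per pair: means, q, span, critical q,
    p value, ``reject`` and ``blocked`` flags.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    k = len(data.values)
    ns = np.array([len(v) for v in data.values])
    big_n = int(ns.sum())
    means = np.array([v.mean() for v in data.values])
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values)
    df_within = big_n - k
    ms_within = ss_within / df_within
    unequal = len(set(ns.tolist())) > 1
    n_h = k / np.sum(1.0 / ns)  # harmonic mean group size

    order = np.argsort(means)
    sig = np.zeros((k, k), dtype=bool)  # over ordered indices i < j
    rows = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            gi, gj = order[i], order[j]
            diff = abs(means[gj] - means[gi])
            if ms_within > 0:
                q = diff / np.sqrt(ms_within / n_h)
                q_crit = float(sps.studentized_range.isf(alpha, span, df_within))
                p = float(sps.studentized_range.sf(q, span, df_within))
            else:
                q = float("inf") if diff > 0 else 0.0
                q_crit = float("nan")
                p = 0.0 if diff > 0 else 1.0
            parents_ok = True
            if span < k:
                if i > 0 and not sig[i - 1, j]:
                    parents_ok = False
                if j < k - 1 and not sig[i, j + 1]:
                    parents_ok = False
            own = p < alpha
            sig[i, j] = own and parents_ok
            rows.append(
                {
                    "group_i": data.labels[gi],
                    "group_j": data.labels[gj],
                    "mean_i": means[gi],
                    "mean_j": means[gj],
                    "span": span,
                    "q": q,
                    "q_crit": q_crit,
                    "p_value": p,
                    "blocked": own and not parents_ok,
                    "reject": bool(sig[i, j]),
                    "harmonic_n": unequal,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def _oriented(x: np.ndarray, direction: str) -> np.ndarray:
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    return -np.asarray(x, float) if direction == "low" else np.asarray(x, float)


def auroc(controls, cases, direction: str = "low") -> float:
    """Concordance index: P(case scored more disease-like than control).

    Computed from midranks (Mann-Whitney U / n1 n2), so tied case-control
    pairs count 1/2.  Under 'low' orientation a case with a *lower* value
    than a control counts as concordant.
    """
    controls = _oriented(np.asarray(controls, float), direction)
    cases = _oriented(np.asarray(cases, float), direction)
    if len(controls) == 0 or len(cases) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([controls, cases])
    ranks = sps.rankdata(combined)
    n1, n2 = len(controls), len(cases)
    u = ranks[n1:].sum() - n2 * (n2 + 1) / 2.0
    return float(u / (n1 * n2))


def roc_curve(controls, cases, direction: str = "low") -> pd.DataFrame:
    """Empirical ROC points over all distinct thresholds.

    Under 'low' orientation the test is "value <= threshold calls disease";
    under 'high' it is ">=".  Returns a table (threshold, fpr, tpr) ordered
    from (0, 0) to (1, 1), with the degenerate all-negative point included.
    """
    controls = np.asarray(controls, float)
    cases = np.asarray(cases, float)
    if len(controls) == 0 or len(cases) == 0:
        raise ValueError("both groups must be non-empty")
    thresholds = np.unique(np.concatenate([controls, cases]))
    if direction == "low":
        tpr = [(cases <= t).mean() for t in thresholds]
        fpr = [(controls <= t).mean() for t in thresholds]
        edge = thresholds[0] - 1.0
    else:
        thresholds = thresholds[::-1]
        tpr = [(cases >= t).mean() for t in thresholds]
        fpr = [(controls >= t).mean() for t in thresholds]
        edge = thresholds[0] + 1.0
    df = pd.DataFrame(
        {
            "threshold": np.concatenate([[edge], thresholds]),
            "fpr": np.concatenate([[0.0], fpr]),
            "tpr": np.concatenate([[0.0], tpr]),
        }
    )
    return df


def auroc_se(auroc_value: float, n1: int, n2: int) -> float:
    """Hanley-McNeil standard error of the AUROC.

    Q1 = A / (2 - A), Q2 = 2 A^2 / (1 + A); n1 controls, n2 cases.
    """
    if not (0.0 <= auroc_value <= 1.0):
        raise ValueError("auroc must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    a = auroc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n2 - 1) * (q1 - a * a) + (n1 - 1) * (q2 - a * a)) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def binormal_auroc(mu_controls, sd_controls, mu_cases, sd_cases, direction="low"):
    """Closed-form AUROC for two normal score distributions.

    Under the 'low' orientation this is
    Phi((mu_controls - mu_cases) / sqrt(sd_controls^2 + sd_cases^2)).
    """
    delta = mu_controls - mu_cases
    if direction == "high":
        delta = -delta
    return float(sps.norm.cdf(delta / np.hypot(sd_controls, sd_cases)))


def cutoff_mean_minus_2sd(healthy_mean: float, healthy_sd: float, direction: str = "low") -> float:
    """Healthy-reference cutoff: mean - 2 SD ('low' direction) or + 2 SD."""
    if direction == "low":
        return healthy_mean - 2.0 * healthy_sd
    return healthy_mean + 2.0 * healthy_sd


def _sens_spec(controls, cases, cutoff: float, direction: str) -> tuple[float, float]:
    if direction == "low":
        sens = float((cases <= cutoff).mean())
        spec = float((controls > cutoff).mean())
    else:
        sens = float((cases >= cutoff).mean())
        spec = float((controls < cutoff).mean())
    return sens, spec


def select_cutoff(
    controls,
    cases,
    direction: str = "low",
    rule: str = "mean_minus_2sd",
) -> RocResult:
    """Full ROC summary of one feature at a chosen operating cutoff.

    ``rule='mean_minus_2sd'`` takes the healthy mean -/+ 2 SD (sample SD,
    ddof=1); ``rule='youden'`` maximizes sensitivity + specificity - 1 over
    the empirical thresholds, ties broken toward higher specificity.
    """
    controls = np.asarray(controls, float)
    cases = np.asarray(cases, float)
    a = auroc(controls, cases, direction)
    se = auroc_se(a, len(controls), len(cases))
    degenerate = False
    if rule == "mean_minus_2sd":
        sd = float(controls.std(ddof=1))
        if sd == 0:
            degenerate = True
        cutoff = cutoff_mean_minus_2sd(float(controls.mean()), sd, direction)
    elif rule == "youden":
        thresholds = np.unique(np.concatenate([controls, cases]))
        best, cutoff = -np.inf, float(thresholds[0])
        ordered = thresholds if direction == "high" else thresholds[::-1]
        for t in ordered:  # later (stricter) thresholds win ties -> higher spec
            sens, spec = _sens_spec(controls, cases, float(t), direction)
            if sens + spec - 1.0 >= best:
                best, cutoff = sens + spec - 1.0, float(t)
    else:
        raise ValueError("rule must be 'mean_minus_2sd' or 'youden'")
    sens, spec = _sens_spec(controls, cases, cutoff, direction)
    infinite = spec >= 1.0
    plr = float("inf") if infinite else sens / (1.0 - spec)
    return RocResult(
        auroc=a,
        se=se,
        ci_low=a - 1.96 * se,
        ci_high=a + 1.96 * se,
        cutoff=cutoff,
        cutoff_rule=rule,
        sensitivity=sens,
        specificity=spec,
        plr=plr,
        direction=direction,
        plr_infinite=infinite,
        degenerate_sd=degenerate,
    )


# ---------------------------------------------------------------------------
# Study-level comparison table
# ---------------------------------------------------------------------------


def compare_layers(
    study: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    cutoff_rule: str = "mean_minus_2sd",
    direction: str | dict[str, str] = "low",
    healthy_label: str = GROUP_HEALTHY,
    diseased_label: str = GROUP_DISEASED,
) -> pd.DataFrame:
    """Per-layer, per-feature comparison of a two-group eye-level table.

    For each of the 7 layers x available features: group means +- SD,
    one-way ANOVA significance at ``alpha``, AUROC +- Hanley-McNeil SE with
    95% CI, operating cutoff, sensitivity, specificity and PLR.  Eyes with
    a missing value are excluded from that row only (counts reported).
    ``direction`` may be a single orientation or a per-feature mapping.
    """
    for col in ("eye_id", "group"):
        if col not in study.columns:
            raise ValueError(f"study table lacks required column {col!r}")
    present = set(study["group"].astype(str))
    if not {healthy_label, diseased_label} <= present:
        raise ValueError(
            f"study table must contain groups {healthy_label!r} and {diseased_label!r}"
        )
    rows = []
    for feature in FEATURES:
        if isinstance(direction, dict):
            feat_dir = direction.get(feature, "low")
        else:
            feat_dir = direction
        for layer in LAYERS:
            col = feature_column(feature, layer)
            if col not in study.columns:
                continue
            sub = study[["group", col]].dropna()
            healthy = sub.loc[sub["group"] == healthy_label, col].to_numpy(float)
            diseased = sub.loc[sub["group"] == diseased_label, col].to_numpy(float)
            n_missing = len(study) - len(sub)
            if len(healthy) < 2 or len(diseased) < 2:
                continue
            f_stat, p = anova_oneway(
                GroupData(feature, [healthy, diseased], [healthy_label, diseased_label])
            )
            roc = select_cutoff(healthy, diseased, direction=feat_dir, rule=cutoff_rule)
            rows.append(
                {
                    "layer": layer,
                    "feature": feature,
                    "healthy_mean": healthy.mean(),
                    "healthy_sd": healthy.std(ddof=1),
                    "diseased_mean": diseased.mean(),
                    "diseased_sd": diseased.std(ddof=1),
                    "n_healthy": len(healthy),
                    "n_diseased": len(diseased),
                    "n_excluded": n_missing,
                    "f_stat": f_stat,
                    "p_value": p,
                    "significant": p < alpha,
                    "auroc": roc.auroc,
                    "auroc_se": roc.se,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                    "cutoff": roc.cutoff,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "plr": roc.plr,
                    "direction": feat_dir,
                }
            )
    return pd.DataFrame(rows)
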