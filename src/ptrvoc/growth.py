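"""Growth-response reporting: fold changes and the assumption-routed test tree.

Shoot fresh-weight experiments are summarized two ways:

* **Fold changes** on treatment means, reported as max/min with a direction
  (``increase`` when the treatment mean is at least the control mean,
  ``reduction`` otherwise) and rounded half away from zero to one decimal —
  the convention that turns 24.8 mg vs 3.5 mg into "7.1-fold increase".

* **Hypothesis tests** routed by assumption checks: Shapiro-Wilk normality
  per group, then Levene homoscedasticity.  If both hold, the parametric
  branch runs (Student's t for two groups; one-way ANOVA followed by Tukey's
  HSD for all-pairs designs or Dunnett's test against a control); otherwise
  the non-parametric branch runs (Kruskal-Wallis followed by Dunn's test with
  Bonferroni adjustment).  The component tests are delegated to scipy and
  statsmodels — the routing and reporting is this module's computation —
  except Dunn's post hoc, implemented here (rank-based z statistics with tie
  correction) because no installed library provides it.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChangeEntry",
    "FoldChangeReport",
    "TestResult",
    "fold_change",
    "summarize_experiment",
    "route_branch",
    "decide_and_test",
    "dunn_test",
    "compact_letters",
]


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class FoldChangeEntry:
    """One treatment-vs-control ratio with direction and printed rounding."""

    treatment: str
    control: str
    ratio: float  # max/min of the two means, always > 0
    direction: str  # increase | reduction
    rounded_ratio: float  # 1-decimal, half away from zero

    def __str__(self) -> str:
        return f"{self.rounded_ratio:.1f}-fold {self.direction} ({self.treatment} vs {self.control})"


@dataclass
class FoldChangeReport:
    control: str
    entries: list[FoldChangeEntry]

    def to_dict(self) -> dict:
        return {
            "control": self.control,
            "comparisons": [
                {
                    "treatment": e.treatment,
                    "control": e.control,
                    "ratio": e.ratio,
                    "direction": e.direction,
                    "rounded_ratio": e.rounded_ratio,
                }
                for e in self.entries
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fold_change(
    treat_mean: float, ctrl_mean: float, treatment: str = "treatment", control: str = "control"
) -> FoldChangeEntry:
    """Ratio of the larger to the smaller mean, with direction.

    Equal means report a 1.0-fold increase by convention.  The unrounded
    ratio is retained; rounding (half away from zero, 1 decimal) is the only
    lossy step.
    """
    if treat_mean <= 0 or ctrl_mean <= 0:
        raise ValueError("fold change requires positive means")
    if treat_mean >= ctrl_mean:
        ratio, direction = treat_mean / ctrl_mean, "increase"
    else:
        ratio, direction = ctrl_mean / treat_mean, "reduction"
    return FoldChangeEntry(
        treatment=treatment,
        control=control,
        ratio=float(ratio),
        direction=direction,
        rounded_ratio=_round_half_away(ratio, 1),
    )


def _groups(table: pd.DataFrame) -> dict[str, np.ndarray]:
    required = {"treatment", "fw_mg"}
    if not required <= set(table.columns):
        raise ValueError(f"fresh-weight table needs columns {sorted(required)}")
    return {
        str(label): grp["fw_mg"].to_numpy(dtype=float)
        for label, grp in table.groupby("treatment", sort=True)
    }


def summarize_experiment(table: pd.DataFrame, control_label: str) -> FoldChangeReport:
    """One fold-change entry per non-control treatment, in sorted label order."""
    groups = _groups(table)
    if control_label not in groups:
        raise ValueError(f"control label {control_label!r} not present in table")
    ctrl_mean = float(groups[control_label].mean())
    entries = [
        fold_change(float(vals.mean()), ctrl_mean, treatment=label, control=control_label)
        for label, vals in groups.items()
        if label != control_label
    ]
    return FoldChangeReport(control=control_label, entries=entries)


def route_branch(
    shapiro_ps: Sequence[float], levene_p: float, alpha: float = 0.05
) -> str:
    """Pure routing: parametric iff every assumption check fails to reject.

    Any per-group Shapiro-Wilk p <= alpha, or a Levene p <= alpha, routes to
    the non-parametric branch.
    """
    if all(p > alpha for p in shapiro_ps) and levene_p > alpha:
        return "parametric"
    return "nonparametric"


def dunn_test(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post hoc on ranks with tie correction and Bonferroni adjustment.

    For groups i, j with mean ranks Ri, Rj over the pooled sample of size N:
    z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), where the tie term
    is T = sum(t^3 - t) / (12 (N - 1)) over tie groups.  Two-sided normal
    p-values are Bonferroni-multiplied by the number of pairs.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n = {k: len(groups[k]) for k in labels}
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for k in labels:
        mean_rank[k] = ranks[start : start + n[k]].mean()
        start += n[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "statistic": z, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out


def compact_letters(
    labels: Sequence[str], significant: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb method.

    Starts from one letter covering all groups; every significant pair splits
    the letters containing both members, and absorbed (subset) letters are
    dropped.  Groups sharing a letter are not significantly different.
    """
    sets: list[set[str]] = [set(labels)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            for reduced in (s - {a}, s - {b}):
                if reduced and not any(reduced <= other for other in sets):
                    sets.append(reduced)
    sets = [s for s in sets if not any(s < other for other in sets)]
    sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {label: "" for label in labels}
    for letter, s in zip(alphabet, sets):
        for label in sorted(s):
            out[label] += letter
    return out


@dataclass
class TestResult:
    """Outcome of the assumption-routed comparison of treatment groups."""

    branch: str  # e.g. parametric_ttest, parametric_anova_tukey, nonparametric_kruskal_dunn
    assumptions: dict  # shapiro p per group, levene p
    omnibus: dict  # test name, statistic, p (omnibus or the two-group test)
    comparisons: pd.DataFrame  # per pair: statistic, p (and p_adj where adjusted)
    letters: dict[str, str] | None = None
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "alpha": self.alpha,
            "assumptions": self.assumptions,
            "omnibus": self.omnibus,
            "comparisons": self.comparisons.to_dict(orient="records"),
            "letters": self.letters,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _ttest_rows(
    pairs: Sequence[tuple[str, str]],
    groups: Mapping[str, np.ndarray],
    sided: str,
) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        alternative = "two-sided"
        if sided == "one":
            # one-sided in the direction of the observed difference (the
            # convention used for treatment-vs-control growth claims)
            alternative = "greater" if groups[a].mean() >= groups[b].mean() else "less"
        res = stats.ttest_ind(groups[a], groups[b], alternative=alternative)
        rows.append({"group1": a, "group2": b, "statistic": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


def decide_and_test(
    table: pd.DataFrame,
    design: str = "all_vs_all",
    control: str | None = None,
    alpha: float = 0.05,
    sided: str = "two",
) -> TestResult:
    """Check assumptions, route to the appropriate test, report comparisons.

    ``design`` is ``pairwise`` (exactly two groups), ``all_vs_all`` (omnibus
    plus Tukey/Dunn letters) or ``all_vs_control`` (omnibus plus Dunnett /
    Dunn against ``control``).  Requires >= 3 replicates per group (the
    normality check is undefined below that).
    """
    if design not in ("pairwise", "all_vs_all", "all_vs_control"):
        raise ValueError(f"unknown design {design!r}")
    if design == "all_vs_control":
        if control is None:
            raise ValueError("all_vs_control design requires a control label")
    groups = _groups(table)
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 treatment groups")
    if design == "pairwise" and len(labels) != 2:
        raise ValueError("pairwise design requires exactly 2 groups")
    if control is not None and control not in groups:
        raise ValueError(f"control label {control!r} not present")
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(
                f"group {label!r} has {len(vals)} replicates; need >= 3 "
                "(normality check is undefined below n = 3)"
            )

    shapiro_ps = {k: float(stats.shapiro(v).pvalue) for k, v in groups.items()}
    levene_p = float(stats.levene(*groups.values()).pvalue)
    assumptions = {"shapiro_p": shapiro_ps, "levene_p": levene_p}
    branch = route_branch(list(shapiro_ps.values()), levene_p, alpha)

    letters: dict[str, str] | None = None
    if branch == "parametric":
        if len(labels) == 2:
            comparisons = _ttest_rows([tuple(labels)], groups, sided)
            omnibus = {
                "test": "student_t",
                "statistic": float(comparisons["statistic"].iloc[0]),
                "p": float(comparisons["p"].iloc[0]),
            }
            branch_name = "parametric_ttest"
        else:
            f_res = stats.f_oneway(*groups.values())
            omnibus = {"test": "anova", "statistic": float(f_res.statistic), "p": float(f_res.pvalue)}
            if design == "all_vs_control":
                others = [k for k in labels if k != control]
                res = stats.dunnett(
                    *[groups[k] for k in others],
                    control=groups[control],
                    alternative="greater" if sided == "one" else "two-sided",
                )
                comparisons = pd.DataFrame(
                    {
                        "group1": others,
                        "group2": control,
                        "statistic": np.asarray(res.statistic, dtype=float),
                        "p": np.asarray(res.pvalue, dtype=float),
                    }
                )
                branch_name = "parametric_anova_dunnett"
            else:
                from statsmodels.stats.multicomp import pairwise_tukeyhsd

                tk = pairwise_tukeyhsd(
                    table["fw_mg"].to_numpy(dtype=float),
                    table["treatment"].astype(str).to_numpy(),
                    alpha=alpha,
                )
                comparisons = pd.DataFrame(
                    {
                        "group1": [str(a) for a, _b in itertools.combinations(tk.groupsunique, 2)],
                        "group2": [str(b) for _a, b in itertools.combinations(tk.groupsunique, 2)],
                        "statistic": np.asarray(tk.meandiffs, dtype=float),
                        "p": np.asarray(tk.pvalues, dtype=float),
                    }
                )
                sig = {
                    (row["group1"], row["group2"]): row["p"] <= alpha
                    for _, row in comparisons.iterrows()
                }
                letters = compact_letters(labels, sig)
                branch_name = "parametric_anova_tukey"
    else:
        kw = stats.kruskal(*groups.values())
        omnibus = {"test": "kruskal_wallis", "statistic": float(kw.statistic), "p": float(kw.pvalue)}
        comparisons = dunn_test(groups)
        if design == "all_vs_control":
            mask = (comparisons["group1"] == control) | (comparisons["group2"] == control)
            comparisons = comparisons[mask].reset_index(drop=True)
            # re-adjust for the reduced family of control comparisons
            comparisons["p_adj"] = np.minimum(comparisons["p"] * len(comparisons), 1.0)
        else:
            sig = {
                (row["group1"], row["group2"]): row["p_adj"] <= alpha
                for _, row in comparisons.iterrows()
            }
            letters = compact_letters(labels, sig)
        branch_name = "nonparametric_kruskal_dunn"

    return TestResult(
        branch=branch_name,
        assumptions=assumptions,
        omnibus=omnibus,
        comparisons=comparisons,
        letters=letters,
        alpha=alpha,
    )
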