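"""Bayesian one-way group-mean model for age at first symptoms.

Age at onset (months) is modelled as Normal(mu_g, sigma^2) within each
mutation-position group — a categorical-predictor linear model in the ANOVA
mould, parametrized as cell means so the Normal(0, 100) prior applies to
each group mean symmetrically.  The residual SD gets a half-Normal(50)
prior, weak relative to the observed spread of onset ages (~13 months).
Missing ages are dropped (complete-case analysis).

The decision quantity is the posterior probability that one group's mean
exceeds another's, Pr(mu_g1 - mu_g2 > 0), read off the joint draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import GROUP_ORDER, MutationGroup, PatientRecord
from .mcmc import McmcSettings, OrSummary, PosteriorDraws, gelman_rubin, run_chains, summarize

__all__ = ["GroupMeanSpec", "GroupMeanModel", "GroupMeanResults", "fit_group_means", "contrast_prob"]


@dataclass(frozen=True)
class GroupMeanSpec:
    """Priors for the group-mean model (variances, not SDs)."""

    mean_prior_mu: float = 0.0
    mean_prior_var: float = 100.0
    residual_sd_scale: float = 50.0

    def __post_init__(self) -> None:
        if self.mean_prior_var <= 0 or self.residual_sd_scale <= 0:
            raise ValueError("prior scales must be positive")


class GroupMeanModel:
    """Cell-means Gaussian model of onset age by mutation group."""

    def __init__(
        self,
        ages: Iterable[tuple[MutationGroup, float]],
        spec: GroupMeanSpec | None = None,
        groups: Sequence[MutationGroup] = GROUP_ORDER,
        fixed_sigma: float | None = None,
    ):
        self.spec = spec if spec is not None else GroupMeanSpec()
        self.groups = tuple(groups)
        if fixed_sigma is not None and fixed_sigma <= 0:
            raise ValueError("fixed_sigma must be positive")
        self.fixed_sigma = fixed_sigma
        data: dict[MutationGroup, list[float]] = {g: [] for g in self.groups}
        for g, age in ages:
            g = g if isinstance(g, MutationGroup) else MutationGroup(g)
            if age is None or (isinstance(age, float) and math.isnan(age)):
                continue
            data[g].append(float(age))
        self._values = {g: np.asarray(v) for g, v in data.items()}
        self.n_obs = int(sum(v.size for v in self._values.values()))
        if self.n_obs < 2:
            raise ValueError("need at least two non-missing onset ages")
        self.empty_groups = [g for g in self.groups if self._values[g].size == 0]
        if self.empty_groups:
            warnings.warn(
                "no observations in group(s) "
                + ", ".join(g.value for g in self.empty_groups)
                + "; their posterior means are prior-dominated",
                RuntimeWarning,
                stacklevel=2,
            )

    @classmethod
    def from_records(
        cls, records: Sequence[PatientRecord], spec: GroupMeanSpec | None = None
    ) -> "GroupMeanModel":
        """Complete-case model from patient records (missing ages dropped)."""
        pairs = [
            (rec.mutation_group, rec.onset_age_months)
            for rec in records
            if rec.onset_age_months is not None
        ]
        return cls(pairs, spec)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        group_col: str = "group",
        age_col: str = "onset_age_months",
        spec: GroupMeanSpec | None = None,
    ) -> "GroupMeanModel":
        sub = frame[[group_col, age_col]].dropna()
        return cls(
            [(MutationGroup(g), a) for g, a in zip(sub[group_col], sub[age_col])], spec
        )

    @property
    def param_names(self) -> list[str]:
        names = [f"mu[{g.value}]" for g in self.groups]
        if self.fixed_sigma is None:
            names.append("log_sigma")
        return names

    def make_log_posterior(self):
        # sufficient statistics: per-group n, sample mean, centred SS
        stats = []
        for g in self.groups:
            v = self._values[g]
            if v.size:
                stats.append((float(v.size), float(v.mean()), float(((v - v.mean()) ** 2).sum())))
            else:
                stats.append((0.0, 0.0, 0.0))
        n_groups = len(self.groups)
        mu0 = self.spec.mean_prior_mu
        var0 = self.spec.mean_prior_var
        sd_scale2 = self.spec.residual_sd_scale ** 2
        exp, log = math.exp, math.log
        inf = math.inf
        fixed = self.fixed_sigma

        if fixed is not None:
            ls_fixed = log(fixed)
            s2_fixed = fixed * fixed

            def log_posterior_fixed(v) -> float:
                lp = 0.0
                for g in range(n_groups):
                    mu = v[g]
                    r = mu - mu0
                    lp -= r * r / (2.0 * var0)
                    n, ybar, ss = stats[g]
                    if n > 0.0:
                        d = ybar - mu
                        lp -= n * ls_fixed + (ss + n * d * d) / (2.0 * s2_fixed)
                return lp

            return log_posterior_fixed

        def log_posterior(v) -> float:
            ls = v[n_groups]
            if ls > 100.0 or ls < -100.0:
                return -inf
            sigma = exp(ls)
            s2 = sigma * sigma
            # half-normal prior on sigma, plus the log|dsigma/dls| Jacobian
            lp = -s2 / (2.0 * sd_scale2) + ls
            for g in range(n_groups):
                mu = v[g]
                r = mu - mu0
                lp -= r * r / (2.0 * var0)
                n, ybar, ss = stats[g]
                if n > 0.0:
                    d = ybar - mu
                    lp -= n * ls + (ss + n * d * d) / (2.0 * s2)
            return lp

        return log_posterior

    def initial_point(self) -> np.ndarray:
        mus = [
            float(self._values[g].mean()) if self._values[g].size else 0.0
            for g in self.groups
        ]
        if self.fixed_sigma is not None:
            return np.array(mus)
        pooled = np.concatenate([v for v in self._values.values() if v.size])
        sd = float(pooled.std()) or 1.0
        return np.array(mus + [math.log(sd)])

    def fit(self, settings: McmcSettings | None = None) -> "GroupMeanResults":
        settings = settings if settings is not None else McmcSettings()
        scales = [2.0] * len(self.groups)
        if self.fixed_sigma is None:
            scales.append(0.2)
        draws = run_chains(
            self.make_log_posterior(),
            self.initial_point(),
            settings,
            param_names=self.param_names,
            initial_scales=scales,
        )
        return GroupMeanResults(self, draws)


class GroupMeanResults:
    """Posterior group-mean summaries and pairwise contrast probabilities."""

    def __init__(self, model: GroupMeanModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self.rhat = gelman_rubin(draws) if draws.n_chains >= 2 else {}

    def group_summary(self, group: MutationGroup) -> OrSummary:
        group = group if isinstance(group, MutationGroup) else MutationGroup(group)
        if group not in self.model.groups:
            raise KeyError(f"unknown group {group}")
        return summarize(self.draws, f"mu[{group.value}]")

    def contrast_prob(self, g1: MutationGroup, g2: MutationGroup) -> float:
        """Pr(mu_g1 - mu_g2 > 0) over the joint posterior draws."""
        g1 = g1 if isinstance(g1, MutationGroup) else MutationGroup(g1)
        g2 = g2 if isinstance(g2, MutationGroup) else MutationGroup(g2)
        for g in (g1, g2):
            if g not in self.model.groups:
                raise KeyError(f"unknown group {g}")
        if g1 == g2:
            warnings.warn(
                "degenerate contrast: identical groups, difference is identically 0",
                RuntimeWarning,
                stacklevel=2,
            )
            return 0.0
        diff = self.draws.stacked(f"mu[{g1.value}]") - self.draws.stacked(f"mu[{g2.value}]")
        return float(np.mean(diff > 0))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.model.groups:
            s = self.group_summary(g)
            rows.append(
                {
                    "group": g.value,
                    "n": int(self.model._values[g].size),
                    "mean_months": s.point,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                }
            )
        return pd.DataFrame(rows).set_index("group")

    def contrast_frame(self) -> pd.DataFrame:
        pairs = [
            (MutationGroup.TWO_DOWN, MutationGroup.TWO_UP),
            (MutationGroup.TWO_DOWN, MutationGroup.ONE_ONE),
            (MutationGroup.ONE_ONE, MutationGroup.TWO_UP),
        ]
        rows = [
            {
                "contrast": f"{a.value} - {b.value}",
                "pr_diff_gt_0_pct": 100 * self.contrast_prob(a, b),
            }
            for a, b in pairs
            if a in self.model.groups and b in self.model.groups
        ]
        return pd.DataFrame(rows).set_index("contrast")

    def summary(self) -> str:
        lines = ["Bayesian group means of age at first symptoms (months)"]
        for g, row in self.summary_frame().iterrows():
            lines.append(
                f"  {g:5s} n={int(row.n):3d}  {row.mean_months:5.1f} "
                f"[{row.ci_low:.1f}-{row.ci_high:.1f}]"
            )
        for label, row in self.contrast_frame().iterrows():
            lines.append(f"  Pr({label} > 0) = {row.pr_diff_gt_0_pct:.1f}%")
        return "\n".join(lines)


def fit_group_means(
    ages: Iterable[tuple[MutationGroup, float]],
    spec: GroupMeanSpec | None = None,
    settings: McmcSettings | None = None,
) -> GroupMeanResults:
    """Functional alias: fit the group-mean model on (group, age) pairs."""
    return GroupMeanModel(ages, spec).fit(settings)


def contrast_prob(fit: GroupMeanResults, g1, g2) -> float:
    return fit.contrast_prob(g1, g2)
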