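"""Bayesian Poisson log-linear analysis of presentation-mode preferences.

Each participant voted for one of three presentation modes per example
conversation; the vote counts per (group, conversation, mode) cell are
modeled as independent Poisson with a log link and a full-factorial design
of either order two (Counts ~ Mode x Group, counts summed over
conversations) or order three (Counts ~ Mode x Group x Conversation,
saturated).  Coefficients use treatment coding with AH / audio /
conversation A as reference levels and wide Normal(0, 5^2) priors on the
log scale; posteriors are sampled with the same NUTS engine as the LBA
model, 4 chains x (2000 warmup + 2000 retained) by default.

Counts are modeled as independent Poisson even though each (group,
conversation) cell's votes sum to the number of participants; a multinomial
alternative is available via ``multinomial_loglik`` for comparison but is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lba import MODES
from .nuts import SamplerConfig, sample_chain
from .synthetic import CONVERSATIONS, GROUPS

COEF_PRIOR_SD = 5.0


def validate_counts(counts: pd.DataFrame, require_total=None) -> pd.DataFrame:
    need = {"group", "conversation", "mode", "count"}
    if not need.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(need)}")
    c = counts["count"]
    if not np.allclose(c, np.round(c)) or (c < 0).any():
        raise ValueError("counts must be non-negative integers")
    if require_total is not None:
        sums = counts.groupby(["group", "conversation"])["count"].sum()
        bad = sums[sums != require_total]
        if len(bad):
            raise ValueError(f"cells with wrong vote totals: {bad.to_dict()}")
    return counts


def _design(cells: pd.DataFrame, order: str):
    """Treatment-coded full-factorial design matrix and coefficient names."""
    modes = [m for m in MODES if m in set(cells["mode"])]
    groups = [g for g in GROUPS if g in set(cells["group"])] or \
        sorted(set(cells["group"]))
    mode_d = {m: i for i, m in enumerate(modes)}
    grp_d = {g: i for i, g in enumerate(groups)}
    cols = [np.ones(len(cells))]
    names = ["intercept"]
    mode_cols, grp_cols = {}, {}
    for m in modes[1:]:
        mode_cols[m] = (cells["mode"] == m).to_numpy(float)
        cols.append(mode_cols[m]); names.append(f"mode[{m}]")
    for g in groups[1:]:
        grp_cols[g] = (cells["group"] == g).to_numpy(float)
        cols.append(grp_cols[g]); names.append(f"group[{g}]")
    for m in modes[1:]:
        for g in groups[1:]:
            cols.append(mode_cols[m] * grp_cols[g])
            names.append(f"mode[{m}]:group[{g}]")
    if order == "three_way":
        convs = [c for c in CONVERSATIONS if c in set(cells["conversation"])] or \
            sorted(set(cells["conversation"]))
        conv_cols = {}
        for c in convs[1:]:
            conv_cols[c] = (cells["conversation"] == c).to_numpy(float)
            cols.append(conv_cols[c]); names.append(f"conv[{c}]")
        for m in modes[1:]:
            for c in convs[1:]:
                cols.append(mode_cols[m] * conv_cols[c])
                names.append(f"mode[{m}]:conv[{c}]")
        for g in groups[1:]:
            for c in convs[1:]:
                cols.append(grp_cols[g] * conv_cols[c])
                names.append(f"group[{g}]:conv[{c}]")
        for m in modes[1:]:
            for g in groups[1:]:
                for c in convs[1:]:
                    cols.append(mode_cols[m] * grp_cols[g] * conv_cols[c])
                    names.append(f"mode[{m}]:group[{g}]:conv[{c}]")
    return np.column_stack(cols), names


@dataclass
class GlmPosterior:
    """Coefficient draws and per-cell predictions of a preference model."""

    coef_draws: np.ndarray  # (chains, iterations, p)
    coef_names: list
    X: np.ndarray
    cells: pd.DataFrame  # cell labels aligned with X rows; includes count
    formula_order: str
    prior_sd: float

    @property
    def n_draws(self) -> int:
        return self.coef_draws.shape[0] * self.coef_draws.shape[1]

    def flat_coefs(self) -> np.ndarray:
        return self.coef_draws.reshape(-1, self.coef_draws.shape[-1])

    def cell_mean_draws(self) -> np.ndarray:
        """Predicted Poisson means per cell, (n_draws, n_cells)."""
        return np.exp(self.flat_coefs() @ self.X.T)

    def coefficient_summary(self, prob: float = 0.95) -> pd.DataFrame:
        flat = self.flat_coefs()
        lo, hi = np.quantile(flat, [(1 - prob) / 2, 1 - (1 - prob) / 2], axis=0)
        return pd.DataFrame({
            "coefficient": self.coef_names,
            "median": np.median(flat, axis=0),
            "cri_low": lo, "cri_high": hi,
        })


def poisson_logp_grad_factory(X: np.ndarray, y: np.ndarray, prior_sd: float):
    XT = X.T.copy()

    def logp_and_grad(beta):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -500, 500))
        lp = float(y @ eta - mu.sum()) - 0.5 * float(beta @ beta) / prior_sd**2
        g = XT @ (y - mu) - beta / prior_sd**2
        return lp, g

    return logp_and_grad


def fit_poisson_model(counts: pd.DataFrame, formula_order: str = "three_way",
                      config: SamplerConfig | None = None,
                      prior_sd: float = COEF_PRIOR_SD) -> GlmPosterior:
    """Fit the Poisson preference model of the given factorial order.

    ``two_way`` sums counts over conversations first; ``three_way`` keeps
    the full (group, conversation, mode) table and is saturated.  Missing
    factorial cells raise (zero counts are valid and must be present as
    explicit rows).
    """
    if formula_order not in ("two_way", "three_way"):
        raise ValueError("formula_order must be 'two_way' or 'three_way'")
    counts = validate_counts(counts)
    if formula_order == "two_way":
        cells = counts.groupby(["group", "mode"], as_index=False)["count"].sum()
        cells["conversation"] = "all"
        expected = {(g, m) for g in set(counts["group"]) for m in set(counts["mode"])}
        have = set(zip(cells["group"], cells["mode"]))
    else:
        cells = counts.copy()
        expected = {(g, c, m) for g in set(counts["group"])
                    for c in set(counts["conversation"]) for m in set(counts["mode"])}
        have = set(zip(cells["group"], cells["conversation"], cells["mode"]))
    if have != expected:
        raise ValueError("incomplete factorial table: missing cells "
                         f"{sorted(expected - have)}")
    cells = cells.reset_index(drop=True)
    X, names = _design(cells, formula_order)
    y = cells["count"].to_numpy(dtype=float)
    config = config or SamplerConfig(chains=4, warmup_iterations=2000,
                                     sampling_iterations=2000)
    lg = poisson_logp_grad_factory(X, y, prior_sd)
    all_draws = []
    for c in range(config.chains):
        rng = np.random.default_rng([int(config.seed) % 2**31, 7, c])
        x0 = rng.uniform(-0.5, 0.5, X.shape[1])
        draws, _, _ = sample_chain(lg, x0, config, rng)
        all_draws.append(draws)
    return GlmPosterior(
        coef_draws=np.stack(all_draws), coef_names=names, X=X,
        cells=cells, formula_order=formula_order, prior_sd=prior_sd,
    )


def conditional_effects(posterior: GlmPosterior, prob: float = 0.95) -> pd.DataFrame:
    """Per-cell predicted mean, median and central credible interval."""
    mu = posterior.cell_mean_draws()
    lo, hi = np.quantile(mu, [(1 - prob) / 2, 1 - (1 - prob) / 2], axis=0)
    out = posterior.cells.copy()
    out["predicted_mean"] = mu.mean(axis=0)
    out["predicted_median"] = np.median(mu, axis=0)
    out["cri_low"] = lo
    out["cri_high"] = hi
    return out


def percentage_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each (group, conversation)'s voters choosing each mode."""
    counts = validate_counts(counts)
    totals = counts.groupby(["group", "conversation"])["count"].transform("sum")
    if (totals == 0).any():
        bad = counts.loc[totals == 0, ["group", "conversation"]].drop_duplicates()
        raise ZeroDivisionError(
            f"zero voters in cells {list(bad.itertuples(index=False, name=None))}"
        )
    out = counts.copy()
    out["percent"] = 100.0 * out["count"] / totals
    return out


def multinomial_loglik(counts: pd.DataFrame, probs: dict) -> float:
    """Log likelihood under the fixed-total multinomial alternative."""
    from scipy.stats import multinomial

    total = 0.0
    for (g, c), sub in counts.groupby(["group", "conversation"]):
        sub = sub.set_index("mode").loc[list(MODES), "count"].to_numpy()
        total += multinomial.logpmf(sub, n=sub.sum(), p=np.asarray(probs[(g, c)]))
    return float(total)
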