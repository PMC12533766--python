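"""Listening efficiency, effect summaries and descriptive surfaces.

Listening efficiency condenses the four drift rates of a condition into a
single number: the drift toward the correct keyword minus the mean of the
three error drifts.  A random guesser accumulates evidence equally fast
toward every option and scores zero; better listeners score higher.  For
reporting, group-level efficiency is normalized so that the acoustic-hearing
group's mean across the three presentation modes equals one — within each
posterior draw, so the normalized posterior fully propagates uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lba import MODES, RESPONSES


def listening_efficiency(v_correct, v_semantic, v_phonetic, v_neither):
    """Correct-response drift minus the mean of the three error drifts.

    Accepts scalars or arrays (broadcast); adding a common constant to all
    four drifts leaves the value unchanged.
    """
    return np.asarray(v_correct) - (
        np.asarray(v_semantic) + np.asarray(v_phonetic) + np.asarray(v_neither)
    ) / 3.0


@dataclass
class EfficiencyPosterior:
    """Per-draw listening efficiency per (group, mode), raw and normalized."""

    raw: dict  # (group, mode) -> 1-D array of draws
    normalized: dict  # same keys
    reference_group: str
    reference_mean: np.ndarray  # per-draw normalization constant
    n_nonpositive_reference: int = 0

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        for (g, m), vals in self.normalized.items():
            lo, hi = hdi(vals, prob)
            rows.append({
                "group": g, "mode": m,
                "median_raw": float(np.median(self.raw[(g, m)])),
                "median_normalized": float(np.median(vals)),
                "hdi_low": lo, "hdi_high": hi,
            })
        return pd.DataFrame(rows)


def efficiency_from_drift_draws(drift_draws: dict) -> dict:
    """Raw per-draw efficiency from drift draws keyed ``v_<resp>_<mode>[<group>]``.

    ``drift_draws`` is the group-level draw dict of a fitted model; any
    array shape is accepted and flattened.  Returns ``(group, mode) ->
    draws``.
    """
    groups = sorted({k.split("[")[1].rstrip("]")
                     for k in drift_draws if k.startswith("v_correct_")})
    out = {}
    for g in groups:
        for m in MODES:
            vals = [np.asarray(drift_draws[f"v_{r}_{m}[{g}]"]).ravel()
                    for r in RESPONSES]
            out[(g, m)] = listening_efficiency(*vals)
    return out


def normalize_to_reference(raw: dict, reference_group: str = "AH") -> EfficiencyPosterior:
    """Divide every cell, per draw, by the reference group's mode average.

    Scale-invariant: multiplying all raw values by any c > 0 leaves the
    normalized posterior unchanged, and the normalized reference group
    averages exactly one across modes in every draw.  Draws in which the
    reference mean is non-positive cannot be normalized meaningfully; they
    are counted and reported, not silently dropped.
    """
    ref_keys = [(reference_group, m) for m in MODES]
    for k in ref_keys:
        if k not in raw:
            raise ValueError(
                f"reference group {reference_group!r} missing mode {k[1]!r}"
            )
    ref_mean = np.mean([raw[k] for k in ref_keys], axis=0)
    n_bad = int(np.sum(ref_mean <= 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = {k: np.asarray(v) / ref_mean for k, v in raw.items()}
    return EfficiencyPosterior(
        raw={k: np.asarray(v) for k, v in raw.items()},
        normalized=normalized,
        reference_group=reference_group,
        reference_mean=ref_mean,
        n_nonpositive_reference=n_bad,
    )


def hdi(draws: np.ndarray, prob: float = 0.95) -> tuple:
    """Narrowest interval containing ``prob`` of the draws (unimodal HDI).

    Slides a window of ``ceil(prob * n)`` over the sorted draws and returns
    the shortest one.
    """
    x = np.sort(np.asarray(draws).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("no draws")
    m = int(np.ceil(prob * n))
    m = min(max(m, 1), n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class EffectSummary:
    label: str
    median: float
    hdi_low: float
    hdi_high: float
    credibility: float

    def to_dict(self) -> dict:
        return {"label": self.label, "median": self.median,
                "hdi_low": self.hdi_low, "hdi_high": self.hdi_high,
                "credibility": self.credibility}


def effect_credibility(draws_a, draws_b, label: str = "a - b",
                       prob: float = 0.95) -> EffectSummary:
    """Paired posterior contrast a - b with HDI and credibility.

    Credibility is the posterior probability that the difference is
    positive; exact ties count one half, so comparing a chain with itself
    yields exactly 0.5.  Draws must be paired (same chain/iteration order).
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("draw vectors must have equal length (paired draws)")
    d = a - b
    cred = float(np.mean(d > 0) + 0.5 * np.mean(d == 0))
    lo, hi = hdi(d, prob)
    return EffectSummary(label=label, median=float(np.median(d)),
                         hdi_low=lo, hdi_high=hi, credibility=cred)


def response_caution(A_draws, b_draws, definition: str = "distance"):
    """Derived response caution per draw.

    ``"distance"`` (default): b - A/2, the gap between the mean start point
    and the threshold; ``"ratio"``: b / A is offered as an alternative.
    Positive whenever b > A under the default definition.
    """
    A = np.asarray(A_draws, dtype=float)
    b = np.asarray(b_draws, dtype=float)
    if definition == "distance":
        return b - A / 2.0
    if definition == "ratio":
        return b / A
    raise ValueError("definition must be 'distance' or 'ratio'")


def observed_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Accuracy, RT quantiles and error-type counts per group x mode.

    Cells absent from the data are reported with NaN statistics rather than
    raising.  Accuracy is in percent.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    groups = list(pd.unique(table["group"]))
    rows = []
    for g in groups:
        for m in MODES:
            cell = table[(table["group"] == g) & (table["mode"] == m)]
            if len(cell) == 0:
                rows.append({"group": g, "mode": m, "n": 0,
                             "accuracy_pct": np.nan, "rt_q10": np.nan,
                             "rt_q50": np.nan, "rt_q90": np.nan,
                             **{f"n_{r}": 0 for r in RESPONSES}})
                continue
            correct = cell["response"].eq("correct")
            q10, q50, q90 = np.quantile(cell["rt_seconds"], [0.1, 0.5, 0.9])
            counts = cell["response"].value_counts()
            rows.append({
                "group": g, "mode": m, "n": len(cell),
                "accuracy_pct": 100.0 * float(correct.mean()),
                "rt_q10": float(q10), "rt_q50": float(q50), "rt_q90": float(q90),
                **{f"n_{r}": int(counts.get(r, 0)) for r in RESPONSES},
            })
    return pd.DataFrame(rows)


def ppc_accuracy_gap(observed: pd.DataFrame, replicated: list) -> pd.DataFrame:
    """|replicated - observed| accuracy per group x mode, percentage points.

    Replicated tables must share the observed design (same cell sizes);
    replicate accuracies are averaged before differencing, following the
    usual posterior-predictive accuracy check.
    """
    if len(replicated) == 0:
        raise ValueError("need at least one replicated dataset")
    obs = observed_summaries(observed).set_index(["group", "mode"])
    reps = [observed_summaries(r).set_index(["group", "mode"]) for r in replicated]
    for r in reps:
        if not (r["n"] == obs["n"]).all():
            raise ValueError("replicated design does not match observed design")
    rep_acc = np.mean([r["accuracy_pct"].to_numpy() for r in reps], axis=0)
    out = obs.reset_index()[["group", "mode", "n", "accuracy_pct"]].copy()
    out = out.rename(columns={"accuracy_pct": "observed_pct"})
    out["replicated_pct"] = rep_acc
    out["gap_pct_points"] = np.abs(out["replicated_pct"] - out["observed_pct"])
    return out


def ppc_rt_quantile_coverage(observed: pd.DataFrame, replicated: list,
                             quantiles=(0.1, 0.5, 0.9)) -> float:
    """Fraction of (group, mode, quantile) cells whose observed RT quantile
    lies within the range of the replicated quantiles."""
    obs = observed_summaries(observed).set_index(["group", "mode"])
    reps = [observed_summaries(r).set_index(["group", "mode"]) for r in replicated]
    cols = {0.1: "rt_q10", 0.5: "rt_q50", 0.9: "rt_q90"}
    inside = 0
    total = 0
    for q in quantiles:
        col = cols[q]
        rep_vals = np.stack([r[col].to_numpy() for r in reps])
        o = obs[col].to_numpy()
        ok = np.isfinite(o)
        inside += int(np.sum((o[ok] >= rep_vals[:, ok].min(axis=0))
                             & (o[ok] <= rep_vals[:, ok].max(axis=0))))
        total += int(np.sum(ok))
    return inside / total if total else float("nan")
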