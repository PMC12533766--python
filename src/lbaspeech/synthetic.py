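"""Synthetic cohort generation from the study's generative model.

The emulated design is a two-group (cochlear-implant users, CI, versus an
acoustic-hearing comparison group, AH), three-mode (audio, video, captions)
closed-set sentence recognition task: each participant completes 60 trials
(20 per mode, seeded random order), each trial requiring three sequential
keyword selections among four options (the keyword plus semantic, phonetic
and unrelated foils).  Responses and response times come from the LBA race
with a contaminant lapse mixture and within-sentence serial dependency of
the correct-response drift.  A companion generator produces the
presentation-mode preference votes for the three example conversations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lba
from .lba import MODES, RESPONSES, IndividualParams, N_PARAMS, PARAM_NAMES
from .transforms import constrain_matrix

GROUPS = ("AH", "CI")
CONVERSATIONS = ("A", "B", "C")


class InvalidDesignError(ValueError):
    """A design specification violates its invariants."""


@dataclass
class DesignSpec:
    """Shape of the behavioral experiment.

    Defaults reproduce the study design: 50 participants per group, three
    presentation modes with 20 trials each (60 trials per participant), and
    three keywords per trial — 18,000 keyword-selection events in total.
    """

    n_per_group: int = 50
    groups: tuple = GROUPS
    modes: tuple = MODES
    trials_per_mode: int = 20
    keywords_per_trial: int = 3
    conversations: tuple = CONVERSATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0 or self.trials_per_mode <= 0 \
                or self.keywords_per_trial <= 0:
            raise InvalidDesignError("counts must be positive")
        if len(self.groups) == 0 or len(self.modes) == 0:
            raise InvalidDesignError("need at least one group and one mode")

    @property
    def trials_per_participant(self) -> int:
        return self.trials_per_mode * len(self.modes)

    @property
    def n_participants(self) -> int:
        return self.n_per_group * len(self.groups)

    @property
    def n_rows(self) -> int:
        return self.n_participants * self.trials_per_participant * self.keywords_per_trial


@dataclass
class TruePopulation:
    """Generating population for synthetic cohorts.

    ``group_means`` holds one 17-vector per group on the *unconstrained*
    scale (drifts and boosts are identity-mapped; A, b - A and t0 - 0.150
    are log-mapped), so individuals drawn from the multivariate normal always
    satisfy the LBA constraints after transformation.
    """

    group_means: dict
    scales: np.ndarray
    correlation: np.ndarray
    contaminant_prop: float = 0.02
    t_max: float = 10.0

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.scales.shape != (N_PARAMS,):
            raise ValueError("scales must be a 17-vector")
        if self.correlation.shape != (N_PARAMS, N_PARAMS):
            raise ValueError("correlation must be 17x17")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation must have unit diagonal")
        if np.any(self.scales < 0):
            raise ValueError("scales must be non-negative")
        if not 0.0 <= self.contaminant_prop <= 1.0:
            raise ValueError("contaminant_prop must lie in [0, 1]")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        self.group_means = {
            g: np.asarray(m, dtype=float) for g, m in self.group_means.items()
        }
        for g, m in self.group_means.items():
            if m.shape != (N_PARAMS,):
                raise ValueError(f"group mean for {g!r} must be a 17-vector")

    def to_dict(self) -> dict:
        return {
            "group_means": {g: m.tolist() for g, m in self.group_means.items()},
            "scales": self.scales.tolist(),
            "correlation": self.correlation.tolist(),
            "contaminant_prop": self.contaminant_prop,
            "t_max": self.t_max,
            "param_names": list(PARAM_NAMES),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruePopulation":
        return cls(
            group_means={g: np.asarray(m) for g, m in d["group_means"].items()},
            scales=np.asarray(d["scales"]),
            correlation=np.asarray(d["correlation"]),
            contaminant_prop=float(d["contaminant_prop"]),
            t_max=float(d["t_max"]),
        )


def default_population(ci_correct_drifts=(1.8, 2.1, 2.4)) -> TruePopulation:
    """Generative defaults that qualitatively mimic the study's groups.

    AH listeners accumulate evidence toward the correct keyword equally fast
    in all modes (near-ceiling accuracy); CI listeners are slower and graded
    across modes (audio < video < captions).  Error drifts are uniform at
    0 — with the unit between-trial drift SD this puts cohort-level accuracy
    near 95% for AH and near 80% for CI-audio, the qualitative pattern of
    the study — serial-dependency boosts are positive for both groups and
    somewhat larger for AH, and the decision architecture (A = 0.8, b = 1.3,
    t0 = 0.3 s) is shared.  Between-subject SDs are 0.3 for drifts, 0.15 for
    boosts and 0.15 on the log scale for A, b - A and t0 - 0.150; the
    generating correlation is the identity.
    """
    def means(v_correct, boosts):
        mu = np.empty(N_PARAMS)
        for m in range(len(MODES)):
            mu[4 * m] = v_correct[m]
            mu[4 * m + 1: 4 * m + 4] = 0.0
        mu[lba.IDX_BOOST2], mu[lba.IDX_BOOST3] = boosts
        mu[lba.IDX_A] = np.log(0.8)
        mu[lba.IDX_B] = np.log(1.3 - 0.8)
        mu[lba.IDX_T0] = np.log(0.3 - lba.T0_FLOOR)
        return mu

    scales = np.concatenate([np.full(12, 0.3), [0.15, 0.15], np.full(3, 0.15)])
    return TruePopulation(
        group_means={
            "AH": means((3.0, 3.0, 3.0), (0.5, 0.7)),
            "CI": means(tuple(ci_correct_drifts), (0.4, 0.55)),
        },
        scales=scales,
        correlation=np.eye(N_PARAMS),
        contaminant_prop=0.02,
        t_max=10.0,
    )


def build_design(spec: DesignSpec) -> pd.DataFrame:
    """Expand a design spec into one row per keyword slot.

    Columns: participant_id, group, trial_id, mode, keyword_index.  Mode
    allocation is exactly balanced within participant and the trial order is
    a seeded permutation, so identical seeds give identical designs.
    """
    rng = np.random.default_rng(spec.seed)
    n_modes = len(spec.modes)
    trials = spec.trials_per_participant
    rows_pid, rows_grp, rows_tid, rows_mode, rows_kw = [], [], [], [], []
    pid = 0
    for g in spec.groups:
        for _ in range(spec.n_per_group):
            mode_seq = np.repeat(np.arange(n_modes), spec.trials_per_mode)
            rng.shuffle(mode_seq)
            for t in range(trials):
                for kw in range(1, spec.keywords_per_trial + 1):
                    rows_pid.append(pid)
                    rows_grp.append(g)
                    rows_tid.append(t + 1)
                    rows_mode.append(spec.modes[mode_seq[t]])
                    rows_kw.append(kw)
            pid += 1
    return pd.DataFrame(
        {
            "participant_id": np.asarray(rows_pid, dtype=np.int64),
            "group": rows_grp,
            "trial_id": np.asarray(rows_tid, dtype=np.int64),
            "mode": rows_mode,
            "keyword_index": np.asarray(rows_kw, dtype=np.int64),
        }
    )


def draw_individual_parameters(pop: TruePopulation, group: str, n: int,
                               seed=None) -> list:
    """Draw ``n`` participants' parameters from the group-level MVN.

    The unconstrained 17-vectors are multivariate normal with covariance
    ``diag(scales) @ correlation @ diag(scales)``; the returned
    :class:`~lbaspeech.lba.IndividualParams` are on the constrained scale.
    """
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(pop.correlation)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "correlation matrix is not positive-definite"
        ) from e
    z = rng.standard_normal((n, N_PARAMS))
    unc = pop.group_means[group] + (z @ L.T) * pop.scales
    con = constrain_matrix(unc)
    return [IndividualParams.from_vector(row) for row in con]


def simulate_trial(params: IndividualParams, mode: str, keyword_index: int,
                   kw1_correct: bool, kw2_correct: bool, lam: float,
                   t_max: float, rng) -> tuple:
    """Simulate one keyword selection; returns (response_index, rt_seconds).

    With probability ``lam`` the event is a lapse: uniform response, RT
    uniform on (0, t_max).  Otherwise each accumulator gets a uniform start
    and a Normal(v_eff, 1) drift, and the winner is the accumulator with
    the smallest finishing time ``(b - start) / drift`` among those with
    positive drift.  Race RTs are unbounded, exactly as the likelihood
    assumes; only the lapse component uses ``t_max``.

    A stalled race (every drift sample negative, ~0.4% of draws at the
    default values) resolves as a lapse whenever a lapse process exists
    (``lam > 0``): the participant eventually guesses.  Statistically this
    parks the race's defective mass in the contaminant component, where it
    only raises the recovered lapse proportion by that fraction.  The
    alternative — redrawing drifts until one is positive — multiplies the
    data density by a parameter-dependent factor ``1/(1 - P(stall))`` that
    the likelihood does not contain; the discrepancy is amplified along
    the model's soft drift/threshold trade-off ridge into a measurable
    upward drift tilt.  With ``lam = 0`` there is no lapse process and the
    race is redrawn instead.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if rng.random() < lam:
        return int(rng.integers(0, len(RESPONSES))), float(rng.uniform(0.0, t_max))
    ctx = lba.TrialContext(mode=mode, keyword_index=keyword_index,
                           kw1_correct=kw1_correct, kw2_correct=kw2_correct)
    drifts = lba.effective_drifts(params, ctx)
    while True:
        out = _race_attempt(params, drifts, rng)
        if out is not None:
            return out
        if lam > 0:
            return int(rng.integers(0, len(RESPONSES))), \
                float(rng.uniform(0.0, t_max))


def _race_attempt(params: IndividualParams, drifts: np.ndarray, rng):
    """One unbounded race draw; ``None`` if every drift sample is negative."""
    rates = rng.normal(drifts, params.s)
    if not np.any(rates > 0):
        return None
    starts = rng.uniform(0.0, params.A, len(RESPONSES))
    with np.errstate(divide="ignore"):
        times = np.where(rates > 0, (params.b - starts) / rates, np.inf)
    winner = int(np.argmin(times))
    return winner, float(params.t0 + times[winner])


def simulate_dataset(spec: DesignSpec, pop: TruePopulation, seed=None,
                     return_truth: bool = False):
    """Simulate a full trial table (and optionally the generating params).

    Walks the seeded design trial by trial, applying the serial-dependency
    boosts according to the simulated correctness of earlier keywords in the
    same sentence, and records the prior-correctness context flags alongside
    each row.  Identical (spec, pop, seed) give identical tables.
    """
    rng = np.random.default_rng(seed)
    design = build_design(spec)
    params_by_pid = {}
    for g in spec.groups:
        drawn = draw_individual_parameters(
            pop, g, spec.n_per_group, rng.integers(0, 2**31 - 1)
        )
        offset = spec.groups.index(g) * spec.n_per_group
        for k, p in enumerate(drawn):
            params_by_pid[offset + k] = p
    table = simulate_from_params(design, params_by_pid,
                                 pop.contaminant_prop, pop.t_max, rng)
    if return_truth:
        return table, params_by_pid
    return table


def simulate_from_params(design: pd.DataFrame, params_by_pid: dict,
                         lam: float, t_max: float, rng) -> pd.DataFrame:
    """Replay a design table with fixed individual parameters.

    Used both by :func:`simulate_dataset` and for posterior predictive
    replication, where the design (and participants) of an observed dataset
    are kept and only responses/RTs are regenerated.

    Dataset-level contaminant bound: race RTs are unbounded (as the
    likelihood assumes), so the slow race tail occasionally exceeds any
    fixed constant.  Because model fitting sets the contaminant bound to
    the *maximum observed RT*, lapse RTs here are drawn uniform on
    ``(0, ceiling)`` with ``ceiling = max(t_max, slowest race RT)`` — the
    generated data then carry exactly the contaminant density the fitted
    model reconstructs from them.  With a fixed lapse bound instead, one
    slow race outlier would dilute the reconstructed contaminant density
    and visibly bias the recovered lapse proportion and drifts.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    design = design.reset_index(drop=True)
    responses = np.empty(len(design), dtype=object)
    rts = np.empty(len(design))
    kw1_flags = np.zeros(len(design), dtype=bool)
    kw2_flags = np.zeros(len(design), dtype=bool)
    is_lapse = np.zeros(len(design), dtype=bool)

    for (pid, _tid), trial in design.groupby(["participant_id", "trial_id"], sort=False):
        params = params_by_pid[pid]
        kw1_ok = kw2_ok = False
        trial = trial.sort_values("keyword_index")
        for idx, row in trial.iterrows():
            kw = int(row["keyword_index"])
            lapse = rng.random() < lam
            if not lapse:
                ctx = lba.TrialContext(mode=row["mode"], keyword_index=kw,
                                       kw1_correct=kw1_ok, kw2_correct=kw2_ok)
                drifts = lba.effective_drifts(params, ctx)
                while True:
                    out = _race_attempt(params, drifts, rng)
                    if out is not None:
                        resp, rts[idx] = out
                        break
                    if lam > 0:  # stalled race resolves as a guess
                        lapse = True
                        break
            if lapse:
                resp = int(rng.integers(0, len(RESPONSES)))
                rts[idx] = rng.random()  # fraction of the ceiling, set below
                is_lapse[idx] = True
            kw1_flags[idx] = kw1_ok if kw >= 2 else False
            kw2_flags[idx] = kw2_ok if kw >= 3 else False
            responses[idx] = RESPONSES[resp]
            correct = resp == 0
            if kw == 1:
                kw1_ok = correct
            elif kw == 2:
                kw2_ok = correct

    if is_lapse.any():
        race_rts = rts[~is_lapse]
        ceiling = max(float(t_max), float(race_rts.max())) if len(race_rts) \
            else float(t_max)
        rts[is_lapse] = np.maximum(rts[is_lapse] * ceiling, 1e-9)

    table = design.copy()
    table["response"] = responses
    table["rt_seconds"] = rts
    table["kw1_correct"] = kw1_flags
    table["kw2_correct"] = kw2_flags
    return table


def simulate_preferences(vote_probs: dict, n_per_group: int = 50,
                         seed=None) -> pd.DataFrame:
    """Multinomial preference votes per (group, conversation) cell.

    ``vote_probs`` maps ``(group, conversation)`` to a probability vector
    over the presentation modes (must sum to 1); each cell's counts sum to
    ``n_per_group`` exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (g, conv), probs in vote_probs.items():
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(MODES),):
            raise ValueError("need one probability per mode")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"probabilities for ({g}, {conv}) sum to {probs.sum()}, not 1"
            )
        counts = rng.multinomial(n_per_group, probs)
        for m, c in zip(MODES, counts):
            rows.append({"group": g, "conversation": conv, "mode": m,
                         "count": int(c)})
    return pd.DataFrame(rows)


def study_preference_probs() -> dict:
    """Vote-probability defaults emulating the observed preference pattern.

    CI users mostly chose captions (most strongly for the lowest-quality
    conversation A), AH listeners mostly chose plain video.
    """
    return {
        ("AH", "A"): (0.26, 0.64, 0.10),
        ("AH", "B"): (0.12, 0.80, 0.08),
        ("AH", "C"): (0.18, 0.72, 0.10),
        ("CI", "A"): (0.02, 0.06, 0.92),
        ("CI", "B"): (0.08, 0.23, 0.69),
        ("CI", "C"): (0.10, 0.27, 0.63),
    }
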