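"""Closed-form linear ballistic accumulator (LBA) mathematics.

The LBA models a single choice among K response options as a race between K
independent evidence accumulators.  On each trial, accumulator *j* starts at a
point drawn uniformly from ``[0, A]`` and accrues evidence linearly at a rate
drawn from ``Normal(v_j, s)``; the first accumulator to reach the threshold
``b > A`` determines the response, and the decision time is the winner's
first-passage time.  Observed response time adds a non-decision component
``t0`` for stimulus encoding and motor execution.

Here the four response options are the correct keyword and three structured
foils (semantically similar, phonetically similar, neither), each crossed with
three presentation modes (audio, audio-visual, audio-visual plus captions).
The between-trial drift SD ``s`` is fixed to 1, the standard scaling
constraint that makes the remaining parameters identifiable.

A small contaminant mixture guards against lapses: with probability ``lam``
the response is uniform over the four options and the RT uniform on
``(0, t_max)``, which keeps the likelihood proper and finite even for
responses faster than ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

MODES = ("audio", "video", "captions")
RESPONSES = ("correct", "semantic", "phonetic", "neither")

T0_FLOOR = 0.150  # seconds; minimum non-decision time
LOG_FLOOR = -745.0  # log-density floor, just above log(min double)

#: Names of the 17 free per-individual parameters, in canonical order:
#: 12 drift means (mode-major, response-minor), two serial-dependency boosts,
#: then A, b, t0.
PARAM_NAMES = tuple(
    [f"v_{r}_{m}" for m in MODES for r in RESPONSES]
    + ["boost_kw2", "boost_kw3", "A", "b", "t0"]
)
N_PARAMS = len(PARAM_NAMES)  # 17

IDX_BOOST2 = 12
IDX_BOOST3 = 13
IDX_A = 14
IDX_B = 15
IDX_T0 = 16


@dataclass
class IndividualParams:
    """The 17 free LBA parameters of one participant (constrained scale).

    ``v[m, r]`` is the mean drift toward response ``r`` in mode ``m``
    (any real value; negative drifts mean the accumulator usually fails).
    ``boost_kw2``/``boost_kw3`` are additive increments to the *correct*
    drift on keywords 2/3 when all preceding keywords in the sentence were
    answered correctly.  ``s`` is fixed at 1 by the scaling constraint and is
    not counted as free.
    """

    v: np.ndarray  # shape (3 modes, 4 responses)
    boost_kw2: float
    boost_kw3: float
    A: float
    b: float
    t0: float
    s: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (len(MODES), len(RESPONSES)):
            raise ValueError(f"v must have shape (3, 4), got {self.v.shape}")
        if not self.A > 0:
            raise ValueError("start-point range A must be positive")
        if not self.b > self.A:
            raise ValueError("threshold b must exceed A")
        if self.t0 < T0_FLOOR:
            raise ValueError(f"non-decision time must be >= {T0_FLOOR} s")

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "IndividualParams":
        """Build from the canonical 17-vector (see :data:`PARAM_NAMES`)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_PARAMS,):
            raise ValueError(f"expected a {N_PARAMS}-vector")
        return cls(
            v=theta[:12].reshape(len(MODES), len(RESPONSES)),
            boost_kw2=float(theta[IDX_BOOST2]),
            boost_kw3=float(theta[IDX_BOOST3]),
            A=float(theta[IDX_A]),
            b=float(theta[IDX_B]),
            t0=float(theta[IDX_T0]),
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.v.ravel(), [self.boost_kw2, self.boost_kw3, self.A, self.b, self.t0]]
        )


@dataclass
class TrialContext:
    """Position of a keyword within its sentence plus prior-correctness flags."""

    mode: str
    keyword_index: int  # 1, 2 or 3
    kw1_correct: bool = False
    kw2_correct: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.keyword_index not in (1, 2, 3):
            raise ValueError("keyword_index must be 1, 2 or 3")


def effective_drifts(params: IndividualParams, ctx: TrialContext) -> np.ndarray:
    """Drift means for the four accumulators after serial-dependency boosts.

    The correct-response drift receives ``boost_kw2`` on keyword 2 when
    keyword 1 was answered correctly, and ``boost_kw3`` on keyword 3 when
    both preceding keywords were; error drifts are never boosted.
    """
    m = MODES.index(ctx.mode)
    drifts = params.v[m].astype(float).copy()
    if ctx.keyword_index == 2 and ctx.kw1_correct:
        drifts[0] += params.boost_kw2
    elif ctx.keyword_index == 3 and ctx.kw1_correct and ctx.kw2_correct:
        drifts[0] += params.boost_kw3
    return drifts


def accumulator_cdf(t, A, b, v, s=1.0):
    """P(single accumulator reaches threshold by decision time ``t``).

    Start point ~ Uniform(0, A), drift ~ Normal(v, s), threshold b.  The
    distribution is defective: the ``t -> inf`` limit is ``Phi(v / s)``, the
    probability that the drift is positive.  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("decision time must be non-negative")
    A, b, v, s = float(A), float(b), float(v), float(s)
    _check_abs(A, b, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        st = s * t
        z1 = (b - A - v * t) / st
        z2 = (b - v * t) / st
        out = (
            1.0
            + ((b - A - v * t) / A) * ndtr(z1)
            - ((b - v * t) / A) * ndtr(z2)
            + (st / A) * (norm.pdf(z1) - norm.pdf(z2))
        )
    out = np.where(t <= 0.0, 0.0, out)
    return np.clip(out, 0.0, 1.0)[()] if out.ndim == 0 else np.clip(out, 0.0, 1.0)


def accumulator_pdf(t, A, b, v, s=1.0):
    """First-passage density of one accumulator; 0 for ``t <= 0``."""
    t = np.asarray(t, dtype=float)
    A, b, v, s = float(A), float(b), float(v), float(s)
    _check_abs(A, b, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        st = s * t
        z1 = (b - A - v * t) / st
        z2 = (b - v * t) / st
        out = (-v * ndtr(z1) + s * norm.pdf(z1) + v * ndtr(z2) - s * norm.pdf(z2)) / A
    out = np.where(t <= 0.0, 0.0, np.maximum(out, 0.0))
    return out[()] if out.ndim == 0 else out


def _check_abs(A: float, b: float, s: float) -> None:
    if not (A > 0 and b > A and s > 0):
        raise ValueError("require A > 0, b > A, s > 0")


def race_defective_log_density(t_decision, response_idx, drifts, A, b, s=1.0):
    """Log defective density of (response, decision time) under the 4-way race.

    ``f_r(t) * prod_{j != r} (1 - F_j(t))``: the chosen accumulator finishes
    at ``t`` while all competitors are still below threshold.  Integrating
    over ``t`` yields the choice probability; the masses over responses sum
    to P(at least one accumulator finishes), which may be below 1 — no
    renormalization over the all-fail event is applied (the contaminant
    mixture in :func:`trial_log_likelihood` keeps the data likelihood
    proper).  Returns values floored at ``LOG_FLOOR``; ``t <= 0`` maps to the
    floor (zero density).
    """
    t = np.asarray(t_decision, dtype=float)
    drifts = np.asarray(drifts, dtype=float)
    if drifts.shape[-1] != len(RESPONSES):
        raise ValueError("drifts must have length 4")
    r = int(response_idx)
    dens = accumulator_pdf(t, A, b, drifts[r], s)
    for j in range(len(RESPONSES)):
        if j == r:
            continue
        dens = dens * (1.0 - accumulator_cdf(np.maximum(t, 0.0), A, b, drifts[j], s))
    with np.errstate(divide="ignore"):
        out = np.where(t > 0, np.log(np.maximum(dens, 0.0)), -np.inf)
    out = np.maximum(out, LOG_FLOOR)
    return out[()] if out.ndim == 0 else out


def race_finish_probability(drifts, s=1.0) -> float:
    """Closed-form P(at least one accumulator ever finishes).

    Accumulator ``j`` finishes eventually iff its drift sample is positive,
    with probability ``Phi(v_j / s)``; independence across accumulators
    gives ``1 - prod_j Phi(-v_j / s)``.
    """
    drifts = np.asarray(drifts, dtype=float)
    return float(1.0 - np.prod(ndtr(-drifts / float(s))))


def trial_log_likelihood(rt, response_idx, params: IndividualParams,
                         ctx: TrialContext, lam: float, t_max: float,
                         renormalize: bool = False) -> float:
    """Log likelihood of one keyword selection under the contaminant mixture.

    ``(1 - lam) * race(rt - t0, response) + lam / (4 * t_max)``: the lapse
    component is uniform over the four options and over RT on ``(0, t_max)``,
    so the value is finite for any ``rt`` in ``(0, t_max]`` — including
    responses faster than the non-decision time, whose race density is zero.

    With ``renormalize=True`` the race term is divided by
    :func:`race_finish_probability`, turning the defective density into a
    proper density over finishing events; this is the convention the
    hierarchical model uses (see :mod:`lbaspeech.model`).  The default
    leaves the race defective.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("contaminant proportion must lie in [0, 1]")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if rt > t_max:
        raise ValueError(f"rt={rt} exceeds t_max={t_max}")
    drifts = effective_drifts(params, ctx)
    t = rt - params.t0
    if t > 0:
        race = float(
            np.exp(
                race_defective_log_density(t, response_idx, drifts, params.A, params.b, params.s)
            )
        )
        if renormalize:
            race /= max(race_finish_probability(drifts, params.s), 1e-12)
    else:
        race = 0.0
    mix = (1.0 - lam) * race + lam / (4.0 * t_max)
    return max(float(np.log(mix)) if mix > 0 else -np.inf, LOG_FLOOR)


def dataset_log_likelihood(table, params_by_pid: dict, lam: float, t_max: float,
                           per_row: bool = False):
    """Summed log likelihood of a trial table (vectorized contract).

    ``table`` is a trial-table DataFrame (see :mod:`lbaspeech.io`);
    ``params_by_pid`` maps participant id to :class:`IndividualParams`.
    Row order does not affect the sum.  With ``per_row=True`` also returns
    the per-row log-likelihood array in the table's row order.
    """
    vals = np.empty(len(table), dtype=float)
    resp_codes = table["response"].map({r: i for i, r in enumerate(RESPONSES)}).to_numpy()
    for k, (_, row) in enumerate(table.iterrows()):
        ctx = TrialContext(
            mode=row["mode"],
            keyword_index=int(row["keyword_index"]),
            kw1_correct=bool(row["kw1_correct"]),
            kw2_correct=bool(row["kw2_correct"]),
        )
        vals[k] = trial_log_likelihood(
            float(row["rt_seconds"]), int(resp_codes[k]),
            params_by_pid[row["participant_id"]], ctx, lam, t_max,
        )
    total = float(vals.sum())
    return (total, vals) if per_row else total
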