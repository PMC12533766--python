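"""Model fitting, posterior containers, diagnostics and predictive checks."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic, transforms
from .lba import PARAM_NAMES, N_PARAMS
from .model import HierarchicalLBA, PackedData, pack_data
from .nuts import SamplerConfig, sample_chain


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws for the hierarchical LBA model.

    Draws are stored on the packed unconstrained scale together with the
    model object, so any derived quantity (constrained group-level
    parameters, individual parameters, the correlation matrix) can be
    reconstructed exactly from ``(mu, tau, L, z)`` — the non-centered
    identity holds by construction.
    """

    model: HierarchicalLBA
    draws: np.ndarray  # (chains, iterations, dim), unconstrained
    logps: np.ndarray  # (chains, iterations)
    config: SamplerConfig
    chain_stats: list = field(default_factory=list)
    data_hash: str = ""

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_iterations

    @property
    def groups(self) -> tuple:
        return self.model.data.groups

    def _flat(self):
        return self.draws.reshape(-1, self.draws.shape[-1])

    def group_level(self) -> dict:
        """Constrained group-level parameters: (chains, iterations) arrays.

        Keys are ``"<param>[<group>]"`` for the transformed group means plus
        the global ``"lambda"``.  These are the quantities reported as
        group-level posteriors.
        """
        m = self.model
        out = {}
        for g_idx, g in enumerate(self.groups):
            sl = slice(m.off_mu + g_idx * N_PARAMS,
                       m.off_mu + (g_idx + 1) * N_PARAMS)
            mu = self.draws[:, :, sl]
            con = transforms.constrain_matrix(mu)
            for k, name in enumerate(PARAM_NAMES):
                out[f"{name}[{g}]"] = con[:, :, k]
        lam = _sigmoid(self.draws[:, :, m.off_lam])
        out["lambda"] = lam
        return out

    def scale_draws(self) -> dict:
        """Between-subject scales tau (shared across groups)."""
        m = self.model
        tau = np.exp(self.draws[:, :, m.off_tau:m.off_corr])
        return {f"tau[{name}]": tau[:, :, k]
                for k, name in enumerate(PARAM_NAMES)}

    def correlation_mean(self) -> np.ndarray:
        """Posterior-mean 17x17 correlation matrix (thinned for speed)."""
        flat = self._flat()
        m = self.model
        step = max(1, len(flat) // 400)
        mats = [transforms.corr_from_unconstrained(x[m.off_corr:m.off_lam])
                for x in flat[::step]]
        return np.mean(mats, axis=0)

    def individual_draws(self, thin: int = 1) -> np.ndarray:
        """Constrained individual parameters, (chains, iters//thin, N, 17)."""
        m = self.model
        sub = self.draws[:, ::thin]
        out = np.empty(sub.shape[:2] + (m.n_ind, N_PARAMS))
        for c in range(sub.shape[0]):
            for i in range(sub.shape[1]):
                out[c, i] = m.individual_constrained(sub[c, i])
        return out

    def lambda_draws(self) -> np.ndarray:
        return _sigmoid(self.draws[:, :, self.model.off_lam])

    def to_long_dataframe(self, include_scales: bool = True) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        entries = self.group_level()
        if include_scales:
            entries.update(self.scale_draws())
        frames = []
        for name, arr in entries.items():
            c, i = np.meshgrid(np.arange(self.n_chains),
                               np.arange(self.n_iterations), indexing="ij")
            frames.append(pd.DataFrame({
                "chain": c.ravel(), "iteration": i.ravel(),
                "parameter": name, "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def data_fingerprint(table: pd.DataFrame) -> str:
    return hashlib.sha256(
        table.to_csv(index=False).encode()
    ).hexdigest()[:16]


def fit_model(table: pd.DataFrame, config: SamplerConfig | None = None,
              groups=None, t_max=None, progress: bool = False) -> PosteriorDraws:
    """Fit the hierarchical LBA model by NUTS.

    Runs ``config.chains`` independent chains (sequentially), each seeded
    from ``(config.seed, chain index)``; identical inputs give identical
    draws.  Initial unconstrained values are Uniform(-0.5, 0.5) per chain,
    re-drawn (up to 20 times) if the joint log posterior is not finite.
    """
    config = config or SamplerConfig()
    packed = pack_data(table, groups=groups, t_max=t_max)
    if len(packed.participant_ids) == 0:
        raise ValueError("cannot fit an empty dataset")
    model = HierarchicalLBA(packed)
    all_draws = []
    all_logps = []
    stats = []
    for c in range(config.chains):
        rng = np.random.default_rng([int(config.seed) % 2**31, c])
        x0 = None
        for _ in range(20):
            cand = model.initial_point(rng, config.init_scale)
            if np.isfinite(model.logp(cand)):
                x0 = cand
                break
        if x0 is None:
            raise FloatingPointError(
                "could not find a finite initial log posterior; check the "
                "data for non-positive RTs or degenerate structure"
            )
        draws, logps, st = sample_chain(model.logp_and_grad, x0, config, rng)
        if progress:
            print(f"chain {c}: step={st.step_size:.4f} "
                  f"accept={st.accept_rate:.2f} divergences={st.divergences}",
                  flush=True)
        all_draws.append(draws)
        all_logps.append(logps)
        stats.append(st)
    return PosteriorDraws(
        model=model,
        draws=np.stack(all_draws),
        logps=np.stack(all_logps),
        config=config,
        chain_stats=stats,
        data_hash=data_fingerprint(table),
    )


def save_fit_state(posterior: PosteriorDraws, path) -> None:
    """Persist the full posterior (unconstrained draws + layout metadata).

    Compact binary container for pipeline hand-off between CLI stages; the
    portable long-format CSV surface is :meth:`PosteriorDraws.to_long_dataframe`.
    """
    d = posterior.model.data
    cfg = posterior.config
    np.savez_compressed(
        path,
        draws=posterior.draws,
        logps=posterior.logps,
        participant_ids=d.participant_ids,
        group_of=d.group_of,
        groups=np.asarray(d.groups),
        t_max=d.t_max,
        data_hash=posterior.data_hash,
        renormalize_race=posterior.model.renormalize_race,
        config=np.asarray(json.dumps({
            "chains": cfg.chains, "warmup_iterations": cfg.warmup_iterations,
            "sampling_iterations": cfg.sampling_iterations, "seed": cfg.seed,
            "target_acceptance": cfg.target_acceptance,
            "max_tree_depth": cfg.max_tree_depth,
        })),
    )


def load_fit_state(path, table: pd.DataFrame | None = None) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` saved by :func:`save_fit_state`.

    If the original trial table is supplied the packed data is rebuilt from
    it (restoring likelihood evaluation and PPC) and its fingerprint is
    checked against the stored hash.
    """
    z = np.load(path, allow_pickle=False)
    groups = tuple(str(g) for g in z["groups"])
    stored_hash = str(z["data_hash"])
    if table is not None:
        if data_fingerprint(table) != stored_hash:
            raise ValueError("trial table does not match the fitted data "
                             "(fingerprint mismatch)")
        packed = pack_data(table, groups=groups, t_max=float(z["t_max"]))
    else:
        empty = np.empty(0, dtype=np.int64)
        packed = PackedData(
            pid=empty, mode=empty, resp=empty, bf2=empty, bf3=empty,
            rt=np.empty(0), participant_ids=z["participant_ids"],
            group_of=z["group_of"], groups=groups, t_max=float(z["t_max"]),
        )
    cfg_d = json.loads(str(z["config"]))
    renorm = bool(z["renormalize_race"]) if "renormalize_race" in z else True
    return PosteriorDraws(
        model=HierarchicalLBA(packed, renormalize_race=renorm),
        draws=z["draws"], logps=z["logps"],
        config=SamplerConfig(**cfg_d),
        data_hash=stored_hash,
    )


def convergence_diagnostics(draws) -> pd.DataFrame:
    """Split-Rhat and bulk/tail effective sample sizes per parameter.

    ``draws`` is a :class:`PosteriorDraws` or a dict mapping parameter name
    to a (chains, iterations) array.  Parameters with Rhat > 1.01 are
    flagged; chains with zero variance yield NaN Rhat and are flagged as
    degenerate.  At least two chains are required for Rhat to be defined.
    """
    import arviz as az

    entries = draws.group_level() if isinstance(draws, PosteriorDraws) else dict(draws)
    first = next(iter(entries.values()))
    if np.asarray(first).shape[0] < 2:
        raise ValueError("Rhat requires at least 2 chains")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in entries.items():
            arr = np.asarray(arr, dtype=float)
            idata = az.from_dict({"p": arr})
            rhat = float(az.rhat(idata)["p"].values)
            ess_bulk = float(az.ess(idata)["p"].values)
            ess_tail = float(az.ess(idata, method="tail")["p"].values)
            degenerate = bool(np.isnan(rhat)) or float(np.var(arr)) == 0.0
            rows.append({
                "parameter": name,
                "rhat": rhat,
                "ess_bulk": ess_bulk,
                "ess_tail": ess_tail,
                "degenerate": degenerate,
                "flagged": degenerate or (np.isfinite(rhat) and rhat > 1.01),
            })
    return pd.DataFrame(rows)


def posterior_predictive_simulate(draws: PosteriorDraws, design: pd.DataFrame,
                                  n_datasets: int, seed=None) -> list:
    """Replicated datasets from sampled posterior draws.

    For each replicate a posterior draw (chain, iteration) is sampled and a
    full dataset is simulated with that draw's individual-level parameters
    over the supplied design (which must contain exactly the fitted
    participants).  Serial-dependency context is replayed from the simulated
    responses, as in the generative model.
    """
    rng = np.random.default_rng(seed)
    if n_datasets == 0:
        return []
    need = {"participant_id", "group", "trial_id", "mode", "keyword_index"}
    if not need.issubset(design.columns):
        raise ValueError(f"design must contain columns {sorted(need)}")
    fitted = set(draws.model.data.participant_ids.tolist())
    given = set(pd.unique(design["participant_id"]).tolist())
    if fitted != given:
        raise ValueError(
            "design participants do not match the fitted participants"
        )
    m = draws.model
    pid_order = {p: i for i, p in enumerate(m.data.participant_ids)}
    out = []
    for _ in range(n_datasets):
        c = int(rng.integers(0, draws.n_chains))
        i = int(rng.integers(0, draws.n_iterations))
        x = draws.draws[c, i]
        theta_c = m.individual_constrained(x)
        lam = m.lam(x)
        params_by_pid = {
            p: _params_from_row(theta_c[pid_order[p]]) for p in given
        }
        out.append(synthetic.simulate_from_params(
            design.copy(), params_by_pid, lam, m.data.t_max, rng,
        ))
    return out


def _params_from_row(theta_row: np.ndarray):
    from .lba import IndividualParams
    return IndividualParams.from_vector(theta_row)
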