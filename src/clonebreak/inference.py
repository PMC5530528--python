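"""Structured variational EM for joint segment/breakpoint copy number.

The posterior over segment copy numbers ``C``, breakpoint copy numbers
``B`` and the point-estimated haploid depths ``h`` and likelihood
parameters ``theta`` is approximated with a structured factorisation

    q(C, B, h, theta) = q(h) q(theta) q(C) prod_k q_k(b_k),

where ``q(C)`` retains the full chain dependency between adjacent segments
(one chain per chromosome) and each breakpoint's copy number has an
independent factor shared by both of its breakends.  Coordinate ascent on
the evidence lower bound (ELBO) alternates:

1. rebuild the chain: emissions from the read-count likelihood, transition
   terms as the expectation of ``log f`` under the current ``q_k``;
2. sum-product (forward-backward) for the single and pairwise marginals
   ``gamma``;
3. exact updates of every ``q_k`` from the pairwise marginals at its
   breakend boundaries;
4. a guarded quasi-Newton update of the point estimates ``h`` (and
   optionally the dispersion parameters), accepted only if the expected
   log-likelihood does not decrease.

Each step can only increase the ELBO, which is tracked incrementally.
Multiple restarts over a grid of candidate normal fractions and tumour
clone splits are screened for a few sweeps each; the best is run to
convergence.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import logsumexp

from .graph import StateSpace
from .likelihood import (
    LikelihoodParams,
    emission_matrix,
    total_count_dll_dmu,
    total_count_loglik,
    total_count_matrix,
)
from .segments import Breakpoint, breakpoints_from_table

__all__ = [
    "FitConfig", "ChainModel", "VariationalState", "MixtureResult",
    "build_chain", "sum_product", "pairwise_marginal",
    "update_q_breakpoints", "update_h_theta", "elbo", "fit",
]

_BREAK = -2
_PLAIN = -1


@dataclass
class FitConfig:
    """Configuration of the variational fit.

    ``lam`` is the telomere penalty (larger values enforce smoother copy
    number); ``max_total_copies`` caps the per-clone total copy number;
    ``b_max`` caps per-clone breakpoint copy number.  The restart grid is
    the cross product of ``normal_fractions`` and ``clone_splits`` (the
    descendant share of the tumour); each restart is screened for
    ``screen_iters`` sweeps and the best ELBO is run to convergence.
    """

    n_tumour_clones: int = 2
    max_total_copies: int = 5
    b_max: int = 2
    lam: float = 4.0
    likelihood: LikelihoodParams = field(default_factory=LikelihoodParams)
    tol: float = 1e-6
    max_iter: int = 100
    screen_iters: int = 5
    h_hold_iters: int = 3
    refine_top: int = 2
    normal_fractions: tuple = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    clone_splits: tuple = (0.05, 0.15, 0.25, 0.35, 0.45)
    fit_dispersion: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["likelihood"] = self.likelihood.to_dict()
        for k in ("normal_fractions", "clone_splits"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        if "likelihood" in d and isinstance(d["likelihood"], dict):
            d["likelihood"] = LikelihoodParams.from_dict(d["likelihood"])
        for k in ("normal_fractions", "clone_splits"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


class ChainModel:
    """Observed data, adjacency structure and pre-computed factor tables."""

    def __init__(self, segments: pd.DataFrame,
                 breakpoints: Union[pd.DataFrame, Sequence[Breakpoint], None],
                 config: FitConfig):
        self.config = config
        seg = segments.reset_index(drop=True)
        self.segments = seg
        self.x = seg["readcount"].to_numpy(dtype=np.int64)
        xa = seg["allele_a_readcount"].to_numpy(dtype=np.int64)
        xb = seg["allele_b_readcount"].to_numpy(dtype=np.int64)
        self.x_major = np.maximum(xa, xb)
        self.x_minor = np.minimum(xa, xb)
        self.eff_len = seg["effective_length"].to_numpy(dtype=float)
        self.length = seg["length"].to_numpy(dtype=float)
        self.chrom = seg["chromosome"].astype(str).to_numpy()
        self.n_segments = len(seg)

        self.space = StateSpace(
            n_tumour=config.n_tumour_clones,
            max_total=config.max_total_copies,
            b_max=config.b_max,
        )
        self.log_trans_plain = -config.lam * self.space.plain_telomere_matrix()
        self.exp_trans_plain = np.exp(self.log_trans_plain)
        self.bp_telomeres = {
            o: self.space.breakpoint_telomere_matrices(o) for o in (1, -1)
        }

        if breakpoints is None:
            breakpoints = []
        if isinstance(breakpoints, pd.DataFrame):
            breakpoints = breakpoints_from_table(breakpoints)
        self.warnings: list[str] = []
        self._build_adjacencies(list(breakpoints))

    def _build_adjacencies(self, breakpoints: list):
        n = self.n_segments
        seg = self.segments
        kind = np.full(max(n - 1, 0), _PLAIN, dtype=np.int64)
        orient = np.zeros(max(n - 1, 0), dtype=np.int64)
        boundary_of = {}
        ends = seg["end"].to_numpy()
        starts = seg["start"].to_numpy()
        for i in range(n - 1):
            if self.chrom[i] != self.chrom[i + 1]:
                kind[i] = _BREAK
            else:
                boundary_of[(self.chrom[i], int(ends[i]))] = i

        self.breakpoint_ids: list[str] = []
        self.bp_boundaries: list[list[tuple[int, int]]] = []
        taken: dict[int, str] = {}
        for bp in breakpoints:
            locs = []
            ok = True
            for be in (bp.breakend_1, bp.breakend_2):
                key = (be.chromosome, int(be.position))
                if key not in boundary_of:
                    self.warnings.append(
                        f"breakpoint {bp.id}: breakend {key} is not an "
                        "interior segment boundary; breakpoint ignored")
                    ok = False
                    break
                locs.append((boundary_of[key], be.orientation))
            if not ok:
                continue
            if locs[0][0] == locs[1][0]:
                self.warnings.append(
                    f"breakpoint {bp.id}: both breakends map to one "
                    "boundary; breakpoint ignored")
                continue
            clash = [i for i, _ in locs if i in taken]
            if clash:
                self.warnings.append(
                    f"breakpoint {bp.id}: boundary already carries breakend "
                    f"of breakpoint {taken[clash[0]]}; breakpoint ignored")
                continue
            k = len(self.breakpoint_ids)
            self.breakpoint_ids.append(bp.id)
            self.bp_boundaries.append(locs)
            for i, o in locs:
                taken[i] = bp.id
                kind[i] = k
                orient[i] = o
        self.kind = kind
        self.orient = orient
        self.n_breakpoints = len(self.breakpoint_ids)

        # contiguous chains (per chromosome)
        chains = []
        start = 0
        for i in range(n - 1):
            if kind[i] == _BREAK:
                chains.append((start, i + 1))
                start = i + 1
        chains.append((start, n))
        self.chains = chains
        self.chain_of = np.zeros(n, dtype=np.int64)
        for ci, (s, e) in enumerate(chains):
            self.chain_of[s:e] = ci

        # map from state index to unique clone-total vector (normal at 2)
        totals_full = np.concatenate(
            [np.full((self.space.n_states, 1), 2), self.space.totals], axis=1)
        self.unique_totals, self.totals_inverse = np.unique(
            totals_full, axis=0, return_inverse=True)


class VariationalState:
    """Mutable variational quantities of one restart."""

    def __init__(self, model: ChainModel, h0: np.ndarray):
        self.h = np.asarray(h0, dtype=float)
        self.params = replace(model.config.likelihood)
        B = model.space.n_breakpoint_states
        self.q_bp = np.full((model.n_breakpoints, B), 1.0 / B)
        self.zeta_single: Optional[np.ndarray] = None
        self.bp_trans: dict[int, np.ndarray] = {}
        self.alpha = self.beta = self.gamma = None
        self.chain_logZ: Optional[np.ndarray] = None
        self.logZ = np.nan
        self.elbo = -np.inf
        self.h_update_failed = False
        self._emission_key = None

    def breakpoint_entropy(self) -> float:
        q = self.q_bp
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(q > 0, q * np.log(q), 0.0)
        return float(-t.sum())


def _log_trans(model: ChainModel, state: VariationalState, i: int) -> np.ndarray:
    if model.kind[i] == _PLAIN:
        return model.log_trans_plain
    return state.bp_trans[i]


def build_chain(model: ChainModel, state: VariationalState) -> None:
    """Recompute emission and transition terms from the current ``h``,
    ``theta`` and ``q_k``: the expectation of ``log f`` under ``q_k`` at
    breakend boundaries and the plain telomere penalty elsewhere.

    The emission matrix only depends on ``h`` and ``theta`` and is cached
    across sweeps in which neither changed.
    """
    key = (state.h.tobytes(), tuple(sorted(state.params.to_dict().items(),
                                           key=lambda kv: kv[0])))
    key = (key[0], str(key[1]))
    if state.zeta_single is None or key != state._emission_key:
        state.zeta_single = emission_matrix(
            model.x, model.x_major, model.x_minor, model.eff_len,
            model.space, state.h, state.params)
        state._emission_key = key
    state.bp_trans = {}
    lam = model.config.lam
    for k in range(model.n_breakpoints):
        for i, o in model.bp_boundaries[k]:
            expected_t = np.tensordot(
                state.q_bp[k], model.bp_telomeres[o], axes=(0, 0))
            state.bp_trans[i] = -lam * expected_t


def sum_product(model: ChainModel, state: VariationalState) -> None:
    """Forward-backward over each chromosome chain: fills the single
    marginals ``gamma``, messages and the log-partition."""
    zeta = state.zeta_single
    n, S = zeta.shape
    alpha = np.empty((n, S))
    beta = np.zeros((n, S))
    chain_logZ = np.empty(len(model.chains))
    if np.any(np.all(np.isinf(zeta) & (zeta < 0), axis=1)):
        bad = int(np.where(np.all(np.isinf(zeta) & (zeta < 0), axis=1))[0][0])
        raise ValueError(f"segment {bad} has no feasible copy-number state")
    with np.errstate(divide="ignore"):
        for ci, (s, e) in enumerate(model.chains):
            a = zeta[s].copy()
            alpha[s] = a
            for i in range(s, e - 1):
                P = (model.exp_trans_plain if model.kind[i] == _PLAIN
                     else np.exp(state.bp_trans[i]))
                m = a.max()
                a = np.log(np.exp(a - m) @ P) + m + zeta[i + 1]
                alpha[i + 1] = a
            chain_logZ[ci] = logsumexp(a)
            b = np.zeros(S)
            for i in range(e - 2, s - 1, -1):
                P = (model.exp_trans_plain if model.kind[i] == _PLAIN
                     else np.exp(state.bp_trans[i]))
                u = zeta[i + 1] + b
                m = u.max()
                b = np.log(P @ np.exp(u - m)) + m
                beta[i] = b
    state.alpha, state.beta = alpha, beta
    state.chain_logZ = chain_logZ
    state.logZ = float(chain_logZ.sum())
    state.gamma = np.exp(alpha + beta - chain_logZ[model.chain_of][:, None])


def pairwise_marginal(model: ChainModel, state: VariationalState,
                      i: int) -> np.ndarray:
    """(S, S) pairwise marginal ``gamma_i(c, c')`` at boundary ``i``."""
    if model.kind[i] == _BREAK:
        raise ValueError("no pairwise marginal across a chromosome break")
    logm = (state.alpha[i][:, None] + _log_trans(model, state, i)
            + (state.zeta_single[i + 1] + state.beta[i + 1])[None, :]
            - state.chain_logZ[model.chain_of[i]])
    return np.exp(logm)


def update_q_breakpoints(model: ChainModel, state: VariationalState) -> float:
    """Exact coordinate update of every breakpoint factor ``q_k`` from the
    pairwise marginals at its breakend boundaries; returns the resulting
    ELBO change (always >= 0 up to round-off)."""
    lam = model.config.lam
    delta = 0.0
    for k in range(model.n_breakpoints):
        scores = np.zeros(model.space.n_breakpoint_states)
        for i, o in model.bp_boundaries[k]:
            gp = pairwise_marginal(model, state, i)
            scores += -lam * np.tensordot(
                model.bp_telomeres[o], gp, axes=([1, 2], [0, 1]))
        q_old = state.q_bp[k]
        q_new = np.exp(scores - logsumexp(scores))
        q_new /= q_new.sum()

        def _ent(q):
            with np.errstate(divide="ignore", invalid="ignore"):
                return float(-np.where(q > 0, q * np.log(q), 0.0).sum())

        delta += float((q_new - q_old) @ scores) + _ent(q_new) - _ent(q_old)
        state.q_bp[k] = q_new
    return delta


def _expected_emission(model: ChainModel, state: VariationalState,
                       h: np.ndarray, params: LikelihoodParams) -> float:
    em = emission_matrix(model.x, model.x_major, model.x_minor,
                         model.eff_len, model.space, h, params)
    return float((state.gamma * em).sum())


def update_h_theta(model: ChainModel, state: VariationalState) -> float:
    """Point-estimate update of the haploid depths ``h`` (and optionally the
    negative binomial dispersions) maximising the gamma-weighted expected
    read-count log-likelihood.

    A quasi-Newton (L-BFGS-B) proposal is computed on the total-count term,
    which carries nearly all of the depth information, then accepted only if
    the full expected log-likelihood (total + allele terms) does not
    decrease; otherwise the previous estimates are kept and the
    non-improvement flagged.  Returns the ELBO change.
    """
    cfg = model.config
    gamma = state.gamma
    n_u = len(model.unique_totals)
    W = np.zeros((model.n_segments, n_u))
    for u in range(n_u):
        cols = model.totals_inverse == u
        W[:, u] = gamma[:, cols].sum(axis=1)

    fit_disp = cfg.fit_dispersion and state.params.family != "poisson"

    def unpack(v):
        h = v[:len(state.h)]
        params = state.params
        if fit_disp:
            r = tuple(np.exp(v[len(state.h):]))
            if params.family == "negbin":
                params = replace(params, inverse_dispersions=(r[0],))
            else:
                params = replace(params, inverse_dispersions=r)
        return h, params

    def objective(v):
        h, params = unpack(v)
        ll = total_count_matrix(model.x, model.eff_len, model.unique_totals,
                                h, params)
        return -float((W * ll).sum())

    uniq = np.asarray(model.unique_totals, dtype=float)
    xcol = model.x[:, None]
    eff = model.eff_len

    def objective_and_grad(h):
        mu = eff[:, None] * (uniq @ h)[None, :]
        ll = total_count_loglik(xcol, mu, state.params)
        d = total_count_dll_dmu(xcol, mu, state.params)
        f = -float((W * ll).sum())
        grad = -((W * d) * eff[:, None]).sum(axis=0) @ uniq
        return f, grad

    x0 = np.array(state.h, dtype=float)
    bounds = [(1e-12, None)] * len(state.h)
    if fit_disp:
        n_r = 1 if state.params.family == "negbin" else 2
        x0 = np.concatenate([x0, np.log(state.params.inverse_dispersions[:n_r])])
        bounds += [(np.log(1e-2), np.log(1e12))] * n_r
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 30})
    else:
        res = minimize(objective_and_grad, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-10})
    h_new, params_new = unpack(res.x)

    f_old = _expected_emission(model, state, state.h, state.params)
    f_new = _expected_emission(model, state, h_new, params_new)
    if np.isfinite(f_new) and f_new >= f_old:
        state.h = np.asarray(h_new, dtype=float)
        state.params = params_new
        state.h_update_failed = False
        return f_new - f_old
    state.h_update_failed = True
    return 0.0


def elbo(model: ChainModel, state: VariationalState) -> float:
    """Evidence lower bound at the current variational state.

    Computed from first principles: the expected joint log-probability
    under ``q`` plus the entropies of ``q(C)`` and the ``q_k`` (the entropy
    of the delta factors on ``h`` and ``theta`` is constant and omitted).
    ``q(C)`` is the chain posterior of the terms built at the last
    sum-product; the expectation uses the *current* ``h``, ``theta`` and
    ``q_k``, so the value is exact after any single coordinate update.
    """
    e_single = _expected_emission(model, state, state.h, state.params)
    lam = model.config.lam
    e_pairs = 0.0
    h_pairs = 0.0
    for i in range(model.n_segments - 1):
        if model.kind[i] == _BREAK:
            continue
        gp = pairwise_marginal(model, state, i)
        built = _log_trans(model, state, i)
        if model.kind[i] == _PLAIN:
            current = model.log_trans_plain
        else:
            k = model.kind[i]
            o = model.orient[i]
            current = -lam * np.tensordot(
                state.q_bp[k], model.bp_telomeres[o], axes=(0, 0))
        with np.errstate(invalid="ignore"):
            e_pairs += float(np.where(gp > 0, gp * current, 0.0).sum())
            h_pairs += float(np.where(gp > 0, gp * built, 0.0).sum())
    h_chain = (state.logZ - float((state.gamma * state.zeta_single).sum())
               - h_pairs)
    return e_single + e_pairs + h_chain + state.breakpoint_entropy()


@dataclass
class MixtureResult:
    """Result of a fit: mixture, copy numbers and diagnostics.

    ``segment_cn`` carries per-clone major/minor copy columns
    (``major_0``/``minor_0`` is the normal clone, fixed at 1/1);
    ``breakpoint_cn`` carries per-tumour-clone breakpoint copies ``cn_m``.
    ``rho`` are mixture proportions over all clones (normal first), derived
    from the haploid depths ``h`` and the inferred genome masses.
    """

    segment_cn: pd.DataFrame
    breakpoint_cn: pd.DataFrame
    h: np.ndarray
    rho: np.ndarray
    elbo: float
    n_iter: int
    converged: bool
    mode: str
    elbo_traces: list
    warnings: list
    config: FitConfig

    @property
    def n_tumour_clones(self) -> int:
        return len(self.h) - 1

    def cn_array(self) -> np.ndarray:
        """(N, n_tumour, 2) array of tumour-clone (major, minor) copies."""
        cols = []
        for m in range(1, self.n_tumour_clones + 1):
            cols.append(self.segment_cn[[f"major_{m}", f"minor_{m}"]].to_numpy())
        return np.stack(cols, axis=1)

    def breakpoint_cn_array(self) -> np.ndarray:
        cols = [f"cn_{m}" for m in range(1, self.n_tumour_clones + 1)]
        return self.breakpoint_cn[cols].to_numpy()

    def summary(self) -> dict:
        return {
            "h": [float(v) for v in self.h],
            "rho": [float(v) for v in self.rho],
            "elbo": float(self.elbo),
            "iterations": int(self.n_iter),
            "converged": bool(self.converged),
            "mode": self.mode,
            "restarts": len(self.elbo_traces),
            "warnings": list(self.warnings),
        }

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.segment_cn.to_csv(path / "segment_cn.tsv", sep="\t", index=False)
        self.breakpoint_cn.to_csv(path / "breakpoint_cn.tsv", sep="\t",
                                  index=False)
        with open(path / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _screen_and_refine(model: ChainModel, inits: Sequence[np.ndarray],
                       config: FitConfig):
    """Run every candidate initialisation for a few sweeps (the first
    ``h_hold_iters`` with the haploid depths held fixed, so each candidate
    commits to its mixture hypothesis before refining it), then run the
    ``refine_top`` best by ELBO to convergence and keep the overall best.

    Returns (state, n_iter, converged, traces) with the winning restart's
    trace last in ``traces``.
    """
    candidates = []
    for h0 in inits:
        state = VariationalState(model, h0)
        trace: list = []
        it = 0
        n_screen = min(config.screen_iters, config.max_iter)
        for j in range(n_screen):
            _sweep(model, state, trace, update_h=j >= config.h_hold_iters)
            it += 1
        candidates.append([state, trace, it, False])

    order = np.argsort([-c[0].elbo for c in candidates], kind="stable")
    for j in order[:max(config.refine_top, 1)]:
        state, trace, it, _ = candidates[j]
        prev = state.elbo
        converged = False
        while it < config.max_iter:
            _sweep(model, state, trace)
            it += 1
            if abs(state.elbo - prev) <= config.tol * max(1.0, abs(prev)):
                converged = True
                break
            prev = state.elbo
        candidates[j][2] = it
        candidates[j][3] = converged

    best_j = int(np.argmax([c[0].elbo for c in candidates]))
    state, trace, n_iter, converged = candidates[best_j]
    traces = [c[1] for i, c in enumerate(candidates) if i != best_j] + [trace]
    return state, n_iter, converged, traces


def _sweep(model: ChainModel, state: VariationalState, trace: list,
           update_h: bool = True) -> None:
    """One coordinate-ascent sweep: q(C), all q_k, then (h, theta)."""
    build_chain(model, state)
    sum_product(model, state)
    state.elbo = state.logZ + state.breakpoint_entropy()
    trace.append(("q_C", state.elbo))
    if model.n_breakpoints:
        state.elbo += update_q_breakpoints(model, state)
        trace.append(("q_b", state.elbo))
    if update_h:
        state.elbo += update_h_theta(model, state)
        trace.append(("h_theta", state.elbo))


def _extract_result(model: ChainModel, state: VariationalState, mode: str,
                    n_iter: int, converged: bool, traces: list,
                    warnings: list) -> MixtureResult:
    space = model.space
    idx = np.argmax(state.gamma, axis=1)
    cn = space.states[idx]  # (N, n_tumour, 2)

    seg = model.segments[["chromosome", "start", "end", "length"]].copy()
    seg["major_0"] = 1
    seg["minor_0"] = 1
    for m in range(model.config.n_tumour_clones):
        seg[f"major_{m + 1}"] = cn[:, m, 0]
        seg[f"minor_{m + 1}"] = cn[:, m, 1]

    rows = []
    for k, bp_id in enumerate(model.breakpoint_ids):
        b = space.breakpoint_states[int(np.argmax(state.q_bp[k]))]
        rows.append({"breakpoint_id": bp_id,
                     **{f"cn_{m + 1}": int(b[m]) for m in range(len(b))}})
    bp_cols = ["breakpoint_id"] + [
        f"cn_{m + 1}" for m in range(model.config.n_tumour_clones)]
    bp_df = pd.DataFrame(rows, columns=bp_cols)

    totals_full = np.concatenate(
        [np.full((model.n_segments, 1), 2), cn.sum(axis=2)], axis=1)
    mass = (model.length[:, None] * totals_full).sum(axis=0)
    weighted = state.h * mass
    rho = weighted / weighted.sum() if weighted.sum() > 0 else weighted
    return MixtureResult(
        segment_cn=seg, breakpoint_cn=bp_df, h=state.h.copy(), rho=rho,
        elbo=float(state.elbo), n_iter=n_iter, converged=converged,
        mode=mode, elbo_traces=traces, warnings=warnings,
        config=model.config)


def fit(segments: pd.DataFrame,
        breakpoints: Union[pd.DataFrame, Sequence[Breakpoint], None] = None,
        config: Optional[FitConfig] = None,
        _mode: str = "breakpoint") -> MixtureResult:
    """Fit the joint segment/breakpoint copy-number model.

    Parameters
    ----------
    segments:
        Segment table with read counts, allele counts and effective lengths.
    breakpoints:
        Breakpoint table (or ``Breakpoint`` objects); may be empty.
    config:
        :class:`FitConfig`; defaults used when omitted.

    Returns the restart with the best ELBO, with per-segment maximum
    marginal copy numbers, per-breakpoint ``argmax q_k`` copies and mixture
    fractions ``rho_m = h_m S_m / sum_j h_j S_j`` where ``S_m`` is the
    clone's inferred genome mass ``sum_n l_n c_nm``.
    """
    config = config or FitConfig()
    model = ChainModel(segments, breakpoints, config)
    mean_depth = model.x.sum() / max(model.eff_len.sum(), 1.0)
    unit = mean_depth / 2.0

    # stage 1: single-tumour-clone purity scan over candidate normal
    # fractions; pins down the normal depth and the total tumour depth
    # before the (much harder) two-clone decomposition
    if config.n_tumour_clones == 1:
        inits = [unit * np.array([fn, 1.0 - fn])
                 for fn in config.normal_fractions]
        state, n_iter, converged, traces = _screen_and_refine(
            model, inits, config)
    else:
        stage1_cfg = replace(config, n_tumour_clones=1)
        stage1_model = ChainModel(segments, breakpoints, stage1_cfg)
        stage1_inits = [unit * np.array([fn, 1.0 - fn])
                        for fn in config.normal_fractions]
        stage1_state, _, _, stage1_traces = _screen_and_refine(
            stage1_model, stage1_inits, stage1_cfg)
        h_normal, h_tumour = stage1_state.h

        # stage 2: scan descendant/ancestral splits of the tumour depth
        inits = [np.array([h_normal, h_tumour * (1.0 - s), h_tumour * s])
                 for s in config.clone_splits]
        state, n_iter, converged, traces = _screen_and_refine(
            model, inits, config)
        traces = stage1_traces + traces

    # final chain refresh so marginals reflect the final h and q_k
    build_chain(model, state)
    sum_product(model, state)
    state.elbo = state.logZ + state.breakpoint_entropy()
    traces[-1].append(("q_C", state.elbo))

    if not converged:
        model.warnings.append(
            "no restart reached the ELBO tolerance; reporting best partial fit")
        _warnings.warn(model.warnings[-1], RuntimeWarning, stacklevel=2)
    return _extract_result(model, state, _mode, n_iter, converged, traces,
                           list(model.warnings))
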