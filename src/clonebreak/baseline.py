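"""Breakpoint-naive comparator: the same chain model with breakpoint copy
number clamped to zero, followed by greedy post-hoc assignment of breakpoint
copies from the fixed integer segment copy numbers.

Clamping ``b = 0`` makes every breakend transition factor collapse to the
plain telomere penalty, so the chain is an ordinary copy-number HMM; the fit
shares the exact code path of the full model with ``b_max = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .graph import telomere_count_breakpoint
from .inference import ChainModel, FitConfig, MixtureResult, fit
from .segments import Breakpoint

__all__ = ["PosthocAssignment", "fit_naive", "greedy_breakpoint_copies"]


@dataclass
class PosthocAssignment:
    """Greedy post-hoc breakpoint copy assignment and its effect on the
    summed telomere count at the breakpoint's two boundaries."""

    breakpoint_id: str
    copies: np.ndarray  # per tumour clone
    telomeres_before: int
    telomeres_after: int


def _boundary_states(model: ChainModel, cn: np.ndarray, i: int):
    return cn[i], cn[i + 1]


def greedy_breakpoint_copies(
    segment_cn: np.ndarray,
    model: ChainModel,
    b_max: int = 2,
) -> list[PosthocAssignment]:
    """Assign non-negative breakpoint copies minimising the summed telomere
    count at each breakpoint's two boundaries.

    ``segment_cn`` is the fixed (N, n_tumour, 2) integer copy array.
    Breakpoints are processed greedily in input order; for each, candidate
    per-clone copy vectors ``0..b_max`` are scored exhaustively and the
    minimiser kept, ties resolved toward the smaller copy vector.
    """
    n_tumour = segment_cn.shape[1]
    grids = np.meshgrid(*([np.arange(b_max + 1)] * n_tumour), indexing="ij")
    bcands = np.stack([g.ravel() for g in grids], axis=1)
    order = np.lexsort(
        np.concatenate([bcands[:, ::-1].T, bcands.sum(axis=1)[None, :]], axis=0))
    bcands = bcands[order]  # b = 0 first, ascending: ties -> smaller b

    out = []
    for k, bp_id in enumerate(model.breakpoint_ids):
        totals = np.zeros(len(bcands), dtype=np.int64)
        for i, o in model.bp_boundaries[k]:
            c, c_prime = _boundary_states(model, segment_cn, i)
            for j, b in enumerate(bcands):
                totals[j] += telomere_count_breakpoint(c, c_prime, b, o)
        j_best = int(np.argmin(totals))
        out.append(PosthocAssignment(
            breakpoint_id=bp_id,
            copies=bcands[j_best].copy(),
            telomeres_before=int(totals[0]),
            telomeres_after=int(totals[j_best]),
        ))
    return out


def fit_naive(
    segments: pd.DataFrame,
    breakpoints: Union[pd.DataFrame, Sequence[Breakpoint], None] = None,
    config: Optional[FitConfig] = None,
) -> MixtureResult:
    """Fit the breakpoint-naive model: identical pipeline with breakpoint
    copy number clamped at zero, then greedy post-hoc breakpoint copies."""
    config = config or FitConfig()
    naive_config = replace(config, b_max=0)
    result = fit(segments, breakpoints, naive_config, _mode="naive")

    # post-hoc breakpoint copy number from the fixed segment copies
    model = ChainModel(segments, breakpoints, naive_config)
    assignments = greedy_breakpoint_copies(
        result.cn_array(), model, b_max=config.b_max)
    rows = [
        {"breakpoint_id": a.breakpoint_id,
         **{f"cn_{m + 1}": int(a.copies[m]) for m in range(len(a.copies))}}
        for a in assignments
    ]
    cols = ["breakpoint_id"] + [
        f"cn_{m + 1}" for m in range(config.n_tumour_clones)]
    result.breakpoint_cn = pd.DataFrame(rows, columns=cols)
    return result
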