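"""Accuracy metrics against simulated truth and breakpoint-based
clone-tracking / chromosome-assembly utilities.

Segment accuracy is the length-weighted proportion of segments whose
clone-specific (major, minor) copy numbers are recovered for every tumour
clone, maximised over tumour clone label permutations (clone labels are
inherently ambiguous).  Breakpoint accuracy is the proportion of true
breakpoints with an exact per-clone copy match under the same permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import FitConfig, MixtureResult, fit
from .baseline import fit_naive
from .simulate import Scenario, SimulatedTruth, simulate

__all__ = [
    "EvalReport", "score", "breakpoint_prevalence",
    "classify_clonal_dynamics", "select_confident_subclonal",
    "ChromosomeWalk", "assemble_chromosome", "run_comparison",
]


@dataclass
class EvalReport:
    """Accuracy of one fit against simulated truth.

    ``*_error`` fields are relative deviations ``|est - sim| / sim``;
    absolute counterparts are included for the mixture fractions since small
    simulated fractions make relative errors unstable.
    """

    segment_accuracy: float
    breakpoint_accuracy: float
    normal_fraction_error: float
    minor_fraction_error: float
    ploidy_error: float
    divergent_error: float
    normal_fraction_abs_error: float
    minor_fraction_abs_error: float
    permutation: tuple

    def to_dict(self) -> dict:
        d = asdict(self)
        d["permutation"] = list(self.permutation)
        return d


def _folded(cn: np.ndarray) -> np.ndarray:
    """Sort each clone's allele pair to (major, minor)."""
    return np.sort(cn, axis=-1)[..., ::-1]


def _rel(est: float, sim: float) -> float:
    if sim == 0:
        return float(abs(est - sim))
    return float(abs(est - sim) / abs(sim))


def score(result: MixtureResult, truth: SimulatedTruth) -> EvalReport:
    """Score a fit against the simulated truth (same segmentation)."""
    seg = result.segment_cn
    if (len(seg) != len(truth.segments)
            or not np.array_equal(seg["start"].to_numpy(),
                                  truth.segments["start"].to_numpy())
            or not np.array_equal(seg["chromosome"].astype(str).to_numpy(),
                                  truth.segments["chromosome"].astype(str).to_numpy())):
        raise ValueError("result and truth segmentations differ")

    lengths = truth.segments["length"].to_numpy(dtype=float)
    est_cn = _folded(result.cn_array())          # (N, M_t, 2)
    true_cn = _folded(truth.cn)
    n_t = est_cn.shape[1]

    best_acc, best_perm = -1.0, tuple(range(n_t))
    for perm in permutations(range(n_t)):
        match = np.all(est_cn[:, perm, :] == true_cn, axis=(1, 2))
        acc = float(lengths[match].sum() / lengths.sum())
        if acc > best_acc:
            best_acc, best_perm = acc, perm

    # breakpoint accuracy under the same label permutation
    true_bp = truth.breakpoints
    est_bp = result.breakpoint_cn.set_index("breakpoint_id")
    n_correct = 0
    for row in true_bp.itertuples(index=False):
        truth_b = np.array([row.true_cn_1, row.true_cn_2][:n_t])
        if row.breakpoint_id in est_bp.index:
            est_b = np.array([est_bp.loc[row.breakpoint_id, f"cn_{m + 1}"]
                              for m in range(n_t)])
        else:
            est_b = np.zeros(n_t, dtype=int)
        if np.array_equal(est_b[list(best_perm)], truth_b):
            n_correct += 1
    bp_acc = n_correct / len(true_bp) if len(true_bp) else np.nan

    frac_sim = truth.clone_fractions()
    rho = np.asarray(result.rho)
    est_norm, sim_norm = float(rho[0]), float(frac_sim[0])
    est_minor = float(np.min(rho[1:]))
    sim_minor = float(np.min(frac_sim[1:]))

    tumour_w = rho[1:] / rho[1:].sum() if rho[1:].sum() > 0 else rho[1:]
    per_clone = (lengths[:, None] * est_cn.sum(axis=2)).sum(axis=0) / lengths.sum()
    est_ploidy = float(per_clone @ tumour_w)
    est_div = float(
        lengths[np.any(est_cn[:, 0, :] != est_cn[:, 1, :], axis=1)].sum()
        / lengths.sum()) if n_t > 1 else 0.0

    return EvalReport(
        segment_accuracy=best_acc,
        breakpoint_accuracy=bp_acc,
        normal_fraction_error=_rel(est_norm, sim_norm),
        minor_fraction_error=_rel(est_minor, sim_minor),
        ploidy_error=_rel(est_ploidy, truth.ploidy()),
        divergent_error=_rel(est_div, truth.divergent_proportion()),
        normal_fraction_abs_error=abs(est_norm - sim_norm),
        minor_fraction_abs_error=abs(est_minor - sim_minor),
        permutation=best_perm,
    )


# -- clone tracking ---------------------------------------------------------


def breakpoint_prevalence(result: MixtureResult) -> dict:
    """Clonal prevalence of each breakpoint: the tumour fraction carrying
    it, ``sum_{m: b_km > 0} rho_m / sum_tumour rho_m``."""
    rho = np.asarray(result.rho)
    tumour_rho = rho[1:]
    denom = tumour_rho.sum()
    out = {}
    b = result.breakpoint_cn_array()
    for j, bp_id in enumerate(result.breakpoint_cn["breakpoint_id"]):
        carried = tumour_rho[b[j] > 0].sum()
        out[str(bp_id)] = float(carried / denom) if denom > 0 else 0.0
    return out


def classify_clonal_dynamics(result_s1: MixtureResult,
                             result_s2a: MixtureResult,
                             result_s2b: MixtureResult,
                             tol: float = 1e-6) -> pd.DataFrame:
    """Classify breakpoints by clonal prevalence change from a first sample
    to two replicate later samples.

    ``ascending``: prevalence rises into both replicates; ``descending``:
    falls in both; ``stable``: unchanged (within ``tol``) in at least one;
    ``conflicting`` otherwise.  Breakpoints missing from a sample count as
    prevalence 0.
    """
    prev = [breakpoint_prevalence(r)
            for r in (result_s1, result_s2a, result_s2b)]
    ids = sorted(set().union(*[set(p) for p in prev]))
    rows = []
    for bp_id in ids:
        p1, p2a, p2b = (p.get(bp_id, 0.0) for p in prev)
        da, db = p2a - p1, p2b - p1
        if da > tol and db > tol:
            label = "ascending"
        elif da < -tol and db < -tol:
            label = "descending"
        elif abs(da) <= tol or abs(db) <= tol:
            label = "stable"
        else:
            label = "conflicting"
        rows.append({"breakpoint_id": bp_id, "prevalence_1": p1,
                     "prevalence_2a": p2a, "prevalence_2b": p2b,
                     "label": label})
    return pd.DataFrame(rows)


# -- confident subclonal breakpoints and chromosome assembly ---------------


def _subclonal_mask(result: MixtureResult) -> np.ndarray:
    b = result.breakpoint_cn_array()
    differ = np.max(b, axis=1) != np.min(b, axis=1)
    return differ & (b.max(axis=1) > 0)


def select_confident_subclonal(
    result: MixtureResult,
    breakpoints: pd.DataFrame,
    min_length: int = 1_000_000,
    smooth_length: int = 100_000,
    max_copy: int = 4,
):
    """High-confidence subclonal breakpoints.

    Segments shorter than ``smooth_length`` are dropped; remaining adjacent
    segments with identical inter-clone allele copy difference are merged;
    merged segments shorter than ``min_length``, with total copy above
    ``max_copy`` or without clonal divergence are discarded.  A breakpoint
    is kept if it is predicted subclonal and both breakends adjoin a kept
    segment.  Returns ``(kept_breakpoints, kept_segments)``.
    """
    seg = result.segment_cn.reset_index(drop=True)
    cn = result.cn_array()
    keep = seg["length"].to_numpy() >= smooth_length
    diff = cn[:, 0, :] - cn[:, -1, :]
    maxcopy = cn.sum(axis=2).max(axis=1)

    merged = []
    current = None
    for i in np.flatnonzero(keep):
        row = seg.iloc[i]
        key = (row["chromosome"], tuple(diff[i]))
        if current is not None and current["key"] == key:
            current["end"] = int(row["end"])
            current["length"] += int(row["length"])
            current["max_copy"] = max(current["max_copy"], int(maxcopy[i]))
            current["end_index"] = i
        else:
            if current is not None:
                merged.append(current)
            current = {"chromosome": row["chromosome"],
                       "start": int(row["start"]), "end": int(row["end"]),
                       "length": int(row["length"]),
                       "diff": tuple(int(v) for v in diff[i]),
                       "max_copy": int(maxcopy[i]),
                       "key": key, "end_index": i}
    if current is not None:
        merged.append(current)
    kept_seg = pd.DataFrame([
        {k: v for k, v in m.items() if k not in ("key", "end_index")}
        for m in merged
        if m["length"] >= min_length and m["max_copy"] <= max_copy
        and any(v != 0 for v in m["diff"])
    ])

    def adjoins(chrom, pos) -> bool:
        if kept_seg.empty:
            return False
        sel = ((kept_seg["chromosome"].astype(str) == str(chrom))
               & (kept_seg["start"] <= pos) & (pos <= kept_seg["end"]))
        return bool(sel.any())

    sub = _subclonal_mask(result)
    sub_ids = set(result.breakpoint_cn.loc[sub, "breakpoint_id"].astype(str))
    rows = []
    for row in breakpoints.itertuples(index=False):
        if str(row.breakpoint_id) not in sub_ids:
            continue
        if adjoins(row.chrom_1, row.position_1) and \
                adjoins(row.chrom_2, row.position_2):
            rows.append(row._asdict())
    kept_bp = pd.DataFrame(rows, columns=list(breakpoints.columns))
    return kept_bp, kept_seg


@dataclass
class ChromosomeWalk:
    """A greedy walk through clonally divergent segments linked by
    subclonal breakpoints; ``steps`` are (segment index, orientation)."""

    steps: list
    cycle: bool = False


def assemble_chromosome(result: MixtureResult, breakpoints: pd.DataFrame,
                        seed_segment: int) -> ChromosomeWalk:
    """Greedy assembly of a partial tumour chromosome.

    Starting from a clonally divergent seed segment, the walk repeatedly
    exits the current segment end, follows the first (by table order)
    subclonal breakpoint with a breakend at that end, and enters the
    divergent segment adjoining the partner breakend.  It terminates at a
    segment with no qualifying outgoing breakend, and flags (and stops at)
    the first revisit of a segment.
    """
    seg = result.segment_cn.reset_index(drop=True)
    cn = result.cn_array()
    divergent = np.any(cn[:, 0, :] != cn[:, -1, :], axis=1)
    if not divergent[seed_segment]:
        raise ValueError("seed segment is not clonally divergent")

    sub = _subclonal_mask(result)
    sub_ids = set(result.breakpoint_cn.loc[sub, "breakpoint_id"].astype(str))
    bp_rows = [row for row in breakpoints.itertuples(index=False)
               if str(row.breakpoint_id) in sub_ids]

    starts = {}
    ends = {}
    for i, row in seg.iterrows():
        starts[(str(row["chromosome"]), int(row["start"]))] = i
        ends[(str(row["chromosome"]), int(row["end"]))] = i

    _o = {"+": 1, "-": -1, 1: 1, -1: -1}

    def breakend_at(chrom, pos, orient):
        """Segment adjoining a breakend and the end it attaches to."""
        if orient > 0:
            return ends.get((str(chrom), int(pos))), +1  # right end
        return starts.get((str(chrom), int(pos))), -1    # left end

    steps = [(seed_segment, +1)]
    visited = {seed_segment}
    current, direction = seed_segment, +1
    while True:
        exit_end = +1 if direction > 0 else -1  # +1: right end, -1: left end
        row = seg.iloc[current]
        if exit_end > 0:
            key = (str(row["chromosome"]), int(row["end"]), 1)
        else:
            key = (str(row["chromosome"]), int(row["start"]), -1)
        nxt = None
        for bp in bp_rows:
            for be, partner in (
                ((bp.chrom_1, bp.position_1, _o[bp.orientation_1]),
                 (bp.chrom_2, bp.position_2, _o[bp.orientation_2])),
                ((bp.chrom_2, bp.position_2, _o[bp.orientation_2]),
                 (bp.chrom_1, bp.position_1, _o[bp.orientation_1])),
            ):
                if (str(be[0]), int(be[1]), be[2]) != key:
                    continue
                nseg, attach = breakend_at(*partner)
                if nseg is None or not divergent[nseg]:
                    continue
                nxt = (nseg, +1 if attach < 0 else -1)
                break
            if nxt is not None:
                break
        if nxt is None:
            return ChromosomeWalk(steps=steps, cycle=False)
        if nxt[0] in visited:
            return ChromosomeWalk(steps=steps, cycle=True)
        steps.append(nxt)
        visited.add(nxt[0])
        current, direction = nxt


# -- experiment driver ------------------------------------------------------


def run_comparison(scenario: Scenario,
                   config: Optional[FitConfig] = None,
                   n_replicates: int = 20,
                   seed: int = 0,
                   methods: Sequence[str] = ("breakpoint", "naive"),
                   normal_fractions: Optional[Sequence[float]] = None,
                   ) -> pd.DataFrame:
    """Replicated simulation experiment.

    For each replicate a history and counts are simulated (replicate
    ``i`` optionally cycling through ``normal_fractions``), each requested
    method is fitted, and its :class:`EvalReport` recorded, along with the
    number of truly subclonal breakpoints in the replicate.
    """
    config = config or FitConfig()
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for i in range(n_replicates):
        scen = Scenario.from_dict(scenario.to_dict())
        if normal_fractions is not None:
            scen.normal_fraction = normal_fractions[i % len(normal_fractions)]
        rep_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        scen.seed = rep_seed
        truth, seg, bp = simulate(scen)
        n_subclonal = int((truth.breakpoint_cn_array()[:, 0]
                           != truth.breakpoint_cn_array()[:, 1]).sum())
        for method in methods:
            fitter = fit if method == "breakpoint" else fit_naive
            result = fitter(seg, bp, config)
            report = score(result, truth)
            rows.append({"replicate": i, "seed": rep_seed, "method": method,
                         "n_subclonal_true": n_subclonal,
                         "descendant_fraction": scen.descendant_fraction,
                         "normal_fraction": scen.normal_fraction,
                         **report.to_dict()})
    return pd.DataFrame(rows)
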