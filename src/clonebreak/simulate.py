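"""Ground-truthed tumour genome simulation.

Two-clone tumour histories are generated on a fixed segment grid by
applying duplication, deletion and balanced rearrangement events to an
initially diploid genome.  Events on the ancestral branch are shared by
both tumour clones; events on the descendant branch are private to the
descendant clone, so the descendant clone fraction and the proportion of
the genome with divergent copy number are controlled.  Histories are drawn
by a scoring and re-sampling strategy: many candidate histories are
proposed and the one whose realised (ploidy, divergent proportion) is
closest to the targets (squared error) is kept.

Read counts are then simulated directly from the likelihood model given the
simulated copy numbers (segment-count simulation).  Unbalanced events
always produce both a breakpoint and a copy change; balanced events produce
breakpoints with no copy change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .likelihood import LikelihoodParams
from .segments import (
    BREAKPOINT_COLUMNS,
    Breakend,
    Breakpoint,
    breakpoints_to_table,
    partition_genome,
)

__all__ = [
    "Scenario", "RearrangementEvent", "SimulatedTruth",
    "sample_history", "replay_events", "simulate_counts", "simulate",
]


@dataclass
class Scenario:
    """Simulation conditions.

    ``depth`` is the expected read depth (reads per nucleotide) of a fully
    diploid mixture; per-clone haploid depths are ``depth * f_m / 2`` for
    cellular fractions ``f_m``.  ``descendant_fraction`` is the descendant
    clone's share of the *tumour* cells; the ancestral/descendant labelling
    is by lineage, not by size, so a fraction x and 1 - x are distinct
    conditions.  ``event_size_mean`` is the mean rearrangement extent in
    segments.  ``target_ploidy`` and ``target_divergent`` steer the
    score-and-resample history search (``n_resample`` proposals).
    """

    n_chromosomes: int = 10
    chromosome_length: int = 50_000_000
    bin_size: int = 500_000
    n_events: int = 30
    balanced_fraction: float = 0.2
    event_size_mean: float = 20.0
    target_ploidy: float = 2.3
    target_divergent: float = 0.3
    normal_fraction: float = 0.5
    descendant_fraction: float = 0.25
    depth: float = 0.02
    allele_rate: float = 0.25
    n_resample: int = 100
    false_positive_rate: float = 0.0
    likelihood: LikelihoodParams = field(
        default_factory=lambda: LikelihoodParams(outlier_weight=0.0))
    seed: int = 0

    def clone_fractions(self) -> np.ndarray:
        """Cellular fractions (normal, ancestral, descendant)."""
        fn, fd = self.normal_fraction, self.descendant_fraction
        return np.array([fn, (1 - fn) * (1 - fd), (1 - fn) * fd])

    def haploid_depths(self) -> np.ndarray:
        return self.depth * self.clone_fractions() / 2.0

    def chrom_lengths(self) -> dict:
        return {str(i + 1): self.chromosome_length
                for i in range(self.n_chromosomes)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["likelihood"] = self.likelihood.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if "likelihood" in d and isinstance(d["likelihood"], dict):
            d["likelihood"] = LikelihoodParams.from_dict(d["likelihood"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class RearrangementEvent:
    """One event of the evolutionary history.

    For duplications/deletions ``start_segment``/``end_segment`` index the
    affected global segment range (half-open) on one allele; balanced events
    carry only breakends.  ``lineage`` is ``ancestral`` (shared by both
    tumour clones) or ``descendant``.
    """

    kind: str
    lineage: str
    allele: int = 0
    start_segment: int = 0
    end_segment: int = 0
    breakend_1: tuple = ()
    breakend_2: tuple = ()


@dataclass
class SimulatedTruth:
    """Ground truth emitted by the simulator."""

    segments: pd.DataFrame
    cn: np.ndarray  # (N, 2 tumour clones, 2 alleles)
    breakpoints: pd.DataFrame  # breakpoint table + true_cn_1, true_cn_2
    events: list
    scenario: Scenario

    @property
    def normal_fraction(self) -> float:
        return self.scenario.normal_fraction

    @property
    def descendant_fraction(self) -> float:
        return self.scenario.descendant_fraction

    def clone_fractions(self) -> np.ndarray:
        return self.scenario.clone_fractions()

    def ploidy(self) -> float:
        """Tumour-mixture-weighted mean copy number per haploid genome / 2
        ... reported as mean total copy over the tumour mixture."""
        lengths = self.segments["length"].to_numpy(dtype=float)
        totals = self.cn.sum(axis=2)  # (N, 2)
        fd = self.scenario.descendant_fraction
        w = np.array([1 - fd, fd])
        per_clone = (lengths[:, None] * totals).sum(axis=0) / lengths.sum()
        return float(per_clone @ w)

    def divergent_proportion(self) -> float:
        lengths = self.segments["length"].to_numpy(dtype=float)
        differ = np.any(self.cn[:, 0, :] != self.cn[:, 1, :], axis=1)
        return float(lengths[differ].sum() / lengths.sum())

    def breakpoint_cn_array(self) -> np.ndarray:
        return self.breakpoints[["true_cn_1", "true_cn_2"]].to_numpy()


def _segment_grid(scenario: Scenario) -> pd.DataFrame:
    seg = partition_genome(scenario.chrom_lengths(), (), scenario.bin_size)
    return seg[["chromosome", "start", "end", "length"]].copy()


def replay_events(events: Sequence[RearrangementEvent],
                  n_segments: int) -> np.ndarray:
    """Deterministically replay an event history into (N, 2, 2) tumour
    clone allele copy numbers, starting from a diploid genome."""
    cn = np.ones((n_segments, 2, 2), dtype=np.int64)
    for ev in events:
        if ev.kind == "balanced":
            continue
        clones = [0, 1] if ev.lineage == "ancestral" else [1]
        delta = 1 if ev.kind == "duplication" else -1
        sl = slice(ev.start_segment, ev.end_segment)
        for m in clones:
            cn[sl, m, ev.allele] += delta
    if np.any(cn < 0):
        raise ValueError("event history deletes below zero copies")
    return cn


def _propose_history(scenario: Scenario, seg: pd.DataFrame,
                     rng: np.random.Generator):
    chroms = seg["chromosome"].to_numpy()
    starts = seg["start"].to_numpy()
    ends = seg["end"].to_numpy()
    chrom_names = list(dict.fromkeys(chroms))
    chrom_range = {c: (int(np.argmax(chroms == c)),
                       int(np.argmax(chroms == c) + (chroms == c).sum()))
                   for c in chrom_names}
    # interior boundary keys available for breakends
    used: set = set()
    cn = np.ones((len(seg), 2, 2), dtype=np.int64)
    events: list[RearrangementEvent] = []

    def boundary_ok(chrom, pos):
        lo, hi = chrom_range[chrom]
        return starts[lo] < pos < ends[hi - 1] and (chrom, pos) not in used

    for _ in range(scenario.n_events):
        balanced = rng.random() < scenario.balanced_fraction
        lineage = "ancestral" if rng.random() < 0.5 else "descendant"
        clones = [0, 1] if lineage == "ancestral" else [1]
        placed = False
        for _attempt in range(40):
            if balanced:
                cands = []
                for _ in range(2):
                    chrom = chrom_names[rng.integers(len(chrom_names))]
                    lo, hi = chrom_range[chrom]
                    if hi - lo < 2:
                        break
                    j = int(rng.integers(lo, hi - 1))
                    cands.append((chrom, int(ends[j]),
                                  int(rng.choice([-1, 1]))))
                if len(cands) < 2:
                    continue
                keys = {(c, p) for c, p, _ in cands}
                if len(keys) < 2 or any(k in used for k in keys):
                    continue
                events.append(RearrangementEvent(
                    kind="balanced", lineage=lineage,
                    breakend_1=cands[0], breakend_2=cands[1]))
                used.update(keys)
                placed = True
                break
            kind = "duplication" if rng.random() < 0.5 else "deletion"
            chrom = chrom_names[rng.integers(len(chrom_names))]
            lo, hi = chrom_range[chrom]
            n_c = hi - lo
            if n_c < 3:
                continue
            size = int(min(rng.geometric(1.0 / scenario.event_size_mean),
                           n_c - 2))
            s = int(rng.integers(lo + 1, hi - size))  # keep breakends interior
            e = s + size
            allele = int(rng.integers(2))
            if kind == "deletion":
                if np.any(cn[s:e][:, clones, allele] < 1):
                    continue
            left, right = (int(starts[s]), int(ends[e - 1]))
            if (chrom, left) in used or (chrom, right) in used:
                continue
            delta = 1 if kind == "duplication" else -1
            for m in clones:
                cn[s:e, m, allele] += delta
            if kind == "deletion":
                be1 = (chrom, left, 1)
                be2 = (chrom, right, -1)
            else:
                be1 = (chrom, left, -1)
                be2 = (chrom, right, 1)
            events.append(RearrangementEvent(
                kind=kind, lineage=lineage, allele=allele,
                start_segment=s, end_segment=e,
                breakend_1=be1, breakend_2=be2))
            used.update([(chrom, left), (chrom, right)])
            placed = True
            break
        if not placed:
            continue
    return events, cn


def _history_score(scenario: Scenario, seg: pd.DataFrame,
                   cn: np.ndarray) -> float:
    lengths = seg["length"].to_numpy(dtype=float)
    fd = scenario.descendant_fraction
    per_clone = (lengths[:, None] * cn.sum(axis=2)).sum(axis=0) / lengths.sum()
    ploidy = float(per_clone @ np.array([1 - fd, fd]))
    differ = np.any(cn[:, 0, :] != cn[:, 1, :], axis=1)
    divergent = float(lengths[differ].sum() / lengths.sum())
    return ((ploidy - scenario.target_ploidy) ** 2
            + (divergent - scenario.target_divergent) ** 2)


def _truth_breakpoints(events: Sequence[RearrangementEvent]) -> pd.DataFrame:
    bps, cn1, cn2 = [], [], []
    for idx, ev in enumerate(events):
        if not ev.breakend_1:
            continue
        c1, p1, o1 = ev.breakend_1
        c2, p2, o2 = ev.breakend_2
        bps.append(Breakpoint(
            id=f"bp_{idx:04d}",
            breakend_1=Breakend(c1, p1, o1),
            breakend_2=Breakend(c2, p2, o2)))
        carried = (1, 1) if ev.lineage == "ancestral" else (0, 1)
        cn1.append(carried[0])
        cn2.append(carried[1])
    table = breakpoints_to_table(bps)
    table["true_cn_1"] = cn1
    table["true_cn_2"] = cn2
    return table


def sample_history(scenario: Optional[Scenario] = None,
                   seed: Optional[int] = None) -> SimulatedTruth:
    """Draw a two-clone evolutionary history by scoring and re-sampling.

    ``n_resample`` candidate histories are proposed; the one with the
    smallest squared distance of realised (ploidy, divergent proportion)
    from the scenario targets is kept.  Fully deterministic given the seed.
    """
    scenario = scenario or Scenario()
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    seg = _segment_grid(scenario)

    best = None
    best_score = np.inf
    for _ in range(max(scenario.n_resample, 1)):
        events, cn = _propose_history(scenario, seg, rng)
        score = _history_score(scenario, seg, cn)
        if score < best_score:
            best_score = score
            best = (events, cn)
    events, cn = best
    truth = SimulatedTruth(
        segments=seg, cn=cn, breakpoints=_truth_breakpoints(events),
        events=events, scenario=scenario)
    tol = 0.1
    if (abs(truth.ploidy() - scenario.target_ploidy) > 3 * tol
            or abs(truth.divergent_proportion()
                   - scenario.target_divergent) > 3 * tol):
        import warnings
        warnings.warn(
            "re-sampling could not reach the target ploidy/divergent "
            "proportion; returning best-scoring history", RuntimeWarning,
            stacklevel=2)
    return truth


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 params: LikelihoodParams) -> np.ndarray:
    if params.family == "poisson":
        return rng.poisson(mu)

    def nb(mu_, r):
        p = r / (r + np.maximum(mu_, 1e-12))
        return rng.negative_binomial(r, p)

    if params.family == "negbin":
        x = nb(mu, params.inverse_dispersions[0])
    else:
        r1, r2 = params.inverse_dispersions[:2]
        comp = rng.random(len(mu)) < params.mixture_weight
        x = np.where(comp, nb(mu, r2), nb(mu, r1))
    return np.where(mu > 0, x, 0)


def simulate_counts(truth: SimulatedTruth,
                    seed: Optional[int] = None) -> tuple:
    """Simulate the observed segment and breakpoint tables from a truth.

    Total counts are drawn from the scenario's likelihood family at the
    expected count ``l_n * sum_m h_m c_nm``; allele-informative reads are a
    binomial thinning of the total, split between alleles by the (optionally
    beta-overdispersed) expected allele fraction.  Returns
    ``(segments, breakpoints)`` data frames in the model's input format.
    """
    scenario = truth.scenario
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    params = scenario.likelihood
    h = scenario.haploid_depths()
    lengths = truth.segments["length"].to_numpy(dtype=float)

    totals = truth.cn.sum(axis=2)  # (N, 2)
    denom = h[0] * 2.0 + totals @ h[1:]
    mu = lengths * denom
    x = _draw_counts(rng, mu, params)

    num = h[0] * 1.0 + truth.cn[:, :, 0] @ h[1:]
    p_a = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.5)
    n_allele = rng.binomial(x, scenario.allele_rate)
    nu = params.allele_overdispersion
    if nu > 0:
        s = 1.0 / nu
        p_draw = rng.beta(np.clip(p_a * s, 1e-9, None),
                          np.clip((1 - p_a) * s, 1e-9, None))
    else:
        p_draw = p_a
    x_a = rng.binomial(n_allele, p_draw)
    x_b = n_allele - x_a

    seg = truth.segments.copy()
    seg["effective_length"] = lengths
    seg["readcount"] = x
    seg["allele_a_readcount"] = x_a
    seg["allele_b_readcount"] = x_b

    bp = truth.breakpoints[BREAKPOINT_COLUMNS].copy()
    if scenario.false_positive_rate > 0:
        n_fp = rng.poisson(scenario.false_positive_rate * max(len(bp), 1))
        starts = truth.segments["start"].to_numpy()
        ends = truth.segments["end"].to_numpy()
        chroms = truth.segments["chromosome"].to_numpy()
        taken = set()
        for t in truth.breakpoints.itertuples(index=False):
            taken.add((t.chrom_1, t.position_1))
            taken.add((t.chrom_2, t.position_2))
        rows = []
        for j in range(n_fp):
            cands = []
            for _ in range(2):
                for _try in range(50):
                    i = int(rng.integers(len(starts) - 1))
                    if chroms[i] != chroms[i + 1]:
                        continue
                    key = (chroms[i], int(ends[i]))
                    if key in taken:
                        continue
                    taken.add(key)
                    cands.append((key[0], key[1], int(rng.choice([-1, 1]))))
                    break
            if len(cands) == 2:
                rows.append({
                    "breakpoint_id": f"fp_{j:04d}",
                    "chrom_1": cands[0][0], "position_1": cands[0][1],
                    "orientation_1": "+" if cands[0][2] > 0 else "-",
                    "chrom_2": cands[1][0], "position_2": cands[1][1],
                    "orientation_2": "+" if cands[1][2] > 0 else "-",
                })
        if rows:
            bp = pd.concat([bp, pd.DataFrame(rows)], ignore_index=True)
    return seg, bp


def simulate(scenario: Optional[Scenario] = None,
             seed: Optional[int] = None):
    """Convenience wrapper: sample a history and simulate counts.

    Returns ``(truth, segments, breakpoints)``.  The history and the counts
    use decorrelated child seeds of ``seed``.
    """
    scenario = scenario or Scenario()
    if seed is None:
        seed = scenario.seed
    ss = np.random.SeedSequence(seed).spawn(2)
    truth = sample_history(scenario, seed=int(ss[0].generate_state(1)[0] % (2**31)))
    seg, bp = simulate_counts(truth, seed=int(ss[1].generate_state(1)[0] % (2**31)))
    return truth, seg, bp
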