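"""Copy-number state space and telomere-count transition factors.

Adjacent genomic segments are coupled through *telomere counts*: the number
of segment extremities left unconnected to another segment end by a proposed
configuration of segment and breakpoint copy numbers.  Without an interposed
breakpoint the count for one clone is ``|c - c'|``; a breakend of
orientation ``o`` with breakpoint copy number ``b`` can absorb part of the
difference, giving ``|c - c' - o * b|``.  Transition factors are the
un-normalised potentials ``exp(-lambda * t)``.

The normal clone is fixed at one copy of each allele throughout and hence
never contributes to a telomere count; only tumour-clone states are
enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "AdjacencyInfo",
    "StateSpace",
    "telomere_count_plain",
    "telomere_count_breakpoint",
    "transition_factor",
]


@dataclass(frozen=True)
class AdjacencyInfo:
    """Description of the boundary between two consecutive segments.

    ``breakpoint_index`` is ``None`` for a plain reference adjacency.
    ``orientation`` is the breakend orientation (+1/-1) at this boundary and
    ``side`` records which breakend (0 or 1) of the breakpoint attaches here.
    """

    breakpoint_index: Optional[int] = None
    orientation: int = 0
    side: int = 0


def _clone_allele_states(max_total: int) -> np.ndarray:
    """Enumerate (major, minor) allele copy pairs with major >= minor and
    major + minor <= max_total, ordered by (total, minor)."""
    states = []
    for total in range(max_total + 1):
        for minor in range(total // 2 + 1):
            states.append((total - minor, minor))
    return np.array(states, dtype=np.int64)


class StateSpace:
    """Joint copy-number state space over tumour clones.

    Parameters
    ----------
    n_tumour:
        Number of tumour clones (1 or 2).
    max_total:
        Maximum total (major + minor) copy number per clone.
    b_max:
        Maximum breakpoint copy number per clone.

    States are ordered by (summed total copies, per-clone totals, minors) so
    that ``argmax`` over equal posterior mass resolves toward lower total
    copy number, then lower clone index.
    """

    def __init__(self, n_tumour: int = 2, max_total: int = 5, b_max: int = 2):
        if n_tumour not in (1, 2):
            raise ValueError("n_tumour must be 1 or 2")
        self.n_tumour = n_tumour
        self.max_total = max_total
        self.b_max = b_max

        clone_states = _clone_allele_states(max_total)
        if n_tumour == 1:
            joint = clone_states[:, None, :]
        else:
            a = np.repeat(clone_states, len(clone_states), axis=0)
            b = np.tile(clone_states, (len(clone_states), 1))
            joint = np.stack([a, b], axis=1)

        # tie-break ordering: total copies ascending, then clone totals,
        # then minors (stable sort keeps a deterministic enumeration)
        totals = joint.sum(axis=2)
        key = np.concatenate(
            [totals.sum(axis=1, keepdims=True), totals, joint[:, :, 1]], axis=1
        )
        order = np.lexsort(key.T[::-1])
        self.states = joint[order]  # (S, n_tumour, 2) as (major, minor)
        self.majors = self.states[:, :, 0]
        self.minors = self.states[:, :, 1]
        self.totals = self.states.sum(axis=2)  # (S, n_tumour)
        self.n_states = len(self.states)

        # breakpoint states: per-clone copy vectors, ordered with b = 0
        # first then ascending by (sum, lexicographic)
        grids = np.meshgrid(*([np.arange(b_max + 1)] * n_tumour), indexing="ij")
        bstates = np.stack([g.ravel() for g in grids], axis=1)
        border = np.lexsort(
            np.concatenate(
                [bstates[:, ::-1].T, bstates.sum(axis=1)[None, :]], axis=0
            )
        )
        self.breakpoint_states = bstates[border]  # (B, n_tumour)
        self.n_breakpoint_states = len(self.breakpoint_states)

        self._plain_t: Optional[np.ndarray] = None
        self._bp_t: dict[int, np.ndarray] = {}

    # -- telomere count matrices -------------------------------------------

    def plain_telomere_matrix(self) -> np.ndarray:
        """(S, S) matrix of telomere counts for reference adjacencies."""
        if self._plain_t is None:
            d_major = np.abs(self.majors[:, None, :] - self.majors[None, :, :])
            d_minor = np.abs(self.minors[:, None, :] - self.minors[None, :, :])
            self._plain_t = (d_major + d_minor).sum(axis=2)
        return self._plain_t

    def breakpoint_telomere_matrices(self, orientation: int) -> np.ndarray:
        """(B, S, S) telomere counts for a breakend of given orientation.

        The breakpoint's allele phase is unobserved: each candidate allele
        track (major or minor) is scored and the minimum-telomere track used.
        """
        if orientation not in (-1, 1):
            raise ValueError("orientation must be -1 or +1")
        if orientation not in self._bp_t:
            d_major = self.majors[:, None, :] - self.majors[None, :, :]
            d_minor = self.minors[:, None, :] - self.minors[None, :, :]
            ob = orientation * self.breakpoint_states  # (B, n_tumour)
            ob = ob[:, None, None, :]
            on_major = (
                np.abs(d_major[None] - ob) + np.abs(d_minor)[None]
            ).sum(axis=3)
            on_minor = (
                np.abs(d_minor[None] - ob) + np.abs(d_major)[None]
            ).sum(axis=3)
            self._bp_t = {**self._bp_t, orientation: np.minimum(on_major, on_minor)}
        return self._bp_t[orientation]


def _as_state(c) -> np.ndarray:
    c = np.asarray(c, dtype=np.int64)
    if c.ndim == 1:
        c = c[None, :]
    return c


def telomere_count_plain(c, c_prime) -> int:
    """Telomere count without an interposed breakpoint.

    ``c`` and ``c_prime`` are per-clone per-allele copy numbers of shape
    (n_clones, 2) (a length-2 vector is treated as one clone).  The count is
    the summed absolute allele copy difference over clones.
    """
    c, c_prime = _as_state(c), _as_state(c_prime)
    return int(np.abs(c - c_prime).sum())


def telomere_count_breakpoint(c, c_prime, b, orientation: int) -> int:
    """Telomere count with a breakend of ``orientation`` and per-clone
    breakpoint copy numbers ``b`` interposed.

    The breakpoint absorbs copy-number change on whichever allele track
    yields the fewer telomeres; the other track contributes plain
    differences.
    """
    if orientation not in (-1, 1):
        raise ValueError("orientation must be -1 or +1")
    c, c_prime = _as_state(c), _as_state(c_prime)
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    diff = c - c_prime  # (n_clones, 2)
    on_track0 = np.abs(diff[:, 0] - orientation * b).sum() + np.abs(diff[:, 1]).sum()
    on_track1 = np.abs(diff[:, 1] - orientation * b).sum() + np.abs(diff[:, 0]).sum()
    return int(min(on_track0, on_track1))


def transition_factor(
    c, c_prime, adjacency: AdjacencyInfo, b=None, lam: float = 1.0
) -> float:
    """Un-normalised transition potential ``exp(-lambda * t)``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if adjacency.breakpoint_index is None or b is None:
        t = telomere_count_plain(c, c_prime)
    else:
        t = telomere_count_breakpoint(c, c_prime, b, adjacency.orientation)
    return float(np.exp(-lam * t))
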