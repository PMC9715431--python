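"""Recombination-rate estimation from F2 intercross ancestry panels.

Each F2 carries two recombinant gametes from F1 parents, so crossovers are
read off as ancestry state changes along ordered markers: AB boundaries
count one crossover, a direct AA<->BB transition counts two (one per
gamete). Single-marker state switches are treated as genotyping error and
removed before counting. Map length in cM is 100 x crossovers / (2 x n_F2)
(two meioses per F2); dividing by interval length in Mb gives cM/Mb.
Within an inversion, only F2s whose F1 parents are inversion heterozygotes
are informative for the recombination-suppression contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import GenomicInterval

# ancestry codes
AA, AB, BB = 0, 1, 2
MISSING_STATE = -1
_STATE_STR = {AA: "AA", AB: "AB", BB: "BB", MISSING_STATE: "NA"}
_STR_STATE = {v: k for k, v in _STATE_STR.items()}


@dataclass
class CrossPanel:
    """Ancestry states of F2 individuals at ordered markers (one chromosome)."""

    chrom: str
    marker_pos: np.ndarray  # 1-based bp, strictly increasing
    ancestry: np.ndarray  # (n_f2, n_markers) in {AA, AB, BB, MISSING_STATE}
    #: regions where the F1 parents are inversion heterozygotes, per F2:
    #: mapping region -> boolean array over F2s (True = informative F2)
    f1_het_regions: dict[GenomicInterval, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker_pos = np.asarray(self.marker_pos, dtype=np.int64)
        self.ancestry = np.asarray(self.ancestry, dtype=np.int8)
        if len(self.marker_pos) < 2:
            raise ValueError("need >= 2 markers")
        if not (np.diff(self.marker_pos) > 0).all():
            raise ValueError("marker positions must be strictly increasing")

    @property
    def n_f2(self) -> int:
        return self.ancestry.shape[0]


def _run_lengths(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encoding [(state, first_index, last_index), ...]."""
    runs: list[tuple[int, int, int]] = []
    for i, s in enumerate(states):
        if runs and runs[-1][0] == s:
            runs[-1] = (runs[-1][0], runs[-1][1], i)
        else:
            runs.append((int(s), i, i))
    return runs


def max_error_run(
    error_rate: float, background_rate: float, marker_spacing_bp: int, cap: int = 3
) -> int:
    """Longest discordant run more plausibly explained by genotyping error
    than by a pair of flanking crossovers.

    A run of L consistently mis-called markers has probability ~error^L; the
    crossover explanation needs two exchanges in ~marker-spacing intervals,
    probability ~(rate x spacing / 100)^2 per gamete. The cleaning threshold
    is the largest L (capped) where the error explanation dominates —
    the parsimony analogue of what an ancestry HMM decides at these rates.
    """
    if error_rate <= 0:
        return 1
    p_x = background_rate * (marker_spacing_bp / 1e6) / 100.0
    if p_x <= 0:
        return cap
    L = 1
    while L < cap and error_rate ** (L + 1) >= p_x**2:
        L += 1
    return L


def _remove_error_runs(
    pos: np.ndarray, states: np.ndarray, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively drop short state runs attributable to genotyping error.

    Interior singletons are always removed; longer interior runs (up to
    ``max_len``) are removed only when both flanking runs share the same
    state — a short run *between* two different states is the genuine
    crossover path through the heterozygous class and is kept. Terminal
    runs are never removed (a terminal switch is indistinguishable from a
    real crossover near the chromosome end, and removal would cascade).
    """
    while True:
        runs = _run_lengths(states)
        if len(runs) <= 1:
            break
        removable = []
        for i, (s, f, l) in enumerate(runs):
            if l - f + 1 > max_len or i == 0 or i == len(runs) - 1:
                continue
            if l == f or runs[i - 1][0] == runs[i + 1][0]:
                removable.append((f, l))  # interior error signature
        if not removable:
            break
        f, l = removable[0]
        keep = np.ones(len(states), dtype=bool)
        keep[f : l + 1] = False
        pos, states = pos[keep], states[keep]
    return pos, states


def infer_crossovers(
    panel: CrossPanel, singleton_clean: bool = True, max_error_run_len: int = 1
) -> list[list[tuple[float, int]]]:
    """Per-F2 crossover events as (midpoint bp, multiplicity).

    With ``singleton_clean``, state runs of up to ``max_error_run_len``
    markers are treated as genotyping error and removed before counting
    (see :func:`max_error_run` for choosing the length from an error model;
    the default 1 removes single-marker switches only). State changes along
    the cleaned non-missing marker sequence contribute |state difference|
    crossovers (AA<->AB: 1, AA<->BB: 2) positioned at the midpoint of the
    flanking markers. An all-missing individual yields an empty event list.
    """
    out: list[list[tuple[float, int]]] = []
    for row in panel.ancestry:
        obs = row != MISSING_STATE
        pos = panel.marker_pos[obs]
        states_seq = row[obs]
        if len(states_seq) == 0:
            out.append([])
            continue
        if singleton_clean:
            pos, states_seq = _remove_error_runs(pos, states_seq, max_error_run_len)
        events: list[tuple[float, int]] = []
        for i in range(1, len(states_seq)):
            d = abs(int(states_seq[i]) - int(states_seq[i - 1]))
            if d:
                events.append(((pos[i - 1] + pos[i]) / 2.0, d))
        out.append(events)
    return out


def recombination_rate_region(
    crossovers: list[list[tuple[float, int]]],
    region: GenomicInterval,
    informative: np.ndarray | None = None,
) -> float:
    """cM/Mb in ``region`` from per-F2 crossover events.

    A crossover belongs to the region when its midpoint falls inside
    (half-open, 0-based). ``informative`` restricts to F2s whose F1 parents
    are heterozygous for the focal inversion. Map length
    cM = 100 x crossovers / (2 x n_F2); rate = cM / Mb.
    """
    if informative is None:
        informative = np.ones(len(crossovers), dtype=bool)
    idx = np.nonzero(np.asarray(informative))[0]
    if len(idx) == 0:
        raise ValueError("no informative F2 after filtering")
    count = 0
    for i in idx:
        for mid, mult in crossovers[i]:
            if region.start <= mid - 1 < region.end:
                count += mult
    cm = 100.0 * count / (2.0 * len(idx))
    return cm / (len(region) / 1e6)
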