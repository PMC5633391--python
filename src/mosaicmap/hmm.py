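"""Viterbi smoothing of A/B/N calls into founder haplotype blocks.

A three-state hidden Markov model (founder 1, founder 2, heterozygous) is
decoded with the Viterbi algorithm; the per-step transition probability is
iteratively re-estimated from the decoded path until the path stops
changing.  Emissions are fixed.  Blocks of constant state and the
"recombination intervals" between them (the marker gap inside which the
crossover must lie) are derived from the final path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genotyping import GenotypeCallSet

# state codes
F1, F2, HET = 0, 1, 2
STATE_NAMES = np.array(["F1", "F2", "Het"])

DEFAULT_EMISSION = np.array([
    # A      B      N
    [0.980, 0.005, 0.015],   # F1
    [0.005, 0.980, 0.015],   # F2
    [0.050, 0.050, 0.900],   # Het
])


def noiseless_emission(eps: float = 1e-6) -> np.ndarray:
    """Emission matrix for (near) error-free calls.

    The default emissions assume ~1-2% call error and therefore smooth away
    genuine single-marker blocks; when the data is known to be error-free,
    an emission error far below the transition probability recovers the
    truth exactly.
    """
    e = np.full((3, 3), eps)
    e[0, 0] = e[1, 1] = e[2, 2] = 1.0 - 2 * eps
    return e


@dataclass
class HmmParams:
    """Transition/emission parameters of the three-state call smoother.

    ``tau`` is the per-adjacent-marker probability of leaving the current
    state (split evenly between the two other states); it is the only
    parameter re-estimated during fitting.
    """

    tau: float = 1e-3
    emission: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION.copy())
    tau_min: float = 1e-6
    max_iter: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 0.5):
            raise ValueError("tau must be in (0, 0.5)")
        e = np.asarray(self.emission, dtype=float)
        if e.shape != (3, 3) or not np.allclose(e.sum(axis=1), 1.0):
            raise ValueError("emission must be 3x3 with rows summing to 1")
        self.emission = e

    def log_transition(self) -> np.ndarray:
        t = np.full((3, 3), self.tau / 2.0)
        np.fill_diagonal(t, 1.0 - self.tau)
        return np.log(t)


def viterbi_path(calls: np.ndarray, params: HmmParams) -> np.ndarray:
    """Maximum-probability state path for one chromosome's call sequence.

    Uniform initial distribution; ties are broken toward remaining in the
    current state, then toward the lower state index (F1 first).
    """
    obs = np.asarray(calls)
    n = len(obs)
    if n == 0:
        raise ValueError("empty call sequence")
    log_e = np.log(params.emission)
    log_t = params.log_transition()
    delta = np.log(1.0 / 3.0) + log_e[:, obs[0]]
    back = np.empty((n, 3), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_t  # cand[i, j]: from i to j
        # tie-break: prefer staying (i == j), then the lowest predecessor index
        best = np.zeros(3, dtype=np.int8)
        best_score = cand[0].copy()
        for i in (1, 2):
            better = cand[i] > best_score
            best_score[better] = cand[i][better]
            best[better] = i
        for j in range(3):
            if cand[j, j] == best_score[j]:
                best[j] = j
        back[t] = best
        delta = best_score + log_e[:, obs[t]]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))  # argmax keeps the lowest index on ties
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_log_probability(calls: np.ndarray, states: np.ndarray,
                         params: HmmParams) -> float:
    """Joint log probability of (path, calls) under the model."""
    obs = np.asarray(calls)
    st = np.asarray(states)
    log_e = np.log(params.emission)
    log_t = params.log_transition()
    lp = np.log(1.0 / 3.0) + log_e[st[0], obs[0]]
    if len(obs) > 1:
        lp += log_t[st[:-1], st[1:]].sum() + log_e[st[1:], obs[1:]].sum()
    return float(lp)


@dataclass
class Block:
    chrom: str
    state: int
    first_marker: int  # index within the chromosome's informative markers
    last_marker: int
    start_bp: int      # bp of first marker
    end_bp: int        # bp of last marker

    @property
    def n_markers(self) -> int:
        return self.last_marker - self.first_marker + 1

    @property
    def state_name(self) -> str:
        return str(STATE_NAMES[self.state])


@dataclass(frozen=True)
class RecombinationEvent:
    """A founder switch localised to the gap between two informative markers."""
    chrom: str
    start_bp: int  # bp of the last marker of the preceding homozygous block
    end_bp: int    # bp of the first marker of the following homozygous block
    from_state: int
    to_state: int

    @property
    def interval_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def polarity(self) -> tuple[int, int]:
        return (self.from_state, self.to_state)


@dataclass
class HaplotypeMap:
    """Per-chromosome founder/Het state at every informative marker."""

    sample: str
    positions: dict[str, np.ndarray]  # chrom -> marker bp positions
    states: dict[str, np.ndarray]     # chrom -> state codes per marker
    converged: bool = True
    n_iterations: int = 0
    tau: float | None = None

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def blocks(self, chrom: str | None = None) -> list[Block]:
        chroms = [chrom] if chrom else self.chromosomes
        out: list[Block] = []
        for c in chroms:
            st, pos = self.states[c], self.positions[c]
            if len(st) == 0:
                continue
            changes = np.flatnonzero(st[1:] != st[:-1]) + 1
            bounds = np.concatenate(([0], changes, [len(st)]))
            for i0, i1 in zip(bounds[:-1], bounds[1:]):
                out.append(Block(c, int(st[i0]), int(i0), int(i1 - 1),
                                 int(pos[i0]), int(pos[i1 - 1])))
        return out

    def swap_founders(self) -> "HaplotypeMap":
        states = {}
        for c, st in self.states.items():
            sw = st.copy()
            sw[st == F1] = F2
            sw[st == F2] = F1
            states[c] = sw
        return HaplotypeMap(self.sample, self.positions, states,
                            self.converged, self.n_iterations, self.tau)


def fit_haplotype_map(callset: GenotypeCallSet, sample: str,
                      init: HmmParams | None = None) -> tuple[HaplotypeMap, HmmParams]:
    """Iterative Viterbi fit for one strain.

    Each iteration decodes every chromosome with the current ``tau`` and
    re-estimates ``tau`` as (state changes) / (adjacent-marker steps) over
    the whole genome (floored at ``tau_min``); iteration stops when the
    decoded paths are identical to the previous iteration's or after
    ``max_iter`` rounds (flagged as non-converged).  Emissions are not
    re-estimated.
    """
    params = init if init is not None else HmmParams()
    chroms = callset.chromosomes
    seqs = {c: callset.chrom_calls(sample, c) for c in chroms}
    paths: dict[str, np.ndarray] | None = None
    converged = False
    iteration = 0
    for iteration in range(1, params.max_iter + 1):
        new_paths = {c: viterbi_path(calls, params)
                     for c, (pos, calls) in seqs.items() if len(calls)}
        if paths is not None and all(np.array_equal(new_paths[c], paths[c])
                                     for c in new_paths):
            paths = new_paths
            converged = True
            break
        paths = new_paths
        changes = sum(int(np.sum(p[1:] != p[:-1])) for p in paths.values())
        steps = sum(max(len(p) - 1, 0) for p in paths.values())
        if steps:
            tau = min(max(changes / steps, params.tau_min), 0.5 - 1e-9)
            params = replace(params, tau=tau)
    assert paths is not None
    hmap = HaplotypeMap(sample,
                        {c: seqs[c][0] for c in paths},
                        paths, converged, iteration, params.tau)
    return hmap, params


def fit_panel(callset: GenotypeCallSet, init: HmmParams | None = None,
              ) -> dict[str, HaplotypeMap]:
    return {s: fit_haplotype_map(callset, s, init)[0] for s in callset.samples}


def extract_recombination_intervals(hmap: HaplotypeMap) -> list[RecombinationEvent]:
    """Recombination events between homozygous founder blocks.

    One event per adjacent pair of blocks with different homozygous states;
    a Het block between two different founder blocks is spanned by a single
    event whose polarity is taken across it (Het flanked by the same
    founder yields no event).
    """
    events: list[RecombinationEvent] = []
    for chrom in hmap.chromosomes:
        homo = [b for b in hmap.blocks(chrom) if b.state != HET]
        for prev, nxt in zip(homo[:-1], homo[1:]):
            if prev.state != nxt.state:
                events.append(RecombinationEvent(chrom, prev.end_bp, nxt.start_bp,
                                                 prev.state, nxt.state))
    return events


def truth_map(strain, genome, callset_probes, founders) -> HaplotypeMap:
    """Ground-truth map of a simulated strain at the given informative markers.

    Marker state is F1/F2 where both haplotypes carry the same panel
    founder, Het otherwise (any non-founder label also maps to Het).
    """
    positions: dict[str, np.ndarray] = {}
    states: dict[str, np.ndarray] = {}
    code1, code2 = founders.code(founders.panel[0]), founders.code(founders.panel[1])
    for chrom in list(dict.fromkeys(callset_probes["chrom"])):
        pos = callset_probes.loc[callset_probes["chrom"] == chrom, "pos"].to_numpy()
        if chrom not in strain.chromosomes or len(pos) == 0:
            continue
        lab = strain.labels_at(chrom, pos)
        if lab.shape[0] == 1:
            lab = np.vstack([lab, lab])
        st = np.full(len(pos), HET, dtype=np.int8)
        st[(lab[0] == code1) & (lab[1] == code1)] = F1
        st[(lab[0] == code2) & (lab[1] == code2)] = F2
        positions[chrom] = pos
        states[chrom] = st
    return HaplotypeMap(strain.name, positions, states)
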