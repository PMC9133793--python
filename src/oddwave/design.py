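"""Psychometric stimulus selection and roving-oddball train-sequence generation.

The experiment presents consecutive "trains" of 4-6 identical syllables drawn
from a 5-stimulus set (A-E) centred on a listener's categorical-perception
boundary along a /ba/-/da/ continuum.  The first token of each train is the
deviant (the stimulus just changed); tokens 2-6 are standards at increasing
levels of repetition.  This module fits the psychometric boundary, picks the
equidistant stimulus set, and generates the pseudo-randomized train sequence
under the published count constraints: 600 trains, 200 each of lengths 4/5/6,
consecutive trains always differing in stimulus, and all 20 ordered
stimulus-to-stimulus transitions occurring with near-equal frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PsychometricFit",
    "StimulusSet",
    "DesignSpec",
    "TrainDesign",
    "DesignError",
    "fit_psychometric",
    "select_stimulus_set",
    "generate_design",
    "position_counts",
    "transition_counts",
]

STIMULUS_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class DesignError(ValueError):
    """Raised when a design constraint set is invalid or infeasible."""


@dataclass(frozen=True)
class PsychometricFit:
    """Four-parameter logistic fit of a labeling-ratio curve.

    ``midpoint`` is the inflection point (the categorical boundary) in
    continuum-step units; ``slope`` is per-step steepness (> 0 for a
    /ba/->/da/ labeling convention); ``lower``/``upper`` are the asymptotes
    as proportions in [0, 1].
    """

    midpoint: float
    slope: float
    lower: float
    upper: float
    converged: bool


@dataclass(frozen=True)
class StimulusSet:
    """Five equidistant continuum steps labeled A-E, centred on the boundary."""

    steps: tuple[int, int, int, int, int]
    spacing: int
    clamped: bool = False

    def __post_init__(self) -> None:
        diffs = np.diff(self.steps)
        if not (diffs > 0).all() or len(set(diffs.tolist())) != 1:
            raise DesignError(f"steps must be strictly increasing and equidistant, got {self.steps}")

    @property
    def labels(self) -> dict[str, int]:
        return dict(zip("ABCDE", self.steps))


@dataclass(frozen=True)
class DesignSpec:
    """Constraints for a roving-oddball sequence.

    ``length_counts`` maps train length (4, 5 or 6) to the number of trains
    with that length.  Timing metadata (stimulus-onset asynchrony and syllable
    duration, in ms) is carried for provenance but not used computationally:
    the simulator emits pre-epoched trials.
    """

    n_trains: int = 600
    length_counts: Mapping[int, int] = field(default_factory=lambda: {4: 200, 5: 200, 6: 200})
    n_stimuli: int = 5
    transition_balance: bool = True
    seed: int | None = None
    soa_ms: float = 575.0
    stimulus_duration_ms: float = 310.0

    def __post_init__(self) -> None:
        if self.n_stimuli < 2:
            raise DesignError("need at least 2 stimuli")
        if any(length not in (4, 5, 6) for length in self.length_counts):
            raise DesignError("train lengths must be in {4, 5, 6}")
        if sum(self.length_counts.values()) != self.n_trains:
            raise DesignError(
                f"length counts {dict(self.length_counts)} do not sum to n_trains={self.n_trains}"
            )


@dataclass(frozen=True)
class TrainDesign:
    """A realized train sequence and its per-trial expansion."""

    trains: tuple[tuple[str, int], ...]
    trial_rows: pd.DataFrame
    spec: DesignSpec

    @property
    def n_trials(self) -> int:
        return len(self.trial_rows)

    def save(self, path: str | Path) -> None:
        """Write the trial table as TSV with a JSON spec sidecar."""
        path = Path(path)
        self.trial_rows.to_csv(path, sep="\t", index=False)
        sidecar = {
            "n_trains": self.spec.n_trains,
            "length_counts": {str(k): v for k, v in self.spec.length_counts.items()},
            "n_stimuli": self.spec.n_stimuli,
            "transition_balance": self.spec.transition_balance,
            "seed": self.spec.seed,
            "soa_ms": self.spec.soa_ms,
            "stimulus_duration_ms": self.spec.stimulus_duration_ms,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _logistic4(x, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_psychometric(step_ids: Sequence[float], response_ratio: Sequence[float]) -> PsychometricFit:
    """Least-squares 4-parameter logistic fit of labeling ratios vs continuum step.

    Degenerate data (flat ratios) or optimizer failure yields a result with
    ``converged=False`` rather than an exception, so callers can substitute a
    default boundary.
    """
    x = np.asarray(step_ids, dtype=float)
    r = np.asarray(response_ratio, dtype=float)
    if len(np.unique(x)) < 4:
        raise DesignError("need responses at >= 4 distinct continuum steps")
    if r.min() < 0 or r.max() > 1:
        raise DesignError("response ratios must lie in [0, 1]")
    if np.ptp(r) < 1e-12:
        return PsychometricFit(np.nan, np.nan, float(r[0]), float(r[0]), converged=False)

    # midpoint guess: step whose ratio is closest to the half-range point
    mid_guess = float(x[np.argmin(np.abs(r - (r.min() + r.max()) / 2.0))])
    span = float(x.max() - x.min())
    p0 = (max(r.min(), 1e-3), min(r.max(), 1 - 1e-3), mid_guess, 1.0)
    bounds = ([0.0, 0.0, x.min() - span, 1e-6], [1.0, 1.0, x.max() + span, 1e3])
    try:
        popt, _ = curve_fit(_logistic4, x, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    lower, upper, midpoint, slope = map(float, popt)
    if not np.isfinite(midpoint):
        return PsychometricFit(np.nan, np.nan, lower, upper, converged=False)
    return PsychometricFit(midpoint, slope, lower, upper, converged=True)


def select_stimulus_set(
    fit: PsychometricFit, n_continuum_steps: int = 10, spacing: int = 2
) -> StimulusSet:
    """Choose 5 equidistant steps centred on the fitted boundary.

    Stimulus C is the continuum step nearest the inflection point, clamped so
    that the set ``{C-2s, C-s, C, C+s, C+2s}`` fits inside the continuum;
    ``clamped`` records whether clamping moved C.
    """
    if not fit.converged:
        raise DesignError(
            "psychometric fit did not converge; supply a default midpoint explicitly"
        )
    if spacing * 4 >= n_continuum_steps:
        raise DesignError("spacing too large for the continuum")
    c_raw = int(np.floor(fit.midpoint + 0.5))
    lo, hi = 1 + 2 * spacing, n_continuum_steps - 2 * spacing
    c = min(max(c_raw, lo), hi)
    steps = tuple(c + spacing * k for k in (-2, -1, 0, 1, 2))
    return StimulusSet(steps=steps, spacing=spacing, clamped=(c != c_raw))


# ---------------------------------------------------------------------------
# Train-sequence generation.
#
# Balanced transitions are generated as an Eulerian path on the complete
# directed graph over stimuli: each ordered pair (a, b) contributes
# q = (n_trains - 1) // (n * (n - 1)) edges, and the remainder r is laid down
# as a trail of r distinct extra edges.  An Eulerian path over this multigraph
# is exactly a train sequence in which consecutive trains differ, every
# transition count is q or q + 1, and (when r = n(n-1) - 1, as at the
# defaults) every stimulus heads the same number of trains.
# ---------------------------------------------------------------------------


def _euler_path(n: int, edge_count: dict[tuple[int, int], int], rng: np.random.Generator,
                start: int | None = None) -> list[int]:
    """Seeded Hierholzer Eulerian path over a directed multigraph on 0..n-1."""
    adj: dict[int, list[int]] = {u: [] for u in range(n)}
    out_deg = np.zeros(n, int)
    in_deg = np.zeros(n, int)
    for (u, v), c in edge_count.items():
        adj[u].extend([v] * c)
        out_deg[u] += c
        in_deg[v] += c
    for u in range(n):
        rng.shuffle(adj[u])
    if start is None:
        surplus = np.flatnonzero(out_deg - in_deg == 1)
        if len(surplus):
            start = int(surplus[0])
        else:
            start = int(rng.choice(np.flatnonzero(out_deg > 0)))
    ptr = {u: 0 for u in range(n)}
    stack, path = [start], []
    while stack:
        u = stack[-1]
        if ptr[u] < len(adj[u]):
            stack.append(adj[u][ptr[u]])
            ptr[u] += 1
        else:
            path.append(stack.pop())
    path.reverse()
    n_edges = int(sum(edge_count.values()))
    if len(path) != n_edges + 1:
        raise DesignError("transition multigraph is disconnected; cannot realize a sequence")
    return path


def _random_trail(n: int, r: int, rng: np.random.Generator) -> list[int]:
    """A trail of r distinct directed edges on the complete graph over 0..n-1.

    When r = n(n-1) - 1 the trail is an Eulerian circuit of the complete graph
    minus its last edge, which visits every node equally often - this keeps
    the trains-per-stimulus count exactly balanced at the defaults.
    """
    full = n * (n - 1)
    if r >= full:
        raise DesignError("remainder trail longer than the complete graph")
    if r == full - 1:
        circuit = _euler_path(n, {(u, v): 1 for u in range(n) for v in range(n) if u != v}, rng)
        return circuit[:-1]
    start = int(rng.integers(n))
    path = [start]
    used: set[tuple[int, int]] = set()

    def extend() -> bool:
        if len(path) == r + 1:
            return True
        u = path[-1]
        nbrs = [v for v in range(n) if v != u and (u, v) not in used]
        order = rng.permutation(len(nbrs))
        for k in order:
            v = nbrs[k]
            used.add((u, v))
            path.append(v)
            if extend():
                return True
            path.pop()
            used.discard((u, v))
        return False

    if not extend():
        raise DesignError("could not construct remainder transition trail")
    return path


def _stimulus_sequence(spec: DesignSpec, rng: np.random.Generator) -> list[int]:
    n, m = spec.n_stimuli, spec.n_trains
    if m == 1:
        return [int(rng.integers(n))]
    if not spec.transition_balance:
        seq = [int(rng.integers(n))]
        for _ in range(m - 1):
            nxt = int(rng.integers(n - 1))
            seq.append(nxt if nxt < seq[-1] else nxt + 1)
        return seq
    q, r = divmod(m - 1, n * (n - 1))
    edge_count = {(u, v): q for u in range(n) for v in range(n) if u != v}
    start = None
    if r:
        trail = _random_trail(n, r, rng)
        for u, v in zip(trail[:-1], trail[1:]):
            edge_count[(u, v)] += 1
        start = trail[0]
    if q == 0:
        edge_count = {e: c for e, c in edge_count.items() if c > 0}
    return _euler_path(n, edge_count, rng, start=start)


def generate_design(spec: DesignSpec) -> TrainDesign:
    """Generate a pseudo-randomized train sequence satisfying the constraints.

    With the defaults this emits 600 trains over 5 stimuli (3,000 trials) in
    which every ordered stimulus transition occurs 29 or 30 times and every
    stimulus heads exactly 120 trains.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    stim_seq = _stimulus_sequence(spec, rng)
    lengths = np.repeat(
        [int(k) for k in spec.length_counts], [spec.length_counts[k] for k in spec.length_counts]
    )
    lengths = rng.permutation(lengths)
    trains = tuple(
        (STIMULUS_ALPHABET[s], int(length)) for s, length in zip(stim_seq, lengths)
    )
    rows = []
    trial = 0
    for train_idx, (stim, length) in enumerate(trains):
        for pos in range(1, length + 1):
            rows.append((trial, train_idx, stim, pos, pos == 1))
            trial += 1
    trial_rows = pd.DataFrame(
        rows, columns=["trial_index", "train_index", "stimulus", "position_in_train", "is_deviant"]
    )
    return TrainDesign(trains=trains, trial_rows=trial_rows, spec=spec)


def position_counts(design: TrainDesign) -> dict[int, int]:
    """Trial counts per position-in-train (1 = deviant, 2..6 = standards)."""
    counts = design.trial_rows["position_in_train"].value_counts().sort_index()
    return {int(k): int(v) for k, v in counts.items()}


def transition_counts(design: TrainDesign) -> dict[tuple[str, str], int]:
    """Counts of ordered stimulus transitions between consecutive trains."""
    labels = [stim for stim, _ in design.trains]
    out: dict[tuple[str, str], int] = {}
    for a, b in zip(labels[:-1], labels[1:]):
        out[(a, b)] = out.get((a, b), 0) + 1
    return out
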