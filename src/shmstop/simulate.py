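"""Monte-Carlo simulator of somatic hypermutation over dark-zone divisions.

Cells start from the V-gene template and, each division, acquire region-
weighted point substitutions and (rarely) short deletions.  The simulator is
the stochastic counterpart of the analytic chain in :mod:`shmstop.expectation`
and the sequence source for synthetic datasets.

Two mutation-count modes exist because the analytic model treats ``L*mu`` as
a per-division *probability* (linear, at most one mutation per division)
while a mechanistic reading makes the per-division mutation count
Poisson(L*mu).  ``"bernoulli"`` is the default when validating the analytic
chain, since that chain is linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .template import (
    BASES,
    STOP_CODONS,
    RegionPartition,
    VGeneTemplate,
)

__all__ = [
    "MutationEvent",
    "SimulatedCell",
    "SimConfig",
    "uniform_deletion_lengths",
    "mutate_one_division",
    "simulate_cohort",
    "classify_against_template",
    "replay_events",
    "translate_has_premature_stop",
]


@dataclass(frozen=True)
class MutationEvent:
    """A single mutation event, recorded with enough coordinates to replay.

    ``seq_index`` is the position in the cell's sequence *at the time of the
    event*; ``template_pos`` is the template position that base derived from
    (deletion events store the template position of the first deleted base).
    """

    division: int
    kind: str  # "substitution" | "deletion"
    seq_index: int
    template_pos: int
    detail: str  # "A>T" for substitutions, "len=2" for deletions


@dataclass
class SimulatedCell:
    cell_id: str
    divisions_completed: int
    seq: str
    events: tuple[MutationEvent, ...]
    has_stop: bool          # stop codon in the in-frame translation
    has_frameshift: bool    # net indel length not a multiple of 3

    @property
    def has_premature_stop(self) -> bool:
        return self.has_stop or self.has_frameshift


def uniform_deletion_lengths(rng: np.random.Generator) -> int:
    """Default deletion length distribution: uniform over {1, 2, 3}, so
    exactly one third of deletions are in-frame."""
    return int(rng.integers(1, 4))


@dataclass
class SimConfig:
    """Simulation parameters; a fixed seed gives byte-identical cohorts."""

    mu: float = 1e-3
    p_del: float = 0.0
    mode: str = "bernoulli"  # "bernoulli" | "poisson"
    deletion_length_dist: Callable[[np.random.Generator], int] = uniform_deletion_lengths

    def __post_init__(self):
        if self.mode not in ("bernoulli", "poisson"):
            raise ValueError("mode must be 'bernoulli' or 'poisson'")
        if not (0.0 <= self.p_del <= 1.0):
            raise ValueError("p_del must be in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


class _CellState:
    """Mutable sequence plus, for every base, its template position."""

    __slots__ = ("bases", "tpos")

    def __init__(self, template: VGeneTemplate):
        self.bases = list(template.seq)
        self.tpos = list(range(len(template.seq)))


def _alt_base(rng: np.random.Generator, current: str) -> str:
    alts = [b for b in BASES if b != current]
    return alts[int(rng.integers(0, 3))]


def mutate_one_division(state: _CellState,
                        weights: np.ndarray,
                        config: SimConfig,
                        rng: np.random.Generator,
                        division: int) -> list[MutationEvent]:
    """Apply one division's worth of mutation to ``state`` in place.

    Substitution positions are sampled proportionally to the region weight of
    each base's template-projected location; the new base is uniform over the
    three alternatives.  With probability ``p_del`` one deletion occurs at a
    uniform position, with length drawn from the configured distribution
    (starts near the 3' end slide left so the full length fits).
    """
    if not state.bases:
        raise ValueError("cannot mutate an empty sequence")
    events: list[MutationEvent] = []

    n_bases = len(state.bases)
    p_m = min(1.0, n_bases * config.mu)
    if config.mode == "bernoulli":
        n_subs = 1 if rng.random() < p_m else 0
    else:
        n_subs = int(rng.poisson(n_bases * config.mu))
    for _ in range(n_subs):
        w = weights[state.tpos]
        w = w / w.sum()
        i = int(rng.choice(len(state.bases), p=w))
        old = state.bases[i]
        new = _alt_base(rng, old)
        state.bases[i] = new
        events.append(MutationEvent(division, "substitution", i, state.tpos[i],
                                    f"{old}>{new}"))

    if config.p_del > 0 and rng.random() < config.p_del:
        length = int(config.deletion_length_dist(rng))
        length = min(length, len(state.bases))
        # a start too close to the 3' end slides left so the full deletion
        # length fits (truncating would silently change the frame impact)
        i = min(int(rng.integers(0, len(state.bases))), len(state.bases) - length)
        if length > 0:
            events.append(MutationEvent(division, "deletion", i, state.tpos[i],
                                        f"len={length}"))
            del state.bases[i:i + length]
            del state.tpos[i:i + length]
    return events


def translate_has_premature_stop(seq: str, before_codon: int | None = None) -> bool:
    """True if the frame-0 translation of ``seq`` has a stop codon strictly
    before ``before_codon`` (default: the sequence's final complete codon)."""
    n_codons = len(seq) // 3
    last = n_codons - 1 if before_codon is None else before_codon
    for j in range(min(last, n_codons)):
        if seq[3 * j:3 * j + 3] in STOP_CODONS:
            return True
    return False


def classify_against_template(template: VGeneTemplate, seq: str) -> dict:
    """Classify a (substitution/deletion-only) mutated sequence.

    A net length change that is not a multiple of 3 is a frameshift and
    counts as stop-causing.  Otherwise the sequence is translated in the
    template frame (net in-frame deletions leave the frame intact downstream)
    and scanned for a stop before the final codon.

    Returns a dict with ``premature_stop``, ``frameshift``, ``has_stop``
    (in-frame translation stop), ``n_substitutions`` and ``n_deletions``.
    Mutation counts are exact for length-preserving sequences and otherwise
    derived from a global alignment.
    """
    if not seq:
        raise ValueError("empty sequence")
    net = template.length - len(seq)
    frameshift = (net % 3) != 0
    has_stop = translate_has_premature_stop(seq)
    if len(seq) == template.length:
        n_subs = sum(1 for a, b in zip(template.seq, seq) if a != b)
        n_dels = 0
    else:
        from .calling import align_to_template  # local import avoids a cycle
        aln = align_to_template(seq, template)
        n_subs, n_dels = aln.n_mismatches, aln.n_gap_blocks
    return {
        "premature_stop": has_stop or frameshift,
        "frameshift": frameshift,
        "has_stop": has_stop,
        "n_substitutions": n_subs,
        "n_deletions": n_dels,
    }


def replay_events(template: VGeneTemplate, events: Sequence[MutationEvent]) -> str:
    """Re-apply an event log to the template; must reproduce the cell."""
    bases = list(template.seq)
    for ev in events:
        if ev.kind == "substitution":
            old, new = ev.detail.split(">")
            if bases[ev.seq_index] != old:
                raise ValueError(f"replay mismatch at event {ev}")
            bases[ev.seq_index] = new
        elif ev.kind == "deletion":
            length = int(ev.detail.split("=")[1])
            del bases[ev.seq_index:ev.seq_index + length]
        else:
            raise ValueError(f"unknown event kind {ev.kind}")
    return "".join(bases)


def simulate_cohort(template: VGeneTemplate,
                    partition: RegionPartition | None,
                    config: SimConfig,
                    division_spec,
                    n_cells: int,
                    rng: np.random.Generator | int,
                    cell_id_prefix: str = "cell",
                    ) -> list[SimulatedCell]:
    """Simulate ``n_cells`` independent cells.

    ``division_spec`` is either a fixed integer number of divisions or a
    :class:`~shmstop.expectation.DivisionDistribution` from which each cell's
    division count is drawn.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if partition is None:
        partition = RegionPartition.uniform(template.length)
    weights = np.asarray(partition.position_weights(), dtype=float)

    if hasattr(division_spec, "probs"):
        ks = sorted(division_spec.probs)
        ps = np.array([division_spec.probs[k] for k in ks])
        draws = rng.choice(ks, size=n_cells, p=ps)
    else:
        draws = np.full(n_cells, int(division_spec))

    cells = []
    for c in range(n_cells):
        state = _CellState(template)
        events: list[MutationEvent] = []
        for d in range(int(draws[c])):
            events.extend(mutate_one_division(state, weights, config, rng, d))
        seq = "".join(state.bases)
        truth = classify_against_template(template, seq)
        cells.append(SimulatedCell(
            cell_id=f"{cell_id_prefix}{c:05d}",
            divisions_completed=int(draws[c]),
            seq=seq,
            events=tuple(events),
            has_stop=truth["has_stop"],
            has_frameshift=truth["frameshift"],
        ))
    return cells
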