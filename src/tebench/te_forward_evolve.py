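"""Forward-time evolution of a TE seed sequence down a phylogeny.

The simulator takes a prototype (ancestral) sequence, a phylogeny, a
trinucleotide substitution-rate table and indel/fragmentation parameters, and
produces the extant (leaf) sequences together with the ground-truth reference
MSA relating them.

Model
-----
Substitutions follow a continuous-time Markov process in units of generations:
site ``i`` with triplet context ``(b[i-1], b[i], b[i+1])`` mutates at rate
``RATE_SCALE`` times its triplet's total rate (the matrix is normalised so the
mean total rate over the 64 triplets is 1, so ``RATE_SCALE`` is the average
per-site per-generation substitution probability).  Events are drawn by the
Gillespie algorithm; context is recomputed after every event, so overlapping
triplet effects are exact.  Sequence edges marginalise the missing flank over
the four bases.

Indels are coupled to realised substitutions: after each substitution an
insertion occurs with probability ``insertion_rate`` (default 0.08) and a
deletion with probability ``deletion_rate`` (default 0.12) — an indel
occurrence rate of 0.20 relative to an average substitution rate of 1.  Indel
lengths follow a Zipf (power-law) distribution truncated to
``{1..max_length}`` whose exponent is calibrated so the mean equals
``mean_length`` (defaults 1.7 and 20).  Inserted bases are drawn i.i.d. from
the current sequence's base composition (configurable to uniform).

Every residue carries an immutable column key; keys of inserted residues are
generated between their neighbours' keys, so sorting the union of keys over
all leaves yields the true alignment — residues share a reference-MSA column
iff they descend from the same ancestral residue.

Fragmentation emulates the decayed, truncated copies seen in genomes: at leaf
emission a fragment length is drawn from a log-normal distribution
(arithmetic mean/sd parameterisation) clamped to ``[min_fragment, len]`` and
a uniform start position selects the retained window.  The first
``min_full_length`` leaves emitted are left full-length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .formats_io import BASES, Msa, SeqRecord, TripletRateMatrix
from .tree_sim import Phylogeny

__all__ = [
    "RATE_SCALE",
    "ZIPF_EXPONENT_CAP",
    "IndelModel",
    "FragmentationModel",
    "SimConfig",
    "BranchEvents",
    "EvolutionResult",
    "SequenceState",
    "SimulationError",
    "calibrate_zipf",
    "truncated_zipf_pmf",
    "evolve_branch",
    "simulate",
    "fragment",
    "kimura_divergence",
    "calibration_run",
]

#: substitutions per site per generation for a triplet of total rate 1.
#: With the matrix normalised to mean rate 1 and the default tree depth of
#: 100 time units, GPUT values of 100..6000 span roughly 1%..50% Kimura
#: divergence on a kb-scale seed.
RATE_SCALE = 1e-6

#: exponent returned for the degenerate "all mass at length 1" boundary.
ZIPF_EXPONENT_CAP = 64.0

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# truncated Zipf indel-length distribution
# ---------------------------------------------------------------------------

def truncated_zipf_pmf(exponent: float, max_length: int) -> np.ndarray:
    """P(L = k) ∝ k^(-exponent) for k in 1..max_length."""
    k = np.arange(1, max_length + 1, dtype=float)
    w = k ** (-exponent)
    return w / w.sum()


def _zipf_mean(exponent: float, max_length: int) -> float:
    pmf = truncated_zipf_pmf(exponent, max_length)
    return float(pmf @ np.arange(1, max_length + 1))


def calibrate_zipf(mean_length: float, max_length: int) -> float:
    """Find the exponent whose truncated-Zipf mean equals ``mean_length``.

    The mean is monotone decreasing in the exponent, from ``(1+max)/2`` at
    exponent 0 towards 1 as the exponent grows, so bisection converges.  The
    boundary ``mean_length == 1`` returns the capped exponent
    :data:`ZIPF_EXPONENT_CAP` (all mass at length 1).
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    uniform_mean = (1 + max_length) / 2
    if math.isclose(mean_length, 1.0, abs_tol=1e-12):
        return ZIPF_EXPONENT_CAP
    if math.isclose(mean_length, uniform_mean, abs_tol=1e-12):
        return 0.0
    if not 1.0 < mean_length < uniform_mean:
        raise ValueError(
            f"mean_length {mean_length} unattainable; attainable interval is "
            f"(1, {uniform_mean}]"
        )
    lo, hi = 0.0, ZIPF_EXPONENT_CAP
    for _ in range(200):
        mid = (lo + hi) / 2
        if _zipf_mean(mid, max_length) > mean_length:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    a = (lo + hi) / 2
    if abs(_zipf_mean(a, max_length) - mean_length) > 1e-9:
        raise ValueError(
            f"bisection failed to reach mean {mean_length} (got {_zipf_mean(a, max_length)})"
        )
    return a


@dataclass
class IndelModel:
    """Indel rates per realised substitution and the length distribution."""

    insertion_rate: float = 0.08
    deletion_rate: float = 0.12
    mean_length: float = 1.7
    max_length: int = 20
    uniform_insert_composition: bool = False
    zipf_exponent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise ValueError("indel rates must be >= 0")
        if self.insertion_rate + self.deletion_rate > 1:
            raise ValueError("coupled indel rates must sum to <= 1 per substitution")
        if not 1 <= self.mean_length <= self.max_length:
            raise ValueError("need 1 <= mean_length <= max_length")
        self.zipf_exponent = calibrate_zipf(self.mean_length, self.max_length)
        self._pmf = truncated_zipf_pmf(self.zipf_exponent, self.max_length)
        self._cdf = np.cumsum(self._pmf)

    def sample_length(self, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self._cdf, rng.random(), side="right")) + 1

    def sample_lengths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.searchsorted(self._cdf, rng.random(n), side="right") + 1


@dataclass
class FragmentationModel:
    """Log-normal fragment sizes (arithmetic mean/sd), uniform start."""

    mean_length: float
    sd_length: float = 300.0
    min_fragment: int = 50
    min_full_length: int = 2

    def __post_init__(self) -> None:
        if self.min_fragment < 1:
            raise ValueError("min_fragment must be >= 1")
        if self.mean_length < self.min_fragment:
            raise ValueError("mean_length must be >= min_fragment")
        if self.min_full_length < 0:
            raise ValueError("min_full_length must be >= 0")
        # moment-match the underlying normal to the arithmetic mean/sd
        m, s = self.mean_length, self.sd_length
        self._sigma2 = math.log(1.0 + (s / m) ** 2)
        self._mu = math.log(m) - self._sigma2 / 2.0

    def sample_raw_length(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(mean=self._mu, sigma=math.sqrt(self._sigma2)))


@dataclass
class SimConfig:
    gput: int = 100
    rng_seed: int = 0
    indel: IndelModel = field(default_factory=IndelModel)
    fragmentation: FragmentationModel | None = None

    def __post_init__(self) -> None:
        if self.gput < 1:
            raise ValueError("gput must be >= 1")


@dataclass
class BranchEvents:
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0
    indel_lengths: list[int] = field(default_factory=list)
    #: (kind, column-key, sampled length) with kind in {"sub","ins","del"};
    #: the key is the mutated site's (or indel anchor's) reference-MSA key.
    records: list[tuple] = field(default_factory=list)

    def merge(self, other: "BranchEvents") -> None:
        self.substitutions += other.substitutions
        self.insertions += other.insertions
        self.deletions += other.deletions
        self.indel_lengths.extend(other.indel_lengths)


# ---------------------------------------------------------------------------
# lineage state and column keys
# ---------------------------------------------------------------------------

class _KeyFactory:
    """Allocates globally unique, totally ordered column keys.

    A key is ``(Fraction, serial)``: the fraction places the column in the
    global left-to-right order, the serial breaks ties between independent
    insertions that land between the same ancestral columns (they are not
    homologous and must occupy distinct columns).
    """

    def __init__(self, start_serial: int = 0):
        self._serial = start_serial

    def between(self, left: Fraction | None, right: Fraction | None, count: int):
        if left is None and right is None:
            left = Fraction(0)
            right = Fraction(1)
        elif left is None:
            left = right - 1
        elif right is None:
            right = left + 1
        span = right - left
        keys = []
        for i in range(count):
            frac = left + span * Fraction(i + 1, count + 1)
            keys.append((frac, self._serial))
            self._serial += 1
        return keys


@dataclass
class SequenceState:
    """A lineage's sequence plus the reference-MSA key of each residue."""

    bases: list[str]
    keys: list[tuple]
    empty: bool = False  # flagged when the lineage shrank below 1 bp

    @classmethod
    def from_record(cls, rec: SeqRecord) -> "SequenceState":
        return cls(list(rec.seq), [(Fraction(i), i) for i in range(len(rec.seq))])

    def copy(self) -> "SequenceState":
        return SequenceState(list(self.bases), list(self.keys), self.empty)

    def sequence(self) -> str:
        return "".join(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


def _site_rate_array(bases: list[str], rates: TripletRateMatrix) -> np.ndarray:
    n = len(bases)
    out = np.empty(n)
    for i in range(n):
        left = bases[i - 1] if i > 0 else None
        right = bases[i + 1] if i < n - 1 else None
        out[i] = rates.context_rates(left, bases[i], right).sum()
    return out * RATE_SCALE


def _choose(weights: np.ndarray, rng: np.random.Generator) -> int:
    cum = np.cumsum(weights)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def evolve_branch(
    state: SequenceState,
    generations: float,
    rates: TripletRateMatrix,
    indel: IndelModel,
    rng: np.random.Generator,
    key_factory: _KeyFactory | None = None,
) -> tuple[SequenceState, BranchEvents]:
    """Evolve one lineage for ``generations`` generations (Gillespie).

    Returns a new state (the input is not mutated) and the event log.  If the
    sequence shrinks below 1 bp the lineage is flagged ``empty`` and the
    branch terminates early.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    state = state.copy()
    events = BranchEvents()
    if state.empty or not state.bases or generations == 0:
        return state, events
    if key_factory is None:
        key_factory = _KeyFactory(start_serial=10 ** 9)
    bases, keys = state.bases, state.keys
    site_rates = _site_rate_array(bases, rates)
    t = 0.0
    while True:
        total = float(site_rates.sum())
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > generations:
            break
        # --- substitution -------------------------------------------------
        i = _choose(site_rates, rng)
        n = len(bases)
        left = bases[i - 1] if i > 0 else None
        right = bases[i + 1] if i < n - 1 else None
        vec = rates.context_rates(left, bases[i], right)
        bases[i] = BASES[_choose(vec, rng)]
        events.substitutions += 1
        events.records.append(("sub", keys[i], 1))
        for j in (i - 1, i, i + 1):
            if 0 <= j < n:
                l = bases[j - 1] if j > 0 else None
                r = bases[j + 1] if j < n - 1 else None
                site_rates[j] = rates.context_rates(l, bases[j], r).sum() * RATE_SCALE
        # --- coupled indels ----------------------------------------------
        dirty = False
        if rng.random() < indel.insertion_rate:
            length = indel.sample_length(rng)
            j = int(rng.integers(len(bases) + 1))
            if indel.uniform_insert_composition:
                comp = np.ones(4)
            else:
                comp = np.array([bases.count(b) for b in BASES], dtype=float)
                if comp.sum() == 0:
                    comp = np.ones(4)
            new_bases = [BASES[_choose(comp, rng)] for _ in range(length)]
            left_key = keys[j - 1][0] if j > 0 else None
            right_key = keys[j][0] if j < len(keys) else None
            new_keys = key_factory.between(left_key, right_key, length)
            bases[j:j] = new_bases
            keys[j:j] = new_keys
            events.insertions += 1
            events.indel_lengths.append(length)
            events.records.append(("ins", new_keys[0], length))
            dirty = True
        if rng.random() < indel.deletion_rate:
            length = indel.sample_length(rng)
            s = int(rng.integers(len(bases)))
            e = min(s + length, len(bases))
            events.deletions += 1
            events.indel_lengths.append(length)
            events.records.append(("del", keys[s], length))
            del bases[s:e]
            del keys[s:e]
            dirty = True
            if not bases:
                state.empty = True
                break
        if dirty:
            site_rates = _site_rate_array(bases, rates)
    return state, events


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def _draw_fragment_interval(
    n: int,
    model: FragmentationModel,
    emitted_full_count: int,
    rng: np.random.Generator,
) -> tuple[int, int, bool]:
    """Returns (start, end, is_full_length) in 0-based half-open coordinates."""
    if emitted_full_count < model.min_full_length:
        return 0, n, True
    if n <= model.min_fragment:
        # parent too short to fragment; emit whole sequence (flagged full)
        return 0, n, True
    raw = model.sample_raw_length(rng)
    length = int(round(raw))
    length = max(model.min_fragment, min(length, n))
    start = int(rng.integers(0, n - length + 1))
    return start, start + length, length == n


def fragment(
    seq: SeqRecord,
    model: FragmentationModel,
    emitted_full_count: int,
    rng: np.random.Generator,
) -> tuple[SeqRecord, tuple[int, int]]:
    """Truncate a copy to a random window of its parent sequence.

    The first ``model.min_full_length`` emissions (tracked by the caller via
    ``emitted_full_count``) are returned full-length.
    """
    start, end, _ = _draw_fragment_interval(len(seq.seq), model, emitted_full_count, rng)
    return SeqRecord(seq.id, seq.seq[start:end]), (start, end)


# ---------------------------------------------------------------------------
# Kimura two-parameter divergence
# ---------------------------------------------------------------------------

def kimura_divergence(row_a: str, row_b: str) -> float:
    """Kimura 2-parameter distance between two equal-length gapped rows.

    Columns containing a gap or N in either row are skipped.  Returns
    ``math.inf`` when the log domain is violated (saturation).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = p = q = 0
    for a, b in zip(row_a, row_b):
        if a in "-N" or b in "-N":
            continue
        n += 1
        if a == b:
            continue
        if (a, b) in transitions:
            p += 1
        else:
            q += 1
    if n == 0:
        return math.inf
    P, Q = p / n, q / n
    x = (1 - 2 * P - Q) * math.sqrt(1 - 2 * Q) if Q < 0.5 else 0.0
    if x <= 0:
        return math.inf
    return -0.5 * math.log(x)


# ---------------------------------------------------------------------------
# whole-tree simulation
# ---------------------------------------------------------------------------

@dataclass
class EvolutionResult:
    extant: list[SeqRecord]
    reference_msa: Msa
    divergence: dict[str, float]  # per-leaf Kimura distance to the seed
    events: dict[str, BranchEvents]  # keyed by child-node name
    dropped: list[str]  # leaves whose lineage shrank to nothing
    fragments: dict[str, tuple[int, int]]  # retained window in parent coords

    def mean_divergence(self) -> float:
        vals = [v for v in self.divergence.values() if math.isfinite(v)]
        if not vals:
            return math.inf
        return float(np.mean(vals))

    def total_events(self) -> BranchEvents:
        out = BranchEvents()
        for ev in self.events.values():
            out.merge(ev)
        return out


def simulate(
    tree: Phylogeny,
    seed: SeqRecord,
    rates: TripletRateMatrix,
    config: SimConfig,
) -> EvolutionResult:
    """Evolve ``seed`` down ``tree`` and assemble the ground-truth MSA."""
    if len(seed.seq) < 3:
        raise ValueError("seed sequence must be at least 3 bp")
    rng = np.random.default_rng(config.rng_seed)
    key_factory = _KeyFactory(start_serial=len(seed.seq))
    root_state = SequenceState.from_record(seed)
    events: dict[str, BranchEvents] = {}
    leaf_states: list[tuple[str, SequenceState]] = []
    dropped: list[str] = []

    # iterative pre-order traversal, each node carrying its evolved state
    stack = [(tree.root, root_state)]
    while stack:
        node, state = stack.pop()
        if node.is_leaf:
            if state.empty or not state.bases:
                dropped.append(node.name)
            else:
                leaf_states.append((node.name, state))
            continue
        for child in reversed(node.children):
            generations = child.branch_length * config.gput
            child_state, ev = evolve_branch(
                state, generations, rates, config.indel, rng, key_factory
            )
            events[child.name] = ev
            stack.append((child, child_state))

    if not leaf_states:
        raise SimulationError("every lineage went extinct (sequence shrank to 0 bp)")

    # fragmentation at leaf emission, in traversal order
    fragments: dict[str, tuple[int, int]] = {}
    emitted: list[tuple[str, list[str], list[tuple]]] = []
    full_count = 0
    for name, state in leaf_states:
        n = len(state)
        if config.fragmentation is not None:
            start, end, is_full = _draw_fragment_interval(
                n, config.fragmentation, full_count, rng
            )
            if is_full:
                full_count += 1
        else:
            start, end = 0, n
        fragments[name] = (start, end)
        emitted.append((name, state.bases[start:end], state.keys[start:end]))

    # assemble the reference MSA from the global column keys
    all_keys = sorted({k for _, _, ks in emitted for k in ks})
    col_of = {k: i for i, k in enumerate(all_keys)}
    ncols = len(all_keys)
    rows: list[tuple[str, str]] = []
    for name, bases, ks in emitted:
        row = ["-"] * ncols
        for b, k in zip(bases, ks):
            row[col_of[k]] = b
        rows.append((name, "".join(row)))
    reference_msa = Msa(rows)

    # per-leaf Kimura divergence to the seed, via the shared column keys
    seed_cols = {(Fraction(i), i): seed.seq[i] for i in range(len(seed.seq))}
    divergence: dict[str, float] = {}
    for name, bases, ks in emitted:
        aligned_seed = []
        aligned_leaf = []
        for b, k in zip(bases, ks):
            sb = seed_cols.get(k)
            if sb is not None:
                aligned_seed.append(sb)
                aligned_leaf.append(b)
        divergence[name] = kimura_divergence("".join(aligned_seed), "".join(aligned_leaf))

    extant = [SeqRecord(name, "".join(bases)) for name, bases, _ in emitted]
    return EvolutionResult(
        extant=extant,
        reference_msa=reference_msa,
        divergence=divergence,
        events=events,
        dropped=dropped,
        fragments=fragments,
    )


# ---------------------------------------------------------------------------
# indel-rate calibration runs
# ---------------------------------------------------------------------------

def calibration_run(
    seed: SeqRecord,
    rates: TripletRateMatrix,
    indel: IndelModel,
    rng_seed: int,
    min_substitutions: int = 100_000,
) -> dict:
    """Accumulate mutation events until ``min_substitutions`` substitutions.

    Deletions outpace insertions under the default parameterisation, so a
    single lineage cannot host arbitrarily many events; fresh lineages are
    evolved from the seed in bursts and their event logs pooled.  Returns the
    pooled counts and the derived per-substitution ratios.
    """
    rng = np.random.default_rng(rng_seed)
    totals = BranchEvents()
    # burst length: ~2000 expected substitutions on the intact seed
    burst_generations = 2000.0 / (len(seed.seq) * RATE_SCALE)
    while totals.substitutions < min_substitutions:
        state = SequenceState.from_record(seed)
        _, ev = evolve_branch(state, burst_generations, rates, indel, rng)
        totals.merge(ev)
    subs = totals.substitutions
    lengths = np.array(totals.indel_lengths, dtype=float)
    return {
        "substitutions": subs,
        "insertions": totals.insertions,
        "deletions": totals.deletions,
        "indel_per_substitution": (totals.insertions + totals.deletions) / subs,
        "insertions_per_substitution": totals.insertions / subs,
        "deletions_per_substitution": totals.deletions / subs,
        "mean_indel_length": float(lengths.mean()) if lengths.size else math.nan,
        "n_indel_lengths": int(lengths.size),
    }
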