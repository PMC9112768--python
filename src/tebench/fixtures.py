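"""Synthetic inputs: TE-like seed sequences and CpG-aware rate matrices.

Real TE studies start from curated family consensi (e.g. Tigger1 at ~2.4 kb,
L2 at ~3.3 kb) and an empirical trinucleotide rate table.  Neither is bundled
here; instead these generators produce sequences and matrices with the two
properties that matter to the toolkit — realistic length/composition and
CpG-context hypermutability — so everything builds and tests offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import BASES, TRIPLETS, SeqRecord, TripletRateMatrix

__all__ = ["FixtureSpec", "make_seed_sequence", "make_rate_matrix"]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class FixtureSpec:
    """Recipe for a synthetic seed (prototype) TE sequence.

    ``seed_length`` defaults to 1200 bp (DNA-transposon scale; use ~3000 for a
    LINE-scale seed).  ``cpg_enrichment`` multiplies the probability of a G
    following a C relative to the background composition: 1 leaves the CpG
    frequency at its compositional expectation, 0 forbids CG dinucleotides.
    """

    seed_length: int = 1200
    gc_fraction: float = 0.4
    cpg_enrichment: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_length < 3:
            raise ValueError("seed_length must be >= 3")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.cpg_enrichment < 0:
            raise ValueError("cpg_enrichment must be >= 0")


def make_seed_sequence(spec: FixtureSpec) -> SeqRecord:
    """Draw a random sequence via a first-order Markov chain over A/C/G/T.

    The background distribution puts ``gc_fraction`` mass on G+C (split
    evenly); after a C, the weight of G is scaled by ``cpg_enrichment`` and
    the row renormalised.
    """
    rng = np.random.default_rng(spec.rng_seed)
    gc = spec.gc_fraction
    background = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    after_c = background.copy()
    after_c[_BASE_INDEX["G"]] *= spec.cpg_enrichment
    total = after_c.sum()
    if total <= 0:  # gc ~ 1 with enrichment 0; cannot happen given gc < 1
        after_c = background
    else:
        after_c = after_c / total
    out = [BASES[rng.choice(4, p=background)]]
    for _ in range(spec.seed_length - 1):
        p = after_c if out[-1] == "C" else background
        out.append(BASES[rng.choice(4, p=p)])
    return SeqRecord(id=f"fixture_seed_{spec.seed_length}bp", seq="".join(out))


def make_rate_matrix(cpg_multiplier: float = 10.0) -> TripletRateMatrix:
    """Build a context-dependent rate table with CpG hypermutability.

    Baseline is K2P-like for every triplet: transitions at twice the rate of
    each transversion.  Triplets containing a CG dinucleotide get their
    deamination-driven transition boosted by ``cpg_multiplier``: C→T when the
    centre C is followed by G, and G→A when the centre G is preceded by C
    (the reverse-strand equivalent).  The result is normalised so the mean
    total rate over the 64 source triplets is 1.
    """
    if cpg_multiplier < 1:
        raise ValueError("cpg_multiplier must be >= 1")
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    rates = np.zeros((64, 4))
    for i, trip in enumerate(TRIPLETS):
        left, center, right = trip
        for b in BASES:
            if b == center:
                continue
            rate = 2.0 if transitions[center] == b else 1.0
            if center == "C" and right == "G" and b == "T":
                rate *= cpg_multiplier
            if center == "G" and left == "C" and b == "A":
                rate *= cpg_multiplier
            rates[i, _BASE_INDEX[b]] = rate
    return TripletRateMatrix(rates).normalized()
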