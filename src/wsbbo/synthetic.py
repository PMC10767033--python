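"""Synthetic fitness landscapes and simulated biopanning count tables.

A motif-based landscape assigns each sequence a true fitness: a baseline
plus a fixed bonus for every motif position carrying its preferred
residue, plus small per-sequence Gaussian noise (a seeded lookup, so the
same sequence always gets the same noise).  Simulated panning draws a
background (N.S.) pool from a uniform multinomial over the variants and
an eluted pool from a multinomial whose weights are softmax-proportional
to exp(fitness) — the standard exponential-selection model, under which
the expected log enrichment score is linear in fitness.  The four
selection rounds of a real campaign are collapsed into one effective
enrichment step, and no PCR or sequencing error is modelled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA20, validate_sequence


@dataclass
class ToyLandscape:
    """Motif-based ground-truth fitness over fixed-length sequences."""

    length: int
    alphabet: str = AA20
    motif: dict[int, str] = field(default_factory=dict)   # position -> residue
    bonus: float = 1.0
    baseline: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pos, aa in self.motif.items():
            if not 0 <= pos < self.length:
                raise ValueError(f"motif position {pos} outside [0, {self.length})")
            if aa not in self.alphabet:
                raise ValueError(f"motif residue {aa!r} not in alphabet")

    @property
    def max_fitness(self) -> float:
        return self.baseline + self.bonus * len(self.motif)

    def optimum(self, fill: str | None = None) -> str:
        """One maximal-fitness sequence (motif residues, *fill* elsewhere)."""
        fill = fill or self.alphabet[0]
        return "".join(
            self.motif.get(i, fill) for i in range(self.length)
        )


def _sequence_noise(landscape: ToyLandscape, sequence: str) -> float:
    if landscape.noise_sd == 0:
        return 0.0
    crc = zlib.crc32(sequence.encode())
    rng = np.random.default_rng((landscape.seed, crc))
    return float(landscape.noise_sd * rng.standard_normal())


def landscape_fitness(landscape: ToyLandscape, sequence: str) -> float:
    """baseline + bonus * (#motif matches) + seeded per-sequence noise."""
    if len(sequence) != landscape.length:
        raise ValueError(
            f"sequence length {len(sequence)} != landscape length {landscape.length}"
        )
    validate_sequence(sequence, landscape.alphabet)
    matches = sum(sequence[pos] == aa for pos, aa in landscape.motif.items())
    return landscape.baseline + landscape.bonus * matches + _sequence_noise(
        landscape, sequence
    )


def simulate_panning(
    landscape: ToyLandscape,
    n_variants: int = 2000,
    reads_per_pool: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-pool count table over random variants.

    Returns columns sequence, count_eluted, count_ns, true_fitness.  Each
    pool's counts sum exactly to *reads_per_pool*.
    """
    if n_variants < 10:
        raise ValueError("need at least 10 variants")
    rng = np.random.default_rng(seed)
    variants: list[str] = []
    seen: set[str] = set()
    while len(variants) < n_variants:
        idx = rng.integers(0, len(landscape.alphabet), size=landscape.length)
        s = "".join(landscape.alphabet[i] for i in idx)
        if s not in seen:
            seen.add(s)
            variants.append(s)
    fitness = np.array([landscape_fitness(landscape, s) for s in variants])
    ns_counts = rng.multinomial(reads_per_pool, np.full(n_variants, 1.0 / n_variants))
    weights = np.exp(fitness - fitness.max())
    weights /= weights.sum()
    eluted_counts = rng.multinomial(reads_per_pool, weights)
    return pd.DataFrame({
        "sequence": variants,
        "count_eluted": eluted_counts,
        "count_ns": ns_counts,
        "true_fitness": fitness,
    })


def default_landscape(seed: int = 0) -> ToyLandscape:
    """The stock desk-scale benchmark: length 12 over a 4-letter alphabet.

    Ten of twelve positions carry a preferred residue with bonus 1.0, so
    random sequences match ~2.5 positions while the optimum scores 10 —
    chance draws cannot exhaust the fitness range, leaving headroom that
    an optimizer must actually search to reach.  Baseline 0 and noise
    sd 0.1 keep labels informative but imperfect.
    """
    return ToyLandscape(
        length=12,
        alphabet="ACDE",
        motif={0: "A", 1: "C", 2: "D", 3: "D", 4: "E", 6: "A", 7: "E",
               8: "C", 9: "D", 11: "E"},
        bonus=1.0,
        baseline=0.0,
        noise_sd=0.1,
        seed=seed,
    )
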