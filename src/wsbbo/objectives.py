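"""Three-objective vectors: activity, stability, solubility (all maximized).

The design loop maximizes (1) the ensemble-mean predicted activity,
(2) prediction stability, encoded as the *negated* ensemble standard
deviation so all objectives share one maximize-all convention, and
(3) a solubility score from a pluggable scorer.

External solubility predictors (protein-language-model or
structure-corrected tools) are not bundled; any tool can be plugged in
through a per-sequence score table, and a deterministic hydropathy-based
toy scorer is shipped for self-contained runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .ensemble import PredictorEnsemble, ensemble_predict

# Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class ObjectiveVector:
    """(activity, stability, solubility) under maximize-all semantics."""

    f_mean: float   # ensemble-mean predicted activity, in [0, 1]
    f_stab: float   # negated ensemble std, in [-0.5, 0]; 0 = perfectly stable
    f_sol: float    # solubility score on the configured scorer's scale

    def as_array(self) -> np.ndarray:
        return np.array([self.f_mean, self.f_stab, self.f_sol])


@dataclass(frozen=True)
class SolubilityScorer:
    """Named deterministic map from sequence to a real-valued solubility score."""

    name: str
    score_fn: Callable[[str], float]

    def __call__(self, sequence: str) -> float:
        return float(self.score_fn(sequence))


def toy_solubility(sequence: str) -> float:
    """Mean per-residue hydrophilicity: negated Kyte-Doolittle hydropathy.

    Hydrophilic-rich sequences score higher; an all-aspartate 39-mer
    scores +3.5, an all-isoleucine one -4.5.  Invariant to residue order.
    """
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return -float(np.mean([KYTE_DOOLITTLE[aa] for aa in sequence]))
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


TOY_SCORER = SolubilityScorer(name="toy", score_fn=toy_solubility)


def table_scorer(path: str | Path, name: str | None = None) -> SolubilityScorer:
    """Adapter for external predictors: a TSV of (sequence, score) pairs."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", header=None, names=["sequence", "score"])
    lookup = dict(zip(table["sequence"], table["score"].astype(float)))

    def score_fn(sequence: str) -> float:
        try:
            return lookup[sequence]
        except KeyError:
            raise ValueError(f"sequence {sequence!r} absent from score table {path}")

    return SolubilityScorer(name=name or f"table:{path}", score_fn=score_fn)


def get_scorer(spec: str) -> SolubilityScorer:
    """Resolve a scorer config value: ``toy`` or ``table:<path>``."""
    if spec == "toy":
        return TOY_SCORER
    if spec.startswith("table:"):
        return table_scorer(spec.split(":", 1)[1])
    raise ValueError(f"unknown solubility scorer {spec!r}")


def evaluate(
    sequence: str, ensemble: PredictorEnsemble, scorer: SolubilityScorer
) -> ObjectiveVector:
    """Assemble the objective vector for one sequence."""
    mean, std = ensemble_predict(ensemble, sequence)
    try:
        sol = scorer(sequence)
    except Exception as exc:
        raise RuntimeError(
            f"solubility scorer {scorer.name!r} failed on {sequence!r}: {exc}"
        ) from exc
    return ObjectiveVector(f_mean=mean, f_stab=-std, f_sol=sol)
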